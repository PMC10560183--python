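"""Regions of interest on the corresponded face mesh.

Two regions drive the expression metrics:

* the **lower face** — all vertices below a plane through the subnasale
  landmark oriented parallel to the horizontal anatomical reference
  plane (Frankfort Horizontal). Its upward normal is supplied as
  recording metadata (``fh_normal``), since the five required landmarks
  cannot reconstruct it;
* the **expression landmarks** — the two most-moving landmarks of each
  expression: the cheilion pair for the smile, the labrale pair for the
  lip purse.

Because the mesh is corresponded, a selection computed once on a clip's
start frame transfers to every other frame (and subject on the same
template) by vertex index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ROIError
from .mesh_io import LandmarkMap, MeshFrame

#: Vertices within this signed distance of the plane count as "below"
#: (included in the lower face) — a deterministic tie-break for vertices
#: lying exactly on the plane.
PLANE_TOL = 1e-9

#: The two most-moving landmarks per expression, in (right/upper, left/lower)
#: order as used by the magnitude and symmetry formulas.
EXPRESSION_LANDMARKS = {
    "smile": ("cheilion_right", "cheilion_left"),
    "lip_purse": ("labrale_superius", "labrale_inferius"),
}


@dataclass(frozen=True)
class CutPlane:
    """An oriented plane: a point on it and a unit normal toward the upper face."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("normal must have unit length")
        object.__setattr__(self, "point", p)
        object.__setattr__(self, "normal", n)

    def signed_distance(self, vertices: np.ndarray) -> np.ndarray:
        """Signed distance of each vertex; positive on the upper-face side."""
        v = np.asarray(vertices, dtype=float)
        return (v - self.point) @ self.normal


@dataclass(frozen=True)
class ROISelection:
    """A sorted, unique set of vertex indices with a semantic label."""

    indices: np.ndarray
    label: str

    def __post_init__(self):
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        if idx.size == 0:
            raise ROIError(f"ROI '{self.label}' is empty")
        if idx.min() < 0:
            raise ROIError(f"ROI '{self.label}' has negative indices")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


def make_subnasale_plane(
    frame: MeshFrame, landmarks: LandmarkMap, fh_normal: np.ndarray
) -> CutPlane:
    """Plane through the subnasale vertex, parallel to the horizontal reference.

    ``fh_normal`` is the (not necessarily unit) upward normal of the
    horizontal reference plane; it is normalized here.
    """
    n = np.asarray(fh_normal, dtype=float).reshape(3)
    norm = np.linalg.norm(n)
    if norm == 0 or not np.isfinite(norm):
        raise ValueError("fh_normal must be a non-zero finite vector")
    point = frame.vertices[landmarks["subnasale"]]
    return CutPlane(point=point, normal=n / norm)


def select_lower_face(frame: MeshFrame, plane: CutPlane, tol: float = PLANE_TOL) -> ROISelection:
    """All vertices on or below the cut plane (signed distance <= tol)."""
    dist = plane.signed_distance(frame.vertices)
    idx = np.flatnonzero(dist <= tol)
    if idx.size == 0:
        raise ROIError(
            "lower-face selection is empty: the cut plane lies below the whole mesh"
        )
    return ROISelection(indices=idx, label="lower_face")


def expression_landmarks(landmarks: LandmarkMap, expression: str) -> ROISelection:
    """The two most-moving landmarks of the given expression as an ROI."""
    try:
        names = EXPRESSION_LANDMARKS[expression]
    except KeyError:
        raise ValueError(
            f"unknown expression '{expression}'; expected one of {sorted(EXPRESSION_LANDMARKS)}"
        ) from None
    return ROISelection(
        indices=np.array([landmarks[n] for n in names], dtype=np.int64),
        label="expression_landmarks",
    )


def write_roi(selection: ROISelection, path) -> None:
    """Export an ROI as a plain index list (one 0-based index per line)."""
    from pathlib import Path

    Path(path).write_text(
        f"# roi {selection.label}\n" + "\n".join(str(i) for i in selection.indices) + "\n"
    )


def read_roi(path, label: str | None = None) -> ROISelection:
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    name = label
    idx = []
    for line in lines:
        line = line.strip()
        if line.startswith("# roi ") and name is None:
            name = line[len("# roi "):].strip()
        elif line and not line.startswith("#"):
            idx.append(int(line))
    return ROISelection(indices=np.array(idx, dtype=np.int64), label=name or "custom")
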