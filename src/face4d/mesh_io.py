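"""Reading and writing corresponded mesh sequences and landmark maps.

A 4D recording is a sequence of triangle meshes sharing one topology:
vertex *i* denotes the same material point of the face in every frame
("correspondence by index", the contract every downstream metric relies
on). This module enforces that contract at load time and round-trips
sequences through standard PLY (ascii / binary little-endian) and OBJ
files. All coordinates are millimetres; vertex indices are 0-based
everywhere, including landmark files.

Landmark maps are flat text files, one ``name index`` pair per line
(``#`` comments allowed), naming anatomical vertices such as the mouth
corners (cheilion) and the midline lip points (labrale superius /
inferius) used by the expression metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import trimesh
import yaml

from .errors import CorrespondenceError, LandmarkError, MeshFormatError

log = logging.getLogger(__name__)

#: Landmarks every analysis needs: subnasale anchors the lower-face cut,
#: the cheilion pair drives the smile metrics, the labrale pair the
#: lip-purse metrics.
REQUIRED_LANDMARKS = (
    "subnasale",
    "cheilion_right",
    "cheilion_left",
    "labrale_superius",
    "labrale_inferius",
)

TIMEPOINTS = ("T0", "T1")
EXPRESSIONS = ("smile", "lip_purse")


@dataclass(frozen=True)
class MeshFrame:
    """One 3D image of a 4D recording.

    vertices : (n, 3) float array, millimetres.
    faces : optional (m, 3) int array of triangle indices; geometry-only
        operations ignore it.
    index : 0-based frame number within its sequence.
    """

    vertices: np.ndarray
    faces: np.ndarray | None = None
    index: int = 0

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 3 or v.shape[0] < 1:
            raise MeshFormatError(f"vertices must be (n, 3) with n >= 1, got {v.shape}")
        if not np.isfinite(v).all():
            raise MeshFormatError("vertex coordinates must be finite")
        object.__setattr__(self, "vertices", v)
        if self.faces is not None:
            f = np.asarray(self.faces, dtype=np.int64)
            if f.size == 0:
                f = None
            elif f.ndim != 2 or f.shape[1] != 3:
                raise MeshFormatError(f"faces must be (m, 3), got {f.shape}")
            elif f.min() < 0 or f.max() >= v.shape[0]:
                raise MeshFormatError("face indices out of vertex range")
            object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]


@dataclass
class MeshSequence:
    """An ordered, corresponded run of MeshFrames at a fixed frame rate."""

    frames: list[MeshFrame]
    fps: float
    subject_id: str | None = None
    timepoint: str | None = None
    expression: str | None = None

    def __post_init__(self):
        if len(self.frames) < 2:
            raise CorrespondenceError("a sequence needs at least 2 frames")
        if not self.fps > 0:
            raise ValueError("fps must be positive")
        n = self.frames[0].n_vertices
        for i, fr in enumerate(self.frames):
            if fr.n_vertices != n:
                raise CorrespondenceError(
                    f"frame {i} has {fr.n_vertices} vertices, expected {n} "
                    "(correspondence violated)"
                )
        if self.timepoint is not None and self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}")
        if self.expression is not None and self.expression not in EXPRESSIONS:
            raise ValueError(f"expression must be one of {EXPRESSIONS}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_vertices(self) -> int:
        return self.frames[0].n_vertices

    def vertex_array(self) -> np.ndarray:
        """Stack all frames into a (n_frames, n_vertices, 3) array."""
        return np.stack([f.vertices for f in self.frames])


@dataclass
class LandmarkMap:
    """Named anatomical landmarks as vertex indices (0-based).

    Because the sequence is corresponded, one index addresses the same
    anatomical point in every frame and every synthetic subject built on
    the same template.
    """

    indices: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.indices = {str(k): int(v) for k, v in self.indices.items()}
        missing = [n for n in REQUIRED_LANDMARKS if n not in self.indices]
        if missing:
            raise LandmarkError(f"missing required landmark(s): {', '.join(missing)}")
        if any(i < 0 for i in self.indices.values()):
            raise LandmarkError("landmark indices must be non-negative")

    def __getitem__(self, name: str) -> int:
        return self.indices[name]

    def __contains__(self, name: str) -> bool:
        return name in self.indices

    def validate(self, n_vertices: int) -> None:
        """Check every index against a concrete vertex count."""
        bad = {k: v for k, v in self.indices.items() if v >= n_vertices}
        if bad:
            raise LandmarkError(
                f"landmark indices out of range for {n_vertices} vertices: {bad}"
            )


def _load_single_mesh(path: Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Load one PLY/OBJ file preserving vertex order exactly."""
    suffix = path.suffix.lower().lstrip(".")
    if suffix not in ("ply", "obj"):
        raise MeshFormatError(f"{path}: unsupported mesh format '.{suffix}'")
    try:
        mesh = trimesh.load(str(path), file_type=suffix, process=False, maintain_order=True)
    except Exception as exc:  # trimesh raises a zoo of types on bad input
        raise MeshFormatError(f"{path}: could not read mesh ({exc})") from exc
    vertices = np.asarray(getattr(mesh, "vertices", np.empty((0, 3))), dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] == 0:
        raise MeshFormatError(f"{path}: no vertices found")
    faces = getattr(mesh, "faces", None)
    if faces is not None:
        faces = np.asarray(faces, dtype=np.int64)
        if faces.size == 0:
            faces = None
    return vertices, faces


def read_mesh_sequence(
    paths: Sequence[str | Path],
    fps: float,
    *,
    subject_id: str | None = None,
    timepoint: str | None = None,
    expression: str | None = None,
) -> MeshSequence:
    """Read an ordered list of PLY/OBJ files as one corresponded sequence.

    Frames are taken in the order given. A vertex-count mismatch between
    frames raises :class:`CorrespondenceError` naming the offending frame.
    """
    frames: list[MeshFrame] = []
    n_ref: int | None = None
    for i, p in enumerate(paths):
        vertices, faces = _load_single_mesh(Path(p))
        if n_ref is None:
            n_ref = vertices.shape[0]
        elif vertices.shape[0] != n_ref:
            raise CorrespondenceError(
                f"frame {i} ({p}) has {vertices.shape[0]} vertices, expected {n_ref}"
            )
        frames.append(MeshFrame(vertices=vertices, faces=faces, index=i))
    if n_ref is None:
        raise MeshFormatError("no mesh paths given")
    return MeshSequence(
        frames=frames,
        fps=fps,
        subject_id=subject_id,
        timepoint=timepoint,
        expression=expression,
    )


def write_mesh_sequence(
    sequence: MeshSequence,
    directory: str | Path,
    stem: str = "frame",
    fmt: str = "ply",
    encoding: str = "binary",
) -> list[Path]:
    """Write every frame as ``<stem>_<index:04d>.<fmt>``; returns the paths.

    PLY files store coordinates as float32, so a round trip preserves
    positions to single precision only.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt not in ("ply", "obj"):
        raise MeshFormatError(f"unsupported output format '{fmt}'")
    paths = []
    for frame in sequence.frames:
        path = directory / f"{stem}_{frame.index:04d}.{fmt}"
        mesh = trimesh.Trimesh(
            vertices=frame.vertices,
            faces=frame.faces if frame.faces is not None else np.empty((0, 3), dtype=np.int64),
            process=False,
        )
        if fmt == "ply":
            data = trimesh.exchange.ply.export_ply(
                mesh, encoding="binary_little_endian" if encoding == "binary" else "ascii"
            )
            path.write_bytes(data if isinstance(data, bytes) else data.encode())
        else:
            path.write_text(trimesh.exchange.obj.export_obj(mesh))
        paths.append(path)
    return paths


def read_landmark_map(path: str | Path, n_vertices: int | None = None) -> LandmarkMap:
    """Read a flat ``name index`` landmark file.

    Lines are ``<name> <0-based vertex index>``, blank lines and ``#``
    comments ignored. If *n_vertices* is given, indices are validated
    against it immediately.
    """
    path = Path(path)
    indices: dict[str, int] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise LandmarkError(f"{path}:{lineno}: expected '<name> <index>', got '{raw}'")
        name, idx = parts
        try:
            indices[name] = int(idx)
        except ValueError as exc:
            raise LandmarkError(f"{path}:{lineno}: index '{idx}' is not an integer") from exc
    lm = LandmarkMap(indices=indices)
    if n_vertices is not None:
        lm.validate(n_vertices)
    return lm


def write_landmark_map(landmarks: LandmarkMap, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{name} {idx}" for name, idx in sorted(landmarks.indices.items())]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_manifest(
    path: str | Path,
    *,
    frame_paths: Iterable[str | Path],
    fps: float,
    landmark_path: str | Path,
    fh_normal: Sequence[float],
    subject_id: str | None = None,
    timepoint: str | None = None,
    expression: str | None = None,
) -> Path:
    """Write a YAML manifest describing one recording.

    The manifest pins the frame order explicitly so ingestion does not
    depend on directory listing order, and carries the head-orientation
    normal (the upward normal of the horizontal reference plane) that the
    lower-face cut needs.
    """
    path = Path(path)
    doc = {
        "fps": float(fps),
        "frames": [str(p) for p in frame_paths],
        "landmarks": str(landmark_path),
        "fh_normal": [float(x) for x in fh_normal],
        "subject_id": subject_id,
        "timepoint": timepoint,
        "expression": expression,
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def read_manifest(path: str | Path) -> dict:
    """Read a recording manifest; relative paths resolve against its folder."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    base = path.parent
    doc["frames"] = [str((base / p) if not Path(p).is_absolute() else Path(p)) for p in doc["frames"]]
    lp = Path(doc["landmarks"])
    doc["landmarks"] = str((base / lp) if not lp.is_absolute() else lp)
    return doc


def load_manifest_sequence(path: str | Path) -> tuple[MeshSequence, LandmarkMap, np.ndarray]:
    """Load the sequence, landmark map and head normal named by a manifest."""
    doc = read_manifest(path)
    seq = read_mesh_sequence(
        doc["frames"],
        fps=doc["fps"],
        subject_id=doc.get("subject_id"),
        timepoint=doc.get("timepoint"),
        expression=doc.get("expression"),
    )
    landmarks = read_landmark_map(doc["landmarks"], n_vertices=seq.n_vertices)
    fh_normal = np.asarray(doc["fh_normal"], dtype=float)
    return seq, landmarks, fh_normal
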