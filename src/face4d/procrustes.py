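"""Ordinary Procrustes superimposition of landmark configurations.

The shape-change parameter asks how much the lower face deformed between
a clip's rest frame and its peak frame *after discounting* any residual
similarity transform (translation, uniform scale, rotation) between the
two configurations. This module implements ordinary Procrustes analysis
(OPA) with reflections disallowed — a face cannot mirror between frames
— via the standard SVD solution.

Two shape-change quantities are exposed:

``shape_change``
    the full Procrustes distance between the two configurations scaled
    to unit centroid size (dimensionless, in [0, 1]); small values
    (~0.02–0.05) are typical for expression-sized deformations of a
    559-vertex lower face.
``shape_change_mm``
    the raw root-sum-of-squares residual in millimetres after the
    similarity fit, which grows with the landmark count.

Both appear in the metrics output; the unit-size form is reported as the
primary shape-change value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateConfigurationError


def _as_configuration(points: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(points, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name} must be a (k, 3) array, got {x.shape}")
    if x.shape[0] < 3:
        raise DegenerateConfigurationError(f"{name} needs at least 3 points")
    if not np.isfinite(x).all():
        raise ValueError(f"{name} has non-finite coordinates")
    return x


def centroid_size(points: np.ndarray) -> float:
    """Root-sum-of-squares of the centred configuration (the usual size measure)."""
    x = np.asarray(points, dtype=float)
    return float(np.linalg.norm(x - x.mean(axis=0)))


@dataclass(frozen=True)
class SuperimpositionResult:
    """The similarity transform mapping Y onto X and the resulting fit.

    ``aligned`` is s·R·y + t applied to every point of Y; ``residual``
    is the root-sum-of-squares distance between X and the aligned Y in
    the input units (mm).
    """

    aligned: np.ndarray
    translation: np.ndarray
    scale: float
    rotation: np.ndarray
    residual: float

    def __post_init__(self):
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")
        if not self.scale > 0:
            raise ValueError("scale must be positive")


def superimpose(X: np.ndarray, Y: np.ndarray) -> SuperimpositionResult:
    """Least-squares similarity fit of Y onto X (reflection disallowed).

    Solves min over (s > 0, R in SO(3), t) of sum_i ||x_i - (s R y_i + t)||^2.
    Requires equal point counts (>= 3), nonzero centroid sizes, and
    configurations of rank >= 2 (a determinate rotation axis).
    """
    X = _as_configuration(X, "X")
    Y = _as_configuration(Y, "Y")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(f"point counts differ: {X.shape[0]} vs {Y.shape[0]}")

    xbar, ybar = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - xbar, Y - ybar
    sx, sy = np.linalg.norm(Xc), np.linalg.norm(Yc)
    if sx <= 0 or sy <= 0:
        raise DegenerateConfigurationError("configuration with zero centroid size")
    if np.linalg.matrix_rank(Yc, tol=1e-9 * sy) < 2 or np.linalg.matrix_rank(Xc, tol=1e-9 * sx) < 2:
        raise DegenerateConfigurationError("configuration of rank < 2 (collinear points)")

    A = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(A)
    # Sign-correct the smallest singular direction so det(R) = +1.
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    trace = float(S[0] + S[1] + d * S[2])
    scale = trace / (sy**2)
    if scale <= 0:
        raise DegenerateConfigurationError("optimal scale is non-positive")
    translation = xbar - scale * (R @ ybar)
    aligned = scale * (Y @ R.T) + translation
    residual = float(np.linalg.norm(X - aligned))
    return SuperimpositionResult(
        aligned=aligned,
        translation=translation,
        scale=scale,
        rotation=R,
        residual=residual,
    )


def shape_change(start_cfg: np.ndarray, end_cfg: np.ndarray) -> float:
    """Full Procrustes distance between the two configurations.

    Both configurations are centred and scaled to unit centroid size
    before the similarity fit, making the result a dimensionless shape
    distance in [0, 1]: 0 iff the configurations differ only by a
    similarity transform, and symmetric in its arguments.
    """
    X = _as_configuration(start_cfg, "start_cfg")
    Y = _as_configuration(end_cfg, "end_cfg")
    sx, sy = centroid_size(X), centroid_size(Y)
    if sx <= 0 or sy <= 0:
        raise DegenerateConfigurationError("configuration with zero centroid size")
    Xu = (X - X.mean(axis=0)) / sx
    Yu = (Y - Y.mean(axis=0)) / sy
    return superimpose(Xu, Yu).residual


def shape_change_mm(start_cfg: np.ndarray, end_cfg: np.ndarray) -> float:
    """Root-sum-of-squares residual (mm) after superimposing end onto start."""
    return superimpose(
        _as_configuration(start_cfg, "start_cfg"),
        _as_configuration(end_cfg, "end_cfg"),
    ).residual
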