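"""Expression clips and the displacement-based motion parameters.

A recording is trimmed to an **expression clip** running from the last
frame in rest position to the first frame at which the expression has
reached its maximum extent. From the clip, per-vertex Euclidean
displacements between start and end frame yield three of the four
motion parameters:

* ``magnitude`` — mean displacement of the two most-moving landmarks
  (cheilion pair for smile, labrale pair for lip purse), in mm;
* ``symmetry`` — absolute difference of those two displacements, in mm
  (0 = perfectly symmetric motion);
* ``time`` — (end − start) / fps, the time needed to reach the maximum
  expression, in s.

The fourth parameter (Procrustes shape change of the lower face) comes
from :mod:`face4d.procrustes`.

Displacement is start-vs-end straight-line distance, not cumulative
path length. No rigid head-motion stabilization is applied by default
(subjects are instructed to hold the head still); an optional rigid
pre-alignment on a stable vertex set is available via
:func:`stabilize_rigid`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import TrimError
from .mesh_io import LandmarkMap, MeshSequence
from .roi import EXPRESSION_LANDMARKS


@dataclass(frozen=True)
class ExpressionClip:
    """A trimmed view of a sequence: rest frame -> maximum frame."""

    sequence: MeshSequence
    start_index: int
    end_index: int

    def __post_init__(self):
        n = self.sequence.n_frames
        if not (0 <= self.start_index < self.end_index < n):
            raise ValueError(
                f"need 0 <= start ({self.start_index}) < end ({self.end_index}) < {n}"
            )

    @property
    def start_frame(self):
        return self.sequence.frames[self.start_index]

    @property
    def end_frame(self):
        return self.sequence.frames[self.end_index]


@dataclass(frozen=True)
class MotionMetrics:
    """The four motion parameters of one expression clip."""

    magnitude: float
    shape_change: float
    symmetry: float
    time: float
    expression: str
    subject_id: str | None = None
    timepoint: str | None = None
    shape_change_mm: float | None = None

    def __post_init__(self):
        if self.magnitude < 0 or self.symmetry < 0:
            raise ValueError("magnitude and symmetry must be non-negative")
        if self.symmetry > 2 * self.magnitude + 1e-9:
            raise ValueError("symmetry cannot exceed twice the magnitude")
        if not self.time > 0:
            raise ValueError("time must be positive")


def displacement_field(clip: ExpressionClip) -> np.ndarray:
    """Per-vertex Euclidean distance (mm) between start and end frame."""
    d = clip.end_frame.vertices - clip.start_frame.vertices
    return np.linalg.norm(d, axis=1)


def _landmark_pair(landmarks: LandmarkMap, expression: str) -> tuple[int, int]:
    try:
        a, b = EXPRESSION_LANDMARKS[expression]
    except KeyError:
        raise ValueError(
            f"unknown expression '{expression}'; expected one of {sorted(EXPRESSION_LANDMARKS)}"
        ) from None
    return landmarks[a], landmarks[b]


def magnitude(field: np.ndarray, landmarks: LandmarkMap, expression: str) -> float:
    """Mean displacement of the expression's two most-moving landmarks (mm)."""
    i, j = _landmark_pair(landmarks, expression)
    return float((field[i] + field[j]) / 2.0)


def symmetry(field: np.ndarray, landmarks: LandmarkMap, expression: str) -> float:
    """Absolute displacement difference of the two landmarks (mm)."""
    i, j = _landmark_pair(landmarks, expression)
    return float(abs(field[i] - field[j]))


def time_to_peak(clip: ExpressionClip) -> float:
    """Seconds from the last rest frame to the first maximum frame."""
    return (clip.end_index - clip.start_index) / clip.sequence.fps


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    half = window // 2
    out = np.empty_like(x, dtype=float)
    for t in range(x.size):
        lo, hi = max(0, t - half), min(x.size, t + half + 1)
        out[t] = x[lo:hi].mean()
    return out


def _robust_noise_scale(x: np.ndarray) -> float:
    """Noise SD estimate from second differences (trend-insensitive).

    For a smooth trajectory the second difference is dominated by the
    additive noise, whose SD it inflates by sqrt(6); the MAD makes the
    estimate robust to the few large values at motion onset/offset.
    """
    if x.size < 3:
        return 0.0
    d2 = np.abs(np.diff(x, n=2))
    return 1.4826 * float(np.median(d2)) / np.sqrt(6.0)


def landmark_activation(
    sequence: MeshSequence, landmarks: LandmarkMap, expression: str
) -> np.ndarray:
    """Mean displacement of the two expression landmarks vs frame 0, per frame."""
    i, j = _landmark_pair(landmarks, expression)
    V = sequence.vertex_array()[:, [i, j], :]  # (T, 2, 3)
    return np.linalg.norm(V - V[0], axis=2).mean(axis=1)


def trim_clip(
    sequence: MeshSequence,
    landmarks: LandmarkMap,
    expression: str,
    *,
    rest_speed_threshold: float = 0.1,
    peak_fraction: float = 0.995,
    min_motion: float = 1.0,
    smooth_window: int = 3,
    start_index: int | None = None,
    end_index: int | None = None,
) -> ExpressionClip:
    """Locate the rest frame and the first maximum frame of an expression.

    The activation a(t) — mean displacement of the two expression
    landmarks relative to frame 0 — is smoothed with a short centred
    moving average; a robust noise scale estimated from its second
    differences makes both rules track the recording's noise level:

    * **end**: the first frame whose smoothed activation reaches
      ``peak_fraction * max - 3 sigma``, advanced to the first local
      maximum of the raw activation (the first frame at which the
      motion has stopped increasing);
    * **start**: the last frame before *end* whose smoothed
      frame-to-frame speed is at or below
      ``max(rest_speed_threshold, 3 sigma_speed)`` while the face is
      still near rest (activation below half maximum); frame 0 if no
      such frame exists (an already-trimmed clip).

    Explicit ``start_index`` / ``end_index`` override either rule.
    Raises :class:`TrimError` when the maximum activation stays below
    ``min_motion`` (mm) — no expression present.
    """
    a = landmark_activation(sequence, landmarks, expression)
    abar = _moving_average(a, smooth_window)
    peak = float(abar.max())
    if peak < min_motion:
        raise TrimError(
            f"no expression detected: peak landmark motion {peak:.3f} mm "
            f"is below the {min_motion:.3f} mm floor"
        )
    # Noise level estimated on the (conservatively delimited) rest
    # segment, where second differences carry no motion signal; if the
    # recording starts mid-motion, fall back to the whole trajectory.
    onset = np.flatnonzero(abar >= 0.05 * peak)
    rest_end = int(onset[0]) - 2 if onset.size else a.size
    sigma = _robust_noise_scale(a[:rest_end]) if rest_end >= 5 else _robust_noise_scale(a)

    if end_index is None:
        thr_end = peak_fraction * peak - 3.0 * sigma
        candidates = np.flatnonzero(abar >= thr_end)
        t = int(candidates[0]) if candidates.size else int(np.argmax(abar))
        while t + 1 < a.size and a[t] < a[t + 1] - 1e-9:
            t += 1
        end = t
    else:
        end = int(end_index)

    if start_index is None:
        zero = a[:end] <= 1e-9
        if sigma <= 1e-9 and zero.any():
            # Noise-free rest (exact zeros cannot occur under continuous
            # noise): the last frame that has not moved at all.
            start = int(np.flatnonzero(zero)[-1])
        else:
            speed = np.diff(abar)
            sigma_speed = np.sqrt(2.0) * _robust_noise_scale(abar)
            thr_start = max(rest_speed_threshold, 3.0 * sigma_speed)
            ok = (speed <= thr_start) & (abar[:-1] <= 0.5 * peak)
            ok = ok[:end]
            if ok.any():
                # Smoothing leaks the onset into the last resting frames,
                # so the last rest-like speed lags the true rest frame by
                # about one frame; step back to stay out of the ramp.
                start = max(int(np.flatnonzero(ok)[-1]) - 1, 0)
            else:
                start = 0
    else:
        start = int(start_index)

    if end <= start:
        end = start + 1
    if end >= sequence.n_frames:
        end = sequence.n_frames - 1
        start = min(start, end - 1)
    return ExpressionClip(sequence=sequence, start_index=start, end_index=end)


def stabilize_rigid(sequence: MeshSequence, indices: np.ndarray) -> MeshSequence:
    """Rigidly align every frame to frame 0 on a stable vertex subset.

    A least-squares rotation+translation (no scaling) is estimated on
    ``indices`` (e.g. upper-face vertices) per frame and applied to the
    whole frame. Off by default in the pipeline; useful when subjects
    moved their head during capture.
    """
    from .mesh_io import MeshFrame

    ref = sequence.frames[0].vertices[indices]
    ref_c = ref - ref.mean(axis=0)
    out = [sequence.frames[0]]
    for frame in sequence.frames[1:]:
        sub = frame.vertices[indices]
        mu = sub.mean(axis=0)
        A = ref_c.T @ (sub - mu)
        U, S, Vt = np.linalg.svd(A)
        D = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
        R = U @ D @ Vt
        aligned = (frame.vertices - mu) @ R.T + ref.mean(axis=0)
        out.append(MeshFrame(vertices=aligned, faces=frame.faces, index=frame.index))
    return MeshSequence(
        frames=out,
        fps=sequence.fps,
        subject_id=sequence.subject_id,
        timepoint=sequence.timepoint,
        expression=sequence.expression,
    )
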