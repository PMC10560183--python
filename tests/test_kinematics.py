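"""Displacement metrics and the clip trimming rule."""

import numpy as np
import pytest

from face4d import (
    ExpressionClip,
    MotionMetrics,
    animate_expression,
    displacement_field,
    magnitude,
    symmetry,
    time_to_peak,
    trim_clip,
)
from face4d.errors import TrimError
from face4d.kinematics import (
    _moving_average,
    _robust_noise_scale,
    landmark_activation,
    stabilize_rigid,
)
from face4d.mesh_io import LandmarkMap, MeshFrame, MeshSequence

LM = dict(subnasale=0, cheilion_right=1, cheilion_left=2, labrale_superius=3,
          labrale_inferius=4)


def _two_frame_clip(disp):
    """A 2-frame sequence where vertex i moves by disp[i] along x."""
    base = np.column_stack([np.zeros(5), np.arange(5.0), np.zeros(5)])
    moved = base.copy()
    moved[:, 0] += np.asarray(disp, dtype=float)
    seq = MeshSequence(
        frames=[MeshFrame(vertices=base, index=0), MeshFrame(vertices=moved, index=1)],
        fps=60.0,
    )
    return ExpressionClip(sequence=seq, start_index=0, end_index=1)


def test_magnitude_and_symmetry_formulas():
    clip = _two_frame_clip([0.0, 10.0, 12.0, 3.0, 5.0])
    field = displacement_field(clip)
    lm = LandmarkMap(indices=LM)
    assert magnitude(field, lm, "smile") == pytest.approx(11.0)  # (10 + 12) / 2
    assert symmetry(field, lm, "smile") == pytest.approx(2.0)  # |10 - 12|
    assert magnitude(field, lm, "lip_purse") == pytest.approx(4.0)
    assert symmetry(field, lm, "lip_purse") == pytest.approx(2.0)


def test_time_to_peak_arithmetic():
    base = np.zeros((3, 3))
    frames = [MeshFrame(vertices=base + t, index=t) for t in range(26)]
    clip = ExpressionClip(sequence=MeshSequence(frames=frames, fps=60.0),
                          start_index=0, end_index=25)
    assert time_to_peak(clip) == pytest.approx(25 / 60)  # 0.41667 s


def test_clip_index_validation():
    seq = _two_frame_clip([0] * 5).sequence
    with pytest.raises(ValueError):
        ExpressionClip(sequence=seq, start_index=1, end_index=1)
    with pytest.raises(ValueError):
        ExpressionClip(sequence=seq, start_index=0, end_index=2)


def test_motion_metrics_validation():
    with pytest.raises(ValueError, match="twice the magnitude"):
        MotionMetrics(magnitude=1.0, shape_change=0.0, symmetry=2.5, time=0.4,
                      expression="smile")
    with pytest.raises(ValueError, match="time"):
        MotionMetrics(magnitude=1.0, shape_change=0.0, symmetry=0.0, time=0.0,
                      expression="smile")


def test_moving_average_edges():
    x = np.array([0.0, 3.0, 6.0, 9.0])
    out = _moving_average(x, 3)
    np.testing.assert_allclose(out, [1.5, 3.0, 6.0, 7.5])  # truncated at the edges
    np.testing.assert_allclose(_moving_average(x, 1), x)


def test_robust_noise_scale_tracks_sigma(rng):
    # On pure noise the second-difference estimator recovers sigma.
    x = rng.normal(0.0, 0.5, size=4000)
    assert abs(_robust_noise_scale(x) - 0.5) < 0.05
    # A smooth trend contributes nothing.
    t = np.linspace(0, 1, 4000)
    assert abs(_robust_noise_scale(10 * t**2 + x) - 0.5) < 0.05


def test_trim_recovers_truth_without_noise(template, rigs):
    seq, truth = animate_expression(template, rigs["smile"], amplitude=12.0,
                                    asymmetry=1.5, time_to_peak=0.4)
    clip = trim_clip(seq, template.landmarks, "smile")
    assert clip.start_index == truth["start_index"]
    assert clip.end_index == truth["end_index"]
    field = displacement_field(clip)
    assert magnitude(field, template.landmarks, "smile") == pytest.approx(12.0, abs=1e-9)
    assert symmetry(field, template.landmarks, "smile") == pytest.approx(1.5, abs=1e-9)


def test_trim_survives_tracking_noise(template, rigs):
    seq, truth = animate_expression(template, rigs["lip_purse"], amplitude=9.0,
                                    asymmetry=1.0, time_to_peak=0.35,
                                    noise_sd=0.15, seed=7)
    clip = trim_clip(seq, template.landmarks, "lip_purse")
    assert abs(clip.start_index - truth["start_index"]) <= 3
    assert abs(clip.end_index - truth["end_index"]) <= 3
    field = displacement_field(clip)
    assert magnitude(field, template.landmarks, "lip_purse") == pytest.approx(9.0, abs=0.5)


def test_trim_rejects_motionless_sequence(template):
    base = template.frame
    seq = MeshSequence(frames=[MeshFrame(vertices=base.vertices, index=t)
                               for t in range(20)], fps=60.0)
    with pytest.raises(TrimError, match="no expression detected"):
        trim_clip(seq, template.landmarks, "smile")


def test_trim_index_overrides(template, rigs):
    seq, _ = animate_expression(template, rigs["smile"], amplitude=10.0)
    clip = trim_clip(seq, template.landmarks, "smile", start_index=2, end_index=20)
    assert (clip.start_index, clip.end_index) == (2, 20)


def test_landmark_activation_zero_at_first_frame(template, rigs):
    seq, _ = animate_expression(template, rigs["smile"], amplitude=10.0)
    a = landmark_activation(seq, template.landmarks, "smile")
    assert a[0] == 0.0
    assert a.argmax() > 0 and a.max() == pytest.approx(10.0, abs=1e-9)


def test_stabilize_rigid_removes_head_motion(template, rigs, rng):
    from scipy.spatial.transform import Rotation

    seq, truth = animate_expression(template, rigs["smile"], amplitude=11.0,
                                    time_to_peak=0.3)
    V = seq.vertex_array().copy()
    # Contaminate every frame after the first with a growing rigid motion.
    for t in range(1, V.shape[0]):
        R = Rotation.from_rotvec([0, 0, 0.002 * t]).as_matrix()
        V[t] = V[t] @ R.T + np.array([0.05, -0.03, 0.02]) * t
    noisy = MeshSequence(
        frames=[MeshFrame(vertices=V[t], index=t) for t in range(V.shape[0])], fps=60.0
    )
    # Stabilize on upper-face vertices (rows above the subnasale row),
    # which the smile rig does not move.
    nx, ny = template.grid_shape
    sn_row = template.landmarks["subnasale"] // nx
    stable = np.arange((sn_row + 3) * nx, nx * ny)
    fixed = stabilize_rigid(noisy, stable)
    clip = trim_clip(fixed, template.landmarks, "smile")
    field = displacement_field(clip)
    assert magnitude(field, template.landmarks, "smile") == pytest.approx(11.0, abs=1e-6)
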