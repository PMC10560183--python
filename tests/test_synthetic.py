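"""Synthetic generator: template construction, rigs, cohorts."""

import numpy as np
import pytest

from face4d import (
    CohortConfig,
    animate_expression,
    build_expression_rig,
    build_face_template,
    generate_cohort,
)
from face4d.mesh_io import REQUIRED_LANDMARKS
from face4d.synthetic import (
    DEFAULT_CALIBRATION,
    SURGICAL_COVARIATES,
    TemplateConstructionError,
    smoothstep,
)


def test_template_basic_properties(template):
    nx, ny = template.grid_shape
    assert template.n_vertices == nx * ny == 1178
    for name in REQUIRED_LANDMARKS:
        assert name in template.landmarks
    assert len(set(template.landmarks.indices.values())) == len(template.landmarks.indices)
    template.landmarks.validate(template.n_vertices)


def test_template_bilateral_symmetry(template):
    V = template.frame.vertices
    nx, ny = template.grid_shape
    grid = V.reshape(ny, nx, 3)
    np.testing.assert_allclose(grid[:, ::-1, 0], -grid[:, :, 0], atol=1e-9)
    np.testing.assert_allclose(grid[:, ::-1, 1:], grid[:, :, 1:], atol=1e-9)
    lm = template.landmarks
    assert V[lm["cheilion_right"], 0] == pytest.approx(-V[lm["cheilion_left"], 0])
    assert V[lm["subnasale"], 0] == 0.0


def test_template_construction_errors():
    with pytest.raises(TemplateConstructionError, match="odd"):
        build_face_template(nx=30)
    with pytest.raises(TemplateConstructionError, match="multiple"):
        build_face_template(nx=25)
    with pytest.raises(TemplateConstructionError, match="lateral_lift"):
        build_face_template(lateral_lift=50.0)


def test_rig_peak_displacement_is_exact(template, rigs):
    for expr, rig in rigs.items():
        ia, ib = (template.landmarks[n] for n in rig.landmark_names)
        peak = rig.peak_displacement(amplitude=10.0, asymmetry=2.0)
        assert np.linalg.norm(peak[ia]) == pytest.approx(11.0, abs=1e-12)
        assert np.linalg.norm(peak[ib]) == pytest.approx(9.0, abs=1e-12)
        # Compact support: the field of one landmark is zero at the other.
        assert np.linalg.norm(rig.field_a[ib]) == 0.0
        assert np.linalg.norm(rig.field_b[ia]) == 0.0
        # Subnasale never moves: the cut plane is stable across the clip.
        assert np.linalg.norm(peak[template.landmarks["subnasale"]]) == 0.0


def test_rig_rejects_overlapping_support(template):
    with pytest.raises(ValueError, match="opposite landmark"):
        build_expression_rig(template, "lip_purse", purse_radius=50.0)


def test_smoothstep_profile():
    t = np.linspace(0, 1, 11)
    s = smoothstep(t)
    assert s[0] == 0.0 and s[-1] == 1.0
    assert (np.diff(s) >= 0).all()
    assert smoothstep(np.array([0.5]))[0] == pytest.approx(0.5)


def test_animate_expression_truth_and_validation(template, rigs):
    seq, truth = animate_expression(template, rigs["smile"], amplitude=10.0,
                                    asymmetry=2.0, time_to_peak=0.4, fps=60.0)
    assert truth["magnitude"] == 10.0 and truth["symmetry"] == 2.0
    assert truth["time"] == pytest.approx(24 / 60)
    assert seq.n_frames == 12 + 24 + 6
    assert truth["end_index"] - truth["start_index"] == 24
    with pytest.raises(ValueError, match="amplitude"):
        animate_expression(template, rigs["smile"], amplitude=0.0)
    with pytest.raises(ValueError, match="asymmetry"):
        animate_expression(template, rigs["smile"], amplitude=1.0, asymmetry=3.0)


def test_animate_expression_noise_is_seeded(template, rigs):
    a, _ = animate_expression(template, rigs["smile"], 10.0, noise_sd=0.2, seed=5)
    b, _ = animate_expression(template, rigs["smile"], 10.0, noise_sd=0.2, seed=5)
    c, _ = animate_expression(template, rigs["smile"], 10.0, noise_sd=0.2, seed=6)
    np.testing.assert_array_equal(a.vertex_array(), b.vertex_array())
    assert not np.array_equal(a.vertex_array(), c.vertex_array())


def test_generate_cohort_is_deterministic(template):
    a = generate_cohort(CohortConfig(seed=3), template=template)
    b = generate_cohort(CohortConfig(seed=3), template=template)
    assert a.ground_truth.equals(b.ground_truth)
    assert a.subjects.equals(b.subjects)
    c = generate_cohort(CohortConfig(seed=4), template=template)
    assert not a.ground_truth.equals(c.ground_truth)


def test_cohort_structure_and_calibration(template):
    cohort = generate_cohort(CohortConfig(seed=1), template=template)
    truth = cohort.ground_truth
    assert len(truth) == 26 * 2 * 2  # subjects x expressions x timepoints
    assert set(truth["timepoint"]) == {"T0", "T1"}
    assert set(truth["expression"]) == {"smile", "lip_purse"}
    assert (truth["magnitude"] > 0).all()
    assert (truth["symmetry"] <= 1.9 * truth["magnitude"] + 1e-9).all()
    # Stratified sampling: cohort means sit on the calibration fixture.
    for expr, cal in DEFAULT_CALIBRATION.items():
        sub = truth[truth["expression"] == expr]
        t0 = sub[sub["timepoint"] == "T0"]
        assert t0["magnitude"].mean() == pytest.approx(cal["magnitude_mean_t0"], abs=0.15)
        assert t0["magnitude"].std(ddof=1) == pytest.approx(cal["magnitude_between_sd"], rel=0.15)
        assert t0["symmetry"].mean() == pytest.approx(cal["symmetry_mean_t0"], abs=0.3)
        assert t0["time"].mean() == pytest.approx(cal["time_mean_t0"], abs=0.02)
    # Covariates: truncated draws stay non-negative.
    for name, (_, _, nonneg) in SURGICAL_COVARIATES.items():
        if nonneg:
            assert (cohort.subjects[name] >= 0).all()
    assert set(cohort.subjects["intervention_type"]) == {"bimax", "bsso_only"}
    assert (cohort.subjects["intervention_type"] == "bimax").sum() == 21


def test_clip_seeds_are_distinct(template):
    cohort = generate_cohort(CohortConfig(seed=0), template=template)
    keys = {
        cohort.clip_seed(i, e, t).spawn_key
        for i in range(3)
        for e in ("smile", "lip_purse")
        for t in ("T0", "T1")
    }
    assert len(keys) == 12


def test_cohort_config_validation():
    with pytest.raises(ValueError, match="n_subjects"):
        CohortConfig(n_subjects=1)
    with pytest.raises(ValueError, match="sampling"):
        CohortConfig(sampling="bootstrap")
    with pytest.raises(ValueError, match="noise_sd"):
        CohortConfig(noise_sd=-0.1)


def test_iid_sampling_differs_from_stratified(template):
    a = generate_cohort(CohortConfig(seed=2, sampling="stratified"), template=template)
    b = generate_cohort(CohortConfig(seed=2, sampling="iid"), template=template)
    assert not np.allclose(
        a.ground_truth["magnitude"].to_numpy(), b.ground_truth["magnitude"].to_numpy()
    )
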