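"""Statistical layer: mixed-model EMMs, Wilcoxon, OLS, and ICC oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from face4d import fit_surgical_model, fit_time_class_model, icc, wilcoxon_paired
from face4d.errors import FitError
from face4d.stats import (
    SURGICAL_TERMS,
    metric_differences,
    validate_cohort_table,
)


def _paired_table(t0, t1, classes, metric="magnitude", expression="smile"):
    rows = []
    for i, (a, b, k) in enumerate(zip(t0, t1, classes)):
        sid = f"S{i:02d}"
        rows.append(dict(subject_id=sid, skeletal_class=k, timepoint="T0",
                         expression=expression, **{metric: a}))
        rows.append(dict(subject_id=sid, skeletal_class=k, timepoint="T1",
                         expression=expression, **{metric: b}))
    return pd.DataFrame(rows)


def test_validate_cohort_table_errors():
    table = _paired_table([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0],
                          ["II", "II", "III", "III"])
    validate_cohort_table(table, "magnitude", "smile")
    with pytest.raises(ValueError, match="no rows"):
        validate_cohort_table(table, "magnitude", "lip_purse")
    with pytest.raises(ValueError, match="both timepoints"):
        validate_cohort_table(table.iloc[:-1], "magnitude", "smile")
    one_class = _paired_table([1.0, 2.0], [2.0, 3.0], ["II", "II"])
    with pytest.raises(ValueError, match="each skeletal class"):
        validate_cohort_table(one_class, "magnitude", "smile")


def test_emm_equals_cell_means_in_balanced_design(rng):
    """Balanced 2x2 layout: the mixed-model EMMs are the sample cell means."""
    n_per_class = 8
    classes = ["II"] * n_per_class + ["III"] * n_per_class
    subj = rng.normal(0, 2.0, size=2 * n_per_class)
    cell = {("T0", "II"): 10.0, ("T1", "II"): 12.0, ("T0", "III"): 9.0, ("T1", "III"): 13.5}
    t0 = np.array([cell[("T0", k)] for k in classes]) + subj + rng.normal(0, 0.5, 2 * n_per_class)
    t1 = np.array([cell[("T1", k)] for k in classes]) + subj + rng.normal(0, 0.5, 2 * n_per_class)
    table = _paired_table(t0, t1, classes)
    res = fit_time_class_model(table, "magnitude", "smile")
    by = res.by_class.set_index(["skeletal_class", "timepoint"])
    for (tp, k), _ in cell.items():
        sample_mean = table[(table["timepoint"] == tp)
                            & (table["skeletal_class"] == k)]["magnitude"].mean()
        assert by.loc[(k, tp), "emm"] == pytest.approx(sample_mean, abs=1e-6)
    for tp in ("T0", "T1"):
        pooled_expected = np.mean([by.loc[("II", tp), "emm"], by.loc[("III", tp), "emm"]])
        assert res.emm(tp) == pytest.approx(pooled_expected, abs=1e-9)
    assert res.p_time < 0.001  # a +2 / +4.5 shift against 0.5 mm residual noise
    assert res.n_subjects == 2 * n_per_class


def test_emm_degenerate_constant_response():
    table = _paired_table([5.0] * 4, [5.0] * 4, ["II", "II", "III", "III"])
    res = fit_time_class_model(table, "magnitude", "smile")
    assert res.degenerate
    assert res.emm("T0") == res.emm("T1") == 5.0
    assert res.p_time == 1.0


def _wilcoxon_enumeration(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = float(ranks[d > 0].sum())
    m = n * (n + 1) / 2.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = float(ranks[np.array(signs, dtype=bool)].sum())
        if abs(w - m / 2.0) >= abs(w_obs - m / 2.0) - 1e-12:
            count += 1
    return count / 2.0**n


def test_wilcoxon_matches_enumeration(rng):
    for _ in range(10):
        n = int(rng.integers(4, 11))
        before = rng.normal(size=n)
        after = before + rng.normal(0.3, 1.0, size=n)
        res = wilcoxon_paired(before, after)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(_wilcoxon_enumeration(after - before), abs=1e-12)


def test_wilcoxon_zero_handling():
    before = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    after = np.array([1.0, 2.5, 3.5, 4.25, 5.75, 6.0])  # two zero differences
    res = wilcoxon_paired(before, after)
    assert res.n_zero == 2 and res.n_used == 4
    res0 = wilcoxon_paired(before, before)
    assert res0.degenerate and res0.p_value == 1.0


def test_wilcoxon_large_sample_uses_approximation(rng):
    before = rng.normal(size=40)
    after = before + rng.normal(0.5, 1.0, size=40)
    res = wilcoxon_paired(before, after)
    assert res.method == "approx"
    assert 0.0 <= res.p_value <= 1.0


def _covariate_frame(rng, n):
    data = {c: rng.normal(2.0, 1.0, size=n) for c in SURGICAL_TERMS}
    data["skeletal_class"] = ["II"] * (n // 2) + ["III"] * (n - n // 2)
    data["intervention_type"] = rng.permutation(["bimax"] * (n - 5) + ["bsso_only"] * 5)
    return pd.DataFrame(data)


def test_surgical_model_recovers_planted_coefficients(rng):
    n = 30
    cov = _covariate_frame(rng, n)
    beta = dict(zip(SURGICAL_TERMS, [0.5, -0.2, 0.0, 0.3, 0.1, 0.0, 0.4, -0.1, 0.2]))
    diff = 1.0 + sum(beta[c] * cov[c] for c in SURGICAL_TERMS) \
        + 0.7 * (cov["skeletal_class"] == "III")
    t0 = rng.normal(10, 2, size=n)
    table = _paired_table(t0, t0 + diff, cov["skeletal_class"])
    for c in SURGICAL_TERMS + ("intervention_type",):
        table = table.merge(
            pd.DataFrame({"subject_id": table["subject_id"].unique(), c: cov[c]}),
            on="subject_id",
        )
    fitted = fit_surgical_model(table, "magnitude", "smile").set_index("term")
    for c in SURGICAL_TERMS:
        assert fitted.loc[c, "estimate"] == pytest.approx(beta[c], abs=1e-8)
    assert fitted.loc["intercept", "estimate"] == pytest.approx(1.0, abs=1e-8)
    assert fitted.loc["skeletal_class_III", "estimate"] == pytest.approx(0.7, abs=1e-8)


def test_surgical_model_names_collinear_columns(rng):
    n = 30
    cov = _covariate_frame(rng, n)
    cov["vertical_translation_maxilla"] = 2.0 * cov["sagittal_translation_maxilla"]
    table = _paired_table(rng.normal(10, 2, n), rng.normal(12, 2, n), cov["skeletal_class"])
    for c in SURGICAL_TERMS + ("intervention_type",):
        table = table.merge(
            pd.DataFrame({"subject_id": table["subject_id"].unique(), c: cov[c]}),
            on="subject_id",
        )
    with pytest.raises(FitError, match="vertical_translation_maxilla"):
        fit_surgical_model(table, "magnitude", "smile")


def test_metric_differences():
    table = _paired_table([1.0, 2.0, 3.0, 4.0], [2.5, 2.0, 6.0, 3.0],
                          ["II", "II", "III", "III"])
    diff = metric_differences(table, "magnitude", "smile").set_index("subject_id")
    np.testing.assert_allclose(diff["difference"], [1.5, 0.0, 3.0, -1.0])


def test_icc_matches_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    for trial in range(5):
        n, k = int(rng.integers(6, 15)), int(rng.integers(2, 5))
        mat = rng.normal(10, 2, size=(n, k)) + rng.normal(0, 1, size=(n, 1))
        long = pd.DataFrame(
            dict(
                targets=np.repeat(np.arange(n), k),
                raters=np.tile(np.arange(k), n),
                ratings=mat.ravel(),
            )
        )
        ref = pg.intraclass_corr(long, targets="targets", raters="raters",
                                 ratings="ratings").set_index("Type")
        assert icc(mat, "agreement").estimate == pytest.approx(
            ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert icc(mat, "consistency").estimate == pytest.approx(
            ref.loc["ICC(C,1)", "ICC"], abs=1e-9)


def test_icc_perfect_agreement():
    col = np.linspace(3.0, 9.0, 8)
    mat = np.column_stack([col, col, col])
    for kind in ("agreement", "consistency"):
        res = icc(mat, kind)
        assert res.estimate == res.ci_low == res.ci_high == 1.0


def test_icc_input_validation(rng):
    with pytest.raises(ValueError, match="at least 5 subjects"):
        icc(rng.normal(size=(4, 2)))
    bad = rng.normal(size=(6, 2))
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        icc(bad)
    with pytest.raises(ValueError, match="kind"):
        icc(rng.normal(size=(6, 2)), kind="anything")
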