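"""Cohort-level statistics for the paired pre/post expression metrics.

The analysis layer mirrors a paired two-timepoint design with a
between-subject factor (skeletal class II vs III):

* a linear mixed-effects model per metric and expression with a random
  subject intercept and fixed effects time, class and their interaction
  (REML), reported as estimated marginal means (EMMs) with 95% CIs —
  pooled over class and per class. Inference uses the split-plot t
  reference distribution with ``n_subjects - 2`` denominator degrees of
  freedom, which is exact for the balanced two-by-two layout;
* a paired Wilcoxon signed-rank sensitivity test (exact for n <= 25
  without ties, normal approximation with continuity correction
  otherwise; zero differences are dropped and counted);
* a multivariate linear model regressing each subject's T1 - T0 metric
  difference on the nine surgical-movement covariates plus skeletal
  class and intervention type (OLS);
* two-way single-measure intraclass correlations for method-error
  analysis, in the absolute-agreement and consistency forms, with
  F-based 95% CIs.

No multiple-testing correction is applied; metrics are reported each on
their own, matching the per-metric reporting convention of the study
design this package emulates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import FitError

METRIC_COLUMNS = ("magnitude", "shape_change", "symmetry", "time")

#: Surgical covariates expected by the difference model (mm / degrees).
SURGICAL_TERMS = (
    "sagittal_translation_maxilla",
    "vertical_translation_maxilla",
    "transversal_translation_maxilla",
    "sagittal_translation_mandibula",
    "vertical_translation_mandibula",
    "transversal_translation_mandibula",
    "roll_maxillomandibular",
    "pitch_maxillomandibular",
    "yaw_maxillomandibular",
)


def validate_cohort_table(table: pd.DataFrame, metric: str, expression: str) -> pd.DataFrame:
    """Subset to one expression and check the complete-case pairing."""
    required = {"subject_id", "skeletal_class", "timepoint", "expression", metric}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns: {sorted(missing)}")
    sub = table[table["expression"] == expression].copy()
    if sub.empty:
        raise ValueError(f"no rows for expression '{expression}'")
    counts = sub.groupby("subject_id")["timepoint"].nunique()
    incomplete = counts[counts < 2].index.tolist()
    if incomplete:
        raise ValueError(f"subjects without both timepoints: {incomplete}")
    per_class = sub.drop_duplicates("subject_id").groupby("skeletal_class").size()
    if (per_class < 2).any() or len(per_class) < 2:
        raise ValueError("need at least 2 subjects in each skeletal class")
    return sub


@dataclass
class EmmResult:
    """Estimated marginal means for one metric of one expression."""

    metric: str
    expression: str
    pooled: pd.DataFrame  # timepoint, emm, ci_low, ci_high
    by_class: pd.DataFrame  # skeletal_class, timepoint, emm, ci_low, ci_high, p_time
    p_time: float
    p_class: float
    p_interaction: float
    n_subjects: int
    degenerate: bool = False

    def __post_init__(self):
        for df in (self.pooled, self.by_class):
            if not ((df["ci_low"] <= df["emm"] + 1e-12) & (df["emm"] <= df["ci_high"] + 1e-12)).all():
                raise ValueError("CI bounds must bracket the estimate")

    def emm(self, timepoint: str) -> float:
        return float(self.pooled.set_index("timepoint").loc[timepoint, "emm"])


def _contrast(est_cov, beta, c, df):
    c = np.asarray(c, dtype=float)
    est = float(c @ beta)
    se = float(np.sqrt(c @ est_cov @ c))
    if se == 0:
        return est, 0.0, 1.0 if est == 0 else 0.0
    p = 2.0 * sps.t.sf(abs(est) / se, df)
    return est, se, float(p)


def fit_time_class_model(table: pd.DataFrame, metric: str, expression: str) -> EmmResult:
    """Mixed model ``metric ~ time * class + (1 | subject)`` with EMMs.

    EMMs average the four cell means with equal class weights (so the
    pooled value is not driven by a class imbalance). Wald-type 95% CIs
    and p-values use t(n_subjects - 2).
    """
    sub = validate_cohort_table(table, metric, expression)
    n_subj = sub["subject_id"].nunique()
    df_t = n_subj - 2
    y = sub[metric].to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise FitError(f"non-finite values in metric '{metric}'")

    if np.var(y) < 1e-24:
        # Constant response: every EMM equals the constant, no time effect.
        c = float(y[0])
        pooled = pd.DataFrame(
            {"timepoint": ["T0", "T1"], "emm": c, "ci_low": c, "ci_high": c}
        )
        by_class = pd.DataFrame(
            [
                {"skeletal_class": k, "timepoint": tp, "emm": c, "ci_low": c, "ci_high": c, "p_time": 1.0}
                for k in ("II", "III")
                for tp in ("T0", "T1")
            ]
        )
        return EmmResult(metric, expression, pooled, by_class, 1.0, 1.0, 1.0, n_subj, degenerate=True)

    sub = sub.rename(columns={metric: "_y"})
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                "_y ~ C(timepoint) * C(skeletal_class)",
                data=sub,
                groups=sub["subject_id"],
            )
            fit = model.fit(reml=True)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise FitError(f"mixed model failed for {metric}/{expression}: {exc}") from exc

    beta = np.asarray(fit.fe_params)
    k = beta.size  # 4 fixed effects with treatment coding
    V = np.asarray(fit.cov_params())[:k, :k]
    if not np.isfinite(V).all():
        raise FitError(f"singular mixed-model fit for {metric}/{expression}")

    # Treatment coding: [intercept, T1, classIII, T1:classIII]
    cells = {
        ("T0", "II"): [1, 0, 0, 0],
        ("T0", "III"): [1, 0, 1, 0],
        ("T1", "II"): [1, 1, 0, 0],
        ("T1", "III"): [1, 1, 1, 1],
    }
    tcrit = sps.t.ppf(0.975, df_t)

    pooled_rows = []
    for tp in ("T0", "T1"):
        c = (np.array(cells[(tp, "II")], float) + np.array(cells[(tp, "III")], float)) / 2.0
        est, se, _ = _contrast(V, beta, c, df_t)
        pooled_rows.append(
            {"timepoint": tp, "emm": est, "ci_low": est - tcrit * se, "ci_high": est + tcrit * se}
        )
    pooled = pd.DataFrame(pooled_rows)

    by_rows = []
    for klass in ("II", "III"):
        c_time = np.array(cells[("T1", klass)], float) - np.array(cells[("T0", klass)], float)
        _, _, p_time_k = _contrast(V, beta, c_time, df_t)
        for tp in ("T0", "T1"):
            est, se, _ = _contrast(V, beta, np.array(cells[(tp, klass)], float), df_t)
            by_rows.append(
                {
                    "skeletal_class": klass,
                    "timepoint": tp,
                    "emm": est,
                    "ci_low": est - tcrit * se,
                    "ci_high": est + tcrit * se,
                    "p_time": p_time_k,
                }
            )
    by_class = pd.DataFrame(by_rows)

    c_time_pooled = np.array([0, 1, 0, 0.5], float)
    _, _, p_time = _contrast(V, beta, c_time_pooled, df_t)
    c_class_pooled = np.array([0, 0, 1, 0.5], float)
    _, _, p_class = _contrast(V, beta, c_class_pooled, df_t)
    _, _, p_inter = _contrast(V, beta, np.array([0, 0, 0, 1], float), df_t)

    return EmmResult(metric, expression, pooled, by_class, p_time, p_class, p_inter, n_subj)


@dataclass(frozen=True)
class WilcoxonResult:
    p_value: float
    statistic: float
    n_used: int
    n_zero: int
    degenerate: bool = False
    method: str = "exact"


def wilcoxon_paired(before, after) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped before ranking (Wilcoxon's original
    convention) and counted in ``n_zero``. The exact null distribution
    is used for n <= 25 when the absolute differences are tie-free;
    otherwise the normal approximation with continuity correction.
    All-zero differences yield the degenerate result p = 1.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.ndim != 1 or before.size < 2:
        raise ValueError("before/after must be equal-length 1-d arrays with n >= 2")
    d = after - before
    nz = d[d != 0]
    n_zero = int(d.size - nz.size)
    if nz.size == 0:
        return WilcoxonResult(1.0, 0.0, 0, n_zero, degenerate=True, method="degenerate")
    ties = np.unique(np.abs(nz)).size < nz.size
    if nz.size <= 25 and not ties:
        method = "exact"
        res = sps.wilcoxon(nz, method="exact", alternative="two-sided")
    else:
        method = "approx"
        res = sps.wilcoxon(nz, method="approx", correction=True, alternative="two-sided")
    return WilcoxonResult(float(res.pvalue), float(res.statistic), int(nz.size), n_zero, method=method)


def metric_differences(table: pd.DataFrame, metric: str, expression: str) -> pd.DataFrame:
    """Per-subject T1 - T0 differences of a metric, with subject covariates."""
    sub = validate_cohort_table(table, metric, expression)
    wide = sub.pivot_table(index="subject_id", columns="timepoint", values=metric, aggfunc="first")
    diff = (wide["T1"] - wide["T0"]).rename("difference").reset_index()
    keep = ["subject_id", "skeletal_class"] + [c for c in SURGICAL_TERMS if c in sub.columns]
    if "intervention_type" in sub.columns:
        keep.append("intervention_type")
    info = sub[keep].drop_duplicates("subject_id")
    return diff.merge(info, on="subject_id")


def fit_surgical_model(table: pd.DataFrame, metric: str, expression: str) -> pd.DataFrame:
    """OLS of the per-subject metric difference on the surgical covariates.

    Design: intercept + the nine surgical movements + skeletal class
    (III vs II) + intervention type (BSSO-only vs bimaxillary). Returns
    a coefficient table with estimate, std. error, t and p per term.
    Raises :class:`FitError` naming (near-)collinear columns on rank
    deficiency.
    """
    data = metric_differences(table, metric, expression)
    missing = [c for c in SURGICAL_TERMS if c not in data.columns]
    if missing:
        raise ValueError(f"cohort table lacks surgical covariates: {missing}")
    X = pd.DataFrame({"intercept": np.ones(len(data))})
    for c in SURGICAL_TERMS:
        X[c] = data[c].to_numpy(dtype=float)
    X["skeletal_class_III"] = (data["skeletal_class"] == "III").astype(float)
    if "intervention_type" in data.columns:
        X["intervention_bsso_only"] = (data["intervention_type"] == "bsso_only").astype(float)
    Xm = X.to_numpy()
    if len(data) <= Xm.shape[1]:
        raise FitError(
            f"only {len(data)} subjects for {Xm.shape[1]} model terms; cannot fit"
        )
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # Name columns whose QR diagonal collapses.
        _, R = np.linalg.qr(Xm)
        diag = np.abs(np.diag(R))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise FitError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(data["difference"].to_numpy(dtype=float), Xm).fit()
    return pd.DataFrame(
        {
            "term": X.columns,
            "estimate": fit.params,
            "std_error": fit.bse,
            "t_value": fit.tvalues,
            "p_value": fit.pvalues,
        }
    ).reset_index(drop=True)


@dataclass(frozen=True)
class IccResult:
    """A single-measure two-way intraclass correlation with 95% CI."""

    kind: str
    estimate: float
    ci_low: float
    ci_high: float
    msr: float
    msc: float
    mse: float
    n_subjects: int
    n_raters: int

    def __post_init__(self):
        if self.estimate > 1 + 1e-12:
            raise ValueError("ICC cannot exceed 1")
        if not (self.ci_low <= self.estimate + 1e-9 and self.estimate <= self.ci_high + 1e-9):
            raise ValueError("CI must bracket the estimate")


def _two_way_mean_squares(ratings: np.ndarray) -> tuple[float, float, float, int, int]:
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-d subjects x raters matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise ValueError("need at least 5 subjects and 2 raters/repetitions")
    if not np.isfinite(x).all():
        raise ValueError("ratings contain missing or non-finite cells")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = max(sst - ssr - ssc, 0.0)
    # Cancellation guard: identical columns leave an O(eps) residue in
    # sse/ssc that would keep a mathematically exact ICC of 1 just below 1.
    tol = 1e-12 * sst
    sse = 0.0 if sse < tol else sse
    ssc = 0.0 if ssc < tol else ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(ratings: np.ndarray, kind: str = "agreement", alpha: float = 0.05) -> IccResult:
    """Two-way single-measure ICC from the ANOVA mean squares.

    ``kind="agreement"`` penalizes systematic rater offsets (absolute
    agreement, two-way random); ``kind="consistency"`` does not. CIs
    follow the standard F-based constructions (exact for consistency,
    Satterthwaite-type for agreement).
    """
    if kind not in ("agreement", "consistency"):
        raise ValueError("kind must be 'agreement' or 'consistency'")
    msr, msc, mse, n, k = _two_way_mean_squares(ratings)

    if mse == 0.0 and msc == 0.0:
        # Identical columns: perfect reliability in both senses.
        return IccResult(kind, 1.0, 1.0, 1.0, msr, msc, mse, n, k)

    if kind == "consistency":
        if mse == 0.0:
            return IccResult(kind, 1.0, 1.0, 1.0, msr, msc, mse, n, k)
        est = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse
        d1, d2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / sps.f.ppf(1 - alpha / 2, d1, d2)
        fu = f_obs * sps.f.ppf(1 - alpha / 2, d2, d1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    else:
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom == 0:
            raise ValueError("degenerate ratings: zero total variance")
        est = (msr - mse) / denom
        if mse == 0.0 and np.isclose(est, 1.0):
            return IccResult(kind, 1.0, 1.0, 1.0, msr, msc, mse, n, k)
        a = k * est / (n * (1 - est)) if est < 1 else np.inf
        b = 1 + k * est * (n - 1) / (n * (1 - est)) if est < 1 else np.inf
        if not np.isfinite(a):
            lo = hi = 1.0
        else:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f1 * mse) / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f2 * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2 * msr)
    lo = min(lo, est)
    hi = max(hi, est)
    return IccResult(kind, float(est), float(lo), float(min(hi, 1.0)), msr, msc, mse, n, k)
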