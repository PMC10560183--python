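"""Shared fixtures for the face4d test suite.

The expensive session fixtures (the default template, the expression
rigs, and the 100-replicate calibrated-recovery study) are built once
and shared; every test that only needs geometry or a small cohort
builds its own cheap objects instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from face4d import (
    CohortConfig,
    build_expression_rig,
    build_face_template,
    fit_time_class_model,
    generate_cohort,
)
from face4d.pipeline import compute_cohort_metrics

#: Replicate seeds for the recovery study: fixed a priori, 0..99.
RECOVERY_SEEDS = tuple(range(100))


@pytest.fixture(scope="session")
def template():
    return build_face_template()


@pytest.fixture(scope="session")
def rigs(template):
    return {e: build_expression_rig(template, e) for e in ("smile", "lip_purse")}


@pytest.fixture(scope="session")
def recovery_replicates(template):
    """Pooled EMMs and mean paired differences over 100 default cohorts.

    For each seed, one full measurement pass (mesh realization, trim,
    ROI, displacement metrics) followed by the mixed-model EMMs for
    magnitude, symmetry and time of both expressions, plus the mean
    per-subject paired magnitude differences straight from the metrics
    table. Shared by the calibrated-recovery and effect-size tests.
    """
    rows = []
    for seed in RECOVERY_SEEDS:
        cohort = generate_cohort(CohortConfig(seed=seed), template=template)
        metrics, failures = compute_cohort_metrics(cohort)
        assert not failures, f"seed {seed}: unexpected clip failures {failures}"
        rec = {"seed": seed}
        for expr in ("smile", "lip_purse"):
            for metric in ("magnitude", "symmetry", "time"):
                res = fit_time_class_model(metrics, metric, expr)
                rec[f"{expr}.{metric}.T0"] = res.emm("T0")
                rec[f"{expr}.{metric}.T1"] = res.emm("T1")
            wide = metrics[metrics["expression"] == expr].pivot_table(
                index="subject_id", columns="timepoint", values="magnitude", aggfunc="first"
            )
            rec[f"{expr}.magnitude.diff"] = float((wide["T1"] - wide["T0"]).mean())
        rows.append(rec)
    return pd.DataFrame(rows).set_index("seed")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
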