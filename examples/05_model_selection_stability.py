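"""Augmented backward elimination with bootstrap stability.

Builds a cohort whose reappraisal success depends only on the focal
(dorsal somatomotor) network's within connectivity, quadratic age, and its
between-connectivity to the lateral somatomotor network; then selects
among 15 candidates by AIC with a change-in-estimate veto and reports
bootstrap inclusion frequencies.
"""

import numpy as np
import pandas as pd

import netseg
from netseg import (
    CohortSpec,
    prepare_predictor,
    simulate_metrics_cohort,
    smd_between_model,
    standardize,
)

FOCAL = "SomatomotorDorsal"
spec = CohortSpec(
    n_subjects=227,
    seed=5,
    planted_beta_seg={},
    planted_beta_within={FOCAL: -0.27},
    planted_beta_pair={"SomatomotorLateral": 0.22},
    age_beta_quad=-0.19,
)
subjects, truth = simulate_metrics_cohort(spec, focal=FOCAL)

success_z = standardize(subjects["success_true"].to_numpy())
age_z = standardize(subjects["age"].to_numpy())
fd = subjects["mean_fd"].to_numpy()
others = [k for k in netseg.ANALYSIS_NETWORKS if k != FOCAL]
pairs = pd.DataFrame(
    {
        j: prepare_predictor(subjects[f"b_pair_{FOCAL}_{j}"].to_numpy(), fd)
        for j in others
    }
)

report = smd_between_model(
    success_z,
    prepare_predictor(subjects[f"w_{FOCAL}"].to_numpy(), fd),
    pairs,
    age_z,
    n_boot=500,
    rng=np.random.default_rng(5),
)

cols = ["full_estimate", "inclusion_pct", "selected_estimate", "rmsd_ratio", "boot_median"]
print(report[cols].sort_values("inclusion_pct", ascending=False).round(2))
print("\nselected model:", report.attrs["selected"])

# The three planted candidates should top the inclusion-frequency column
# (>= 75% each, intercept forced at 100%); unselected candidates show a
# selected-model estimate of 0 and inclusion mostly below ~55%.
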