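# netseg

Resting-state brain-network **segregation** and its association with
**cognitive-reappraisal success**, as a tested, reproducible pipeline.

The package is for researchers who want to go from per-subject ROI time
series and realignment traces to network-level statistics: motion-based
frame censoring, nuisance cleaning, Fisher-z connectivity, within/between
network metrics, and a statistical layer with FDR correction and
bootstrap-stabilized model selection. A first-class synthetic-cohort
generator plants known effects so that every stage can be validated against
a recoverable ground truth.

## The science in brief

**Network segregation.** Given a parcellation of ROIs into networks, a
subject's ROI × ROI Pearson correlation matrix is Fisher-transformed
(z = atanh r) and negative values set to zero. For network *k*, with mean
within-network connectivity *W<sub>k</sub>* (all ROI pairs inside *k*) and
mean between-network connectivity *B<sub>k</sub>* (pairs from *k* to the
rest of the brain),

&nbsp;&nbsp;&nbsp;&nbsp;*S<sub>k</sub>* = (*W<sub>k</sub>* − *B<sub>k</sub>*) / *W<sub>k</sub>*.

Higher *S* means a more functionally distinct network.

**Frame censoring.** Framewise displacement
FD<sub>t</sub> = Σ|Δd| + 50 mm · Σ|Δθ| is low-pass filtered; frames with
FD > 0.2 mm are censored, retained islands under 5 contiguous frames and
runs under 50 frames are dropped, and the first 800 surviving frames
(13.3 min at TR = 1 s) are selected; subjects with fewer are excluded.

**Behavior.** Reappraisal success = mean negativity rating on
look-negative trials minus mean rating on reappraise (decrease) trials, on
a 1–5 scale.

**Models.** Per network: success<sub>z</sub> ~ *S* (FD-residualized,
standardized) + age<sub>z</sub> + age<sub>z</sub>², with
Benjamini–Hochberg correction of the 13 overall-model p-values. Follow-up
models split *W* and *B* with age interactions. For a focal network, its
12 pairwise between-connectivities plus within and age terms enter
augmented backward elimination (AIC-driven, with a change-in-estimate veto
protecting stable coefficients), and 1000 bootstrap resamples yield
inclusion frequencies, percentile intervals, RMSD ratios and conditional
bias per candidate.

## Worked example

```python
import pandas as pd
import netseg
from netseg import (CohortSpec, simulate_metrics_cohort, standardize,
                    prepare_predictor, segregation_models)

spec = CohortSpec(n_subjects=227, seed=4)          # plants 0.35 on the DMN
subjects, truth = simulate_metrics_cohort(spec)

success_z = standardize(subjects["success_true"].to_numpy())
age_z = standardize(subjects["age"].to_numpy())
fd = subjects["mean_fd"].to_numpy()
seg = pd.DataFrame({k: prepare_predictor(subjects[f"seg_{k}"].to_numpy(), fd)
                    for k in netseg.ANALYSIS_NETWORKS})

fits, summary = segregation_models(success_z, seg, age_z)
row = summary.loc["DefaultMode", ["beta_seg", "p_seg", "p_model_fdr"]]
print(row.astype(float).round(3))
print(list(summary.index[summary["significant"]]))
```

Output:

```
beta_seg       0.4
p_seg          0.0
p_model_fdr    0.0
Name: DefaultMode, dtype: float64
['DefaultMode']
```

The estimated standardized segregation coefficient (0.400 for this seed)
recovers the planted 0.35 within sampling error — averaged over hundreds
of replicate cohorts the estimate is unbiased within 0.05 — and the
default-mode network is the only one of 13 flagged after FDR correction;
the 12 unplanted networks behave as nulls.

The `examples/` directory holds one short script per capability
(simulation, censoring, connectivity metrics, association models,
selection stability); each prints the numbers it computes. A thin CLI
wraps the on-disk pipeline:

```bash
netseg run-all --data demo/data --out demo/out --seed 1 --n-subjects 40
```

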