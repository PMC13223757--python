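# Methods

This note documents the models implemented in `netseg`, the synthetic
cohort they are validated against, and the numerical and design choices a
maintainer would want to know about.

## Processing model

### Framewise displacement and censoring

FD at frame *t* is the sum of absolute backward differences of the six
rigid-body parameters, with the three rotations converted to arc length on
a 50 mm sphere (the conventional head radius): FD₀ = 0,
FDₜ = Σᵢ|Δtransᵢ| + 50·Σᵢ|Δrotᵢ|. Multiband acquisitions leak
respiration-band noise into the realignment estimates, so the FD trace is
low-pass filtered before thresholding — a zero-phase (forward–backward)
second-order Butterworth at 0.1 Hz by default (`fd_filter_hz`). The first
frame stays pinned at 0 after filtering (it is uncensorable by
definition), and filtered FD is clipped at 0.

Censoring semantics, all boundary cases inclusive on the "keep" side:

| rule | keep | drop |
|---|---|---|
| FD threshold (0.2 mm) | FD ≤ 0.2 | FD > 0.2 (strictly greater) |
| contiguity (5 frames) | islands of ≥ 5 retained frames | islands of ≤ 4 |
| run floor (50 frames) | runs retaining ≥ 50 | runs retaining ≤ 49 |
| selection (800 frames) | earliest 800 retained frames | everything after |

Subjects retaining fewer than 800 frames are flagged ineligible, never
silently processed. The mean-FD covariate is the mean of *filtered* FD
over **all acquired frames** (pre-censoring) — the cascade's inputs define
a subject's motion burden, not the frames that happen to survive it.
Censoring is evaluated on the filtered trace (the stated motivation for
filtering); the raw trace is retained for reporting.

### Cleaning

Per run, in fixed order: (1) demean and least-squares detrend each ROI;
(2) nuisance regression — global signal (ROI mean), optional CSF/WM
channels, and a 24-parameter motion block (6 parameters, their first
differences with the first row defined as 0, and the squares of those 12);
(3) linear interpolation across censored frames (edge frames take the
nearest retained value); (4) zero-phase second-order Butterworth band-pass,
0.009–0.08 Hz. The nuisance fit uses retained frames only, so motion
spikes cannot leverage the regression; residuals are computed for all
frames. Interpolated frames exist solely to stabilize the band-pass filter
and are re-censored before any correlation. At these band edges the
squared-magnitude (filtfilt) response is ≥ 0.99 at 0.04 Hz and ≤ 0.004 at
0.3 Hz, comfortably inside the ±5% passband / ≥ 90% stopband contract the
tests assert.

Interpolation is linear rather than spectral: the interpolated frames
never enter a statistic, so only filter stability matters. When CSF/WM
channels are absent the design is global + motion only, logged as such.

### Connectivity and segregation

The selected retained frames are concatenated across runs (the 800-frame
selection is defined over the concatenation, so per-run correlation would
change the estimand) and Pearson-correlated; z = atanh r with the diagonal
masked; negative z set to zero before averaging (global-signal regression
manufactures anticorrelations, and a signed mean would conflate them with
genuine coupling). Segregation: S = (W − B)/W, undefined (NaN, with a
warning) when W ≤ 0.

B comes in two flavours behind one switch: `brainwide` (default) averages
a network's ROIs against every other ROI including the unassigned ones —
the metric's definition is brain-wide; `labeled` restricts to the 13
analysis networks. Pairwise means B₍kj₎ always use labeled networks.
Unassigned ROIs never anchor a network mean of their own.

## Statistical layer

Response and age are z-scored (sample SD); the quadratic age regressor is
the square of standardized age, deliberately not orthogonalized against
the linear term — the model reports both raw polynomial terms in one
table. Each RSFC measure is residualized on mean FD cohort-wide before
modeling, then z-scored (`standardize_predictors`, default on): the
planted effects are defined in standardized units and only standardized
predictors return coefficients on that scale. OLS fitting, t/F statistics,
AIC and Benjamini–Hochberg adjustment are statsmodels; the BH adjustment
applies to the 13 overall-model p-values, per-coefficient p-values stay
unadjusted. A network is reported as showing a segregation effect only
when its overall model survives FDR **and** its segregation coefficient is
significant — every model shares the age terms, so the overall F alone
cannot attribute a fit to segregation.

### Augmented backward elimination

From the full candidate set, the drop that most lowers AIC is taken each
step; a drop is vetoed when it would change a remaining coefficient by
more than τ·|β| (τ = 0.05 by default, the conventional change-in-estimate
threshold; τ = ∞ reduces to plain backward-AIC, verified against an
exhaustive-drop reference). The veto is evaluated only for coefficients
distinguishable from zero (|β| > 2 SE): a relative change in an estimate
that is itself noise carries no confounding information, and applying the
rule to near-zero coefficients stalls elimination entirely (in experiments
it pushed null-candidate bootstrap inclusion to 80–90%, destroying the
selection's purpose). The intercept is passive and never dropped. AIC uses
the Gaussian-likelihood convention n·(log 2πσ̂² + 1) + 2k; it differs from
R's `AIC()` by a constant (R counts σ as a parameter), which cancels in
every comparison.

### Bootstrap stability

Subject-level resampling with replacement (default n = 1000; rank-deficient
resamples are redrawn and counted). Per candidate: bootstrap inclusion
frequency; unconditional median and 2.5/97.5 percentiles of the estimate
(0 when unselected); RMSD ratio = RMSD of bootstrap estimates around the
full-model estimate ÷ full-model SE (≈ 1 for stable candidates); relative
conditional bias = 100·(mean estimate given selection − full estimate)/full
estimate (large for weak candidates, whose estimates are only recorded
when they happen to look strong — selection bias made visible).

### Network contrast t-tests

Per-network one-sample t-tests of task-contrast values support two axes:
`subjects` (default; network-mean betas per subject, df = n_subjects − 1)
and `rois` (subject-mean betas per ROI, df = n_rois − 1). Both exist
because summaries of this design appear in the literature with either
convention; the subject axis is the inferentially standard one.

## Synthetic cohort

The generator emulates a lifespan cohort (default n = 227, ages uniform
6–80, TR = 1 s, 3 × 340-frame runs):

- **Connectivity.** Per network, true within-z ~ N(μₖ, 0.12²) with
  μₖ = 0.5 default; between-z ~ N(0.1, 0.03²), drawn independently per
  network so that (after motion is accounted for) one network's
  segregation carries no information about another's. ROI time series are
  zero-mean Gaussian with block-exchangeable correlation
  (tanh of the z targets; positive-definiteness checked by eigenvalue at
  construction), plus a shared global component (0.5 SD) and per-ROI
  linear drifts (0.3 SD) for the cleaning stage to remove. Unassigned
  ROIs correlate at the between level.
- **Motion confound.** Each subject carries a latent motion factor
  m ~ N(0,1). Mean FD = 0.11·exp(0.35·m) mm (lognormal, median ≈ 0.11).
  Motion contaminates the *measured* z values (negative loading on
  within, positive on between), with the loading solved analytically —
  linearizing S = 1 − b/w around the targets and accounting for the
  lognormal FD link — so that corr(measured segregation, mean FD) ≈ −0.40,
  the motion-confound strength of the emulated study. The behavioral
  effect acts on the *true* (motion-free) segregation: FD residualization
  therefore removes contamination rather than signal, which is what makes
  planted standardized coefficients recoverable and mirrors the physical
  reading of motion as a measurement artifact.
- **Behavior.** True success = 1.02 + 0.75·(β_lin·z(age) +
  β_quad·(z(age)² − 1) + Σβₖ·z(seg_true,k) + ε), ε ~ N(0, 0.905). The
  quadratic term is centred so the intercept is the cohort mean; the noise
  SD makes the standardized linear combination unit-variance at the
  default effect sizes, so the cohort mean/SD of success is 1.02/0.75 —
  the calibration of the emulated study. Defaults plant 0.35 on the
  default-mode network's segregation and β_quad = −0.17;
  `planted_beta_within` / `planted_beta_pair` plant effects on a focal
  network's within connectivity and pairwise between connectivity for
  selection experiments. Trials: 20 per condition, Gaussian around
  condition baselines (look-negative 3.5, neutral 1.5, decrease =
  3.5 − true success; trial SD 0.8), rounded half-up and clipped to 1–5.
  Discretization pulls the measured cohort mean down by ≈ 0.04; tests and
  calibration checks allow for it explicitly.
- **Motion traces.** Slow random walk (0.01 mm/frame SD; rotations scaled
  to equivalent arc length) plus one-frame displacement spikes whose
  per-subject rate scales with exp(0.6·m), tying realized FD to the same
  latent factor that contaminates connectivity.

What the generator does **not** emulate: hemodynamics, task-evoked
structure, spatial autocorrelation within networks, heavier-tailed motion,
or heterogeneous network sizes' interaction with SNR. Passing recovery
tests therefore demonstrate the pipeline's correctness and calibration
under a block-Gaussian world, not robustness to every property of real
BOLD data.

### Default parcellation

300 ROIs across 14 networks, 13 analyzed. The default-mode (65), dorsal
somatomotor (40) and dorsal attention (14) counts match the reference set;
the remaining counts are plausible allocations summing to 300. All code is
agnostic to ROI and network counts, and the test suite exercises reduced
parcellations throughout.

## Problem sizes

Validation experiments are sized to run on a laptop-class single core: the
closed-form segregation check uses 50 replicate subjects at 800 frames
(mean within ±0.02 of the analytic limit); planted-effect recovery uses
500 replicate cohorts of n = 227 in the test suite and 300 in the
acceptance script; selection stability uses 5 replicate cohorts at 200
bootstrap resamples in the tests (the pipeline default remains 1000). The
end-to-end on-disk demo (40 subjects, 3 × 340 frames, 300 ROIs) completes
in under a minute.

## Known limitations

- The change-in-estimate veto's 2-SE protection rule is a design choice on
  a spectrum; published descriptions of augmented elimination leave the
  guard unspecified, and other choices shift null-candidate inclusion
  frequencies by tens of points.
- Segregation is undefined for W ≤ 0 (possible after aggressive
  global-signal regression in small parcellations); affected subjects are
  flagged per network rather than dropped globally.
- The linear FD residualization removes the linear part of a lognormal
  confound; a small nonlinear remnant attenuates recovered coefficients by
  ≲ 2% at the default calibration.
- Rank-deficient bootstrap resamples are redrawn, which at very small n
  (tens of subjects with 15 candidates) makes inclusion frequencies
  optimistic; the pipeline warns and skips selection when n is too small
  to support the candidate set.
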