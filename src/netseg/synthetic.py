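"""Synthetic study generator with known ground truth.

Produces a full synthetic cohort — ages, ROI time series with planted
block-structured network covariance, realignment traces with motion spikes,
and trial-level behavioral ratings — so that every downstream stage of the
pipeline has a recoverable truth.

Generative model
----------------
Each subject carries a latent motion factor ``m ~ N(0, 1)``.

* **Connectivity.**  The *true* (motion-free) within-network Fisher z of
  network *k* is ``w_true_k = within_z[k] + within_z_sd * e_k`` with
  ``e_k ~ N(0, 1)``; between-network z is ``b_true = between_z +
  between_z_sd * u``.  The *measured* values add a motion-artifact loading:
  ``w_meas_k = w_true_k + a_w * m`` and ``b_meas = b_true + a_b * m`` with
  loadings chosen so that measured segregation correlates with mean FD at
  roughly ``fd_seg_corr``.  ROI time series are drawn from a zero-mean
  Gaussian with block-exchangeable correlation ``tanh(w_meas_k)`` within
  network *k* and ``tanh(b_meas)`` across networks, plus an additive shared
  global component and a per-ROI linear drift for the cleaning stage to
  remove.
* **Behavior.**  True reappraisal success is
  ``intercept + success_scale * (age_beta_linear * z(age) + age_beta_quad *
  (z(age)^2 - 1) + sum_k planted_beta_seg[k] * z(seg_true_k) + eps)`` with
  ``eps ~ N(0, noise_sd)``; the quadratic term is centred so the intercept
  is the cohort mean.  Trial ratings are Gaussian around condition baselines
  (Decrease = LookNegative baseline minus true success), rounded half-up to
  the integer 1-5 scale.
* **Motion.**  Realignment traces are a slow random walk plus sparse
  one-frame displacement spikes; a subject's spike rate scales with
  ``exp(0.6 * m)`` so realized mean FD tracks the latent motion factor.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .parcellation import analysis_networks, default_parcellation, write_parcellation

CONDITIONS = ("LookNegative", "LookNeutral", "Decrease")


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate the study conditions: n=227 subjects aged 6-80,
    TR=1.0 s, roughly 15 minutes of resting data split over runs, cohort
    mean reappraisal success 1.02 (SD 0.75), a quadratic age effect, a
    planted default-mode segregation effect of 0.35 (standardized), and a
    segregation-FD correlation of -0.40.
    """

    n_subjects: int = 227
    age_range: tuple[float, float] = (6.0, 80.0)
    tr: float = 1.0
    n_frames_per_run: int = 340
    n_runs: int = 3
    # Fisher-z connectivity targets (scalar within_z applies to every network)
    within_z: float | Mapping[str, float] = 0.5
    between_z: float = 0.1
    within_z_sd: float = 0.12
    between_z_sd: float = 0.03
    fd_seg_corr: float = -0.40
    # behavioral model (standardized effects)
    planted_beta_seg: Mapping[str, float] = field(
        default_factory=lambda: {"DefaultMode": 0.35}
    )
    #: standardized effect of a network's true within-network z on success
    planted_beta_within: Mapping[str, float] = field(default_factory=dict)
    #: standardized effect of the focal network's true between-z to the named
    #: network on success (keys are the partner-network names)
    planted_beta_pair: Mapping[str, float] = field(default_factory=dict)
    age_beta_linear: float = 0.0
    age_beta_quad: float = -0.17
    noise_sd: float = 0.905
    success_scale: float = 0.75
    success_intercept: float = 1.02
    baseline_look_negative: float = 3.5
    baseline_look_neutral: float = 1.5
    trial_sd: float = 0.8
    n_trials_per_condition: int = 20
    # motion model
    motion_spike_rate: float = 0.02
    motion_spike_scale: float = 1.0
    motion_walk_sd: float = 0.01
    fd_base: float = 0.11
    fd_log_sd: float = 0.35
    # artifacts injected into the time series for the cleaning stage
    global_amp: float = 0.5
    drift_amp: float = 0.3
    #: required total frames per subject (the eligibility floor the pipeline
    #: will apply); reduced cohorts for fast experiments may lower it
    frames_floor: int = 800
    seed: int = 0

    def within_z_map(self, networks) -> dict[str, float]:
        if isinstance(self.within_z, Mapping):
            missing = [n for n in networks if n not in self.within_z]
            if missing:
                raise ValueError(f"within_z missing networks: {missing}")
            return {n: float(self.within_z[n]) for n in networks}
        return {n: float(self.within_z) for n in networks}

    def validate(self, networks) -> None:
        if self.n_subjects < 1:
            raise ValueError("empty cohort: n_subjects must be >= 1")
        lo, hi = self.age_range
        if not (6.0 <= lo <= hi <= 80.0):
            raise ValueError("age_range must satisfy 6 <= min <= max <= 80")
        wz = self.within_z_map(networks)
        if any(w <= self.between_z for w in wz.values()):
            raise ValueError("within_z must exceed between_z for every network")
        if self.n_frames_per_run * self.n_runs < self.frames_floor:
            raise ValueError(
                f"total frames must allow a {self.frames_floor}-frame selection"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["within_z"] = (
            dict(self.within_z) if isinstance(self.within_z, Mapping) else self.within_z
        )
        d["planted_beta_seg"] = dict(self.planted_beta_seg)
        d["planted_beta_within"] = dict(self.planted_beta_within)
        d["planted_beta_pair"] = dict(self.planted_beta_pair)
        d["age_range"] = list(self.age_range)
        return d


@dataclass
class GroundTruth:
    """Truth record serialized alongside a generated dataset."""

    planted_beta_seg: dict[str, float]
    age_beta_linear: float
    age_beta_quad: float
    subjects: pd.DataFrame  # subject_id, age, seg_true_<k>, success_true, ...

    def to_json(self, path) -> None:
        payload = {
            "planted_beta_seg": self.planted_beta_seg,
            "age_beta_linear": self.age_beta_linear,
            "age_beta_quad": self.age_beta_quad,
            "subjects": json.loads(self.subjects.to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _rng(spec: CohortSpec, rng: np.random.Generator | None) -> np.random.Generator:
    return np.random.default_rng(spec.seed) if rng is None else rng


def sample_ages(spec: CohortSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Uniform ages within ``spec.age_range``, deterministic under the seed."""
    if spec.n_subjects < 1:
        raise ValueError("empty cohort: n_subjects must be >= 1")
    rng = _rng(spec, rng)
    lo, hi = spec.age_range
    return rng.uniform(lo, hi, size=spec.n_subjects)


def block_correlation(
    parc: pd.DataFrame,
    within_z: Mapping[str, float],
    between_z: float | Mapping[tuple[str, str], float],
) -> np.ndarray:
    """Block-exchangeable ROI correlation matrix from Fisher-z targets.

    Within-network correlation is ``tanh(within_z[k])`` and cross-network
    correlation ``tanh(between_z)`` (scalar or per unordered network pair).
    Raises if the resulting matrix is not positive definite.
    """
    labels = parc["network"].to_numpy()
    n = len(labels)
    if isinstance(between_z, Mapping):
        def bz(a, b):
            key = (a, b) if (a, b) in between_z else (b, a)
            return float(between_z[key])
    else:
        def bz(a, b):
            return float(between_z)

    networks = parc["network"].drop_duplicates().tolist()
    corr = np.empty((n, n))
    idx = {k: np.flatnonzero(labels == k) for k in networks}
    for a in networks:
        ra = np.tanh(within_z.get(a, 0.0)) if a in within_z else np.tanh(bz(a, a))
        corr[np.ix_(idx[a], idx[a])] = ra
        for b in networks:
            if a == b:
                continue
            corr[np.ix_(idx[a], idx[b])] = np.tanh(bz(a, b))
    np.fill_diagonal(corr, 1.0)
    eigmin = np.linalg.eigvalsh(corr).min()
    if eigmin <= 1e-8:
        raise ValueError(
            f"requested block correlation matrix is not positive definite "
            f"(min eigenvalue {eigmin:.3g}); reduce |between_z| or within_z spread"
        )
    return corr


def simulate_roi_timeseries(
    spec: CohortSpec,
    parc: pd.DataFrame,
    rng: np.random.Generator,
    within_z: Mapping[str, float] | None = None,
    between_z: float | None = None,
    global_amp: float | None = None,
    drift_amp: float | None = None,
) -> list[np.ndarray]:
    """Draw ``spec.n_runs`` runs of frames x ROIs block-correlated signal.

    Each run is zero-mean Gaussian with the block covariance implied by the
    Fisher-z targets, plus a shared global component (``global_amp`` SD units)
    and a per-ROI linear drift (slopes ~ N(0, drift_amp)).
    """
    if within_z is None:
        # Unassigned ROIs carry no network structure: they correlate at the
        # between level and need no within-z target
        wz = dict(spec.within_z_map(analysis_networks(parc)))
    else:
        wz = dict(within_z)
    bz = spec.between_z if between_z is None else between_z
    g_amp = spec.global_amp if global_amp is None else global_amp
    d_amp = spec.drift_amp if drift_amp is None else drift_amp

    corr = block_correlation(parc, wz, bz)
    chol = np.linalg.cholesky(corr)
    n_roi = len(parc)
    runs = []
    for _ in range(spec.n_runs):
        x = rng.standard_normal((spec.n_frames_per_run, n_roi)) @ chol.T
        if g_amp > 0:
            x += g_amp * rng.standard_normal((spec.n_frames_per_run, 1))
        if d_amp > 0:
            t = np.linspace(-1.0, 1.0, spec.n_frames_per_run)[:, None]
            x += t * (d_amp * rng.standard_normal(n_roi))[None, :]
        runs.append(x)
    return runs


def simulate_motion(
    spec: CohortSpec,
    n_frames: int,
    rng: np.random.Generator,
    spike_rate: float | None = None,
) -> np.ndarray:
    """Realignment trace, frames x 6: three rotations (rad) then three
    translations (mm).

    A slow random walk forms the baseline; sparse one-frame displacement
    spikes (probability ``spike_rate`` per frame, magnitude ~ |N(0,
    motion_spike_scale)| mm applied to a random translation) produce FD
    excursions at the spike frame and the return frame.
    """
    rate = spec.motion_spike_rate if spike_rate is None else spike_rate
    trace = np.zeros((n_frames, 6))
    if spec.motion_walk_sd > 0:
        steps = rng.standard_normal((n_frames, 6))
        steps[:, :3] *= spec.motion_walk_sd / 50.0  # rotations, rad (~mm at r=50)
        steps[:, 3:] *= spec.motion_walk_sd
        steps[0] = 0.0
        trace = np.cumsum(steps, axis=0)
    if rate > 0:
        spikes = rng.random(n_frames) < rate
        spikes[0] = False
        for t in np.flatnonzero(spikes):
            col = 3 + rng.integers(0, 3)
            trace[t, col] += rng.normal(0.0, spec.motion_spike_scale)
    return trace


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def simulate_behavior(
    spec: CohortSpec,
    subject_id: str,
    true_success: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Trial table (60 rows) for one subject.

    LookNegative ratings are drawn around ``baseline_look_negative``,
    LookNeutral around ``baseline_look_neutral``, and Decrease around
    ``baseline_look_negative - true_success``; each rating is rounded
    half-up and clipped to the integer 1-5 scale.
    """
    n = spec.n_trials_per_condition
    baselines = {
        "LookNegative": spec.baseline_look_negative,
        "LookNeutral": spec.baseline_look_neutral,
        "Decrease": spec.baseline_look_negative - true_success,
    }
    rows = []
    trial = 0
    for cond in CONDITIONS:
        latent = baselines[cond] + spec.trial_sd * rng.standard_normal(n)
        ratings = np.clip(_round_half_up(latent), 1, 5).astype(int)
        for r in ratings:
            trial += 1
            rows.append((subject_id, trial, cond, int(r)))
    return pd.DataFrame(rows, columns=["subject_id", "trial", "condition", "rating"])


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def simulate_metrics_cohort(
    spec: CohortSpec,
    rng: np.random.Generator | None = None,
    networks: tuple[str, ...] | None = None,
    focal: str = "SomatomotorDorsal",
) -> tuple[pd.DataFrame, dict]:
    """Subject-level statistical twin of the full pipeline output.

    Samples, for every subject, the true and measured within/between
    Fisher-z values per network (plus per-pair between z for the *focal*
    network), mean FD, and the true reappraisal success — the quantities
    the time-series pipeline would estimate — without simulating frames.

    Returns
    -------
    (subjects, truth)
        *subjects* has one row per subject with columns ``age``,
        ``mean_fd``, ``w_<k>``, ``b_<k>``, ``seg_<k>`` (measured),
        ``seg_true_<k>``, ``b_pair_<focal>_<j>``, and ``success_true``.
        *truth* records the planted coefficients and latent loadings.
    """
    if networks is None:
        networks = analysis_networks(default_parcellation())
    networks = list(networks)
    spec.validate(networks)
    rng = _rng(spec, rng)
    n = spec.n_subjects
    wz = spec.within_z_map(networks)

    # Motion-artifact loadings on the measured Fisher-z values: contamination
    # lowers within-network z and raises between-network z as motion grows.
    # The loading scale is solved so that, linearizing S = 1 - b/w around the
    # target within/between values and accounting for the lognormal FD link,
    # corr(measured segregation, mean FD) ~ fd_seg_corr.
    lam = abs(spec.fd_seg_corr)
    w0 = float(np.mean(list(wz.values())))
    gw, gb = spec.between_z / w0**2, 1.0 / w0  # |dS/dw|, |dS/db|
    noise_var = (gw * spec.within_z_sd) ** 2 + (gb * spec.between_z_sd) ** 2
    rho_fd_m = spec.fd_log_sd / np.sqrt(np.expm1(spec.fd_log_sd**2))
    rho_m = min(lam / rho_fd_m, 0.99)
    c_m = rho_m * np.sqrt(noise_var / (1.0 - rho_m**2))
    scale = c_m / (gw * spec.within_z_sd + gb * spec.between_z_sd)
    a_w = -scale * spec.within_z_sd
    a_b = +scale * spec.between_z_sd

    ages = sample_ages(spec, rng)
    m = rng.standard_normal(n)
    mean_fd = spec.fd_base * np.exp(spec.fd_log_sd * m)

    data: dict[str, np.ndarray] = {"age": ages, "mean_fd": mean_fd, "motion_factor": m}
    b_floor = 0.01
    seg_true, w_true_all, pair_true = {}, {}, {}
    # within and between deviations are drawn independently per network, so
    # that (once motion contamination is removed) one network's segregation
    # carries no information about another's
    for k in networks:
        e = rng.standard_normal(n)
        w_true = wz[k] + spec.within_z_sd * e
        b_true = np.maximum(
            spec.between_z + spec.between_z_sd * rng.standard_normal(n), b_floor
        )
        w_true = np.maximum(w_true, b_true + 0.05)
        w_meas = w_true + a_w * m
        b_meas = np.clip(b_true + a_b * m, b_floor, None)
        w_meas = np.maximum(w_meas, b_meas + 0.05)
        w_true_all[k] = w_true
        data[f"w_{k}"] = w_meas
        data[f"b_{k}"] = b_meas
        data[f"seg_{k}"] = (w_meas - b_meas) / w_meas
        seg_true[k] = (w_true - b_true) / w_true
        data[f"seg_true_{k}"] = seg_true[k]
    if focal in networks:
        others = [j for j in networks if j != focal]
        for j in others:
            b_pair = spec.between_z + spec.between_z_sd * rng.standard_normal(n)
            b_pair = np.maximum(b_pair, b_floor)
            pair_true[j] = b_pair
            data[f"b_pair_{focal}_{j}"] = np.clip(b_pair + a_b * m, b_floor, None)

    z_age = _zscore(ages)
    lin = spec.age_beta_linear * z_age + spec.age_beta_quad * (z_age**2 - 1.0)
    for k, beta in dict(spec.planted_beta_seg).items():
        if k not in networks:
            raise ValueError(f"planted_beta_seg names unknown network {k!r}")
        lin = lin + beta * _zscore(seg_true[k])
    for k, beta in dict(spec.planted_beta_within).items():
        if k not in networks:
            raise ValueError(f"planted_beta_within names unknown network {k!r}")
        lin = lin + beta * _zscore(w_true_all[k])
    for j, beta in dict(spec.planted_beta_pair).items():
        if j not in pair_true:
            raise ValueError(
                f"planted_beta_pair names {j!r}, not a partner of focal {focal!r}"
            )
        lin = lin + beta * _zscore(pair_true[j])
    eps = spec.noise_sd * rng.standard_normal(n)
    success_true = spec.success_intercept + spec.success_scale * (lin + eps)
    data["success_true"] = success_true

    subjects = pd.DataFrame(data)
    subjects.insert(0, "subject_id", [f"sub-{i + 1:03d}" for i in range(n)])
    truth = {
        "planted_beta_seg": dict(spec.planted_beta_seg),
        "planted_beta_within": dict(spec.planted_beta_within),
        "planted_beta_pair": dict(spec.planted_beta_pair),
        "age_beta_linear": spec.age_beta_linear,
        "age_beta_quad": spec.age_beta_quad,
        "artifact_loading_within": a_w,
        "artifact_loading_between": a_b,
        "networks": networks,
        "focal": focal,
    }
    return subjects, truth


def generate_cohort(
    spec: CohortSpec,
    outdir,
    parc: pd.DataFrame | None = None,
) -> GroundTruth:
    """Write a complete synthetic dataset and its ground truth to *outdir*.

    Layout: ``parcellation.tsv``, ``covariates.csv``, ``behavior.csv``,
    ``ground_truth.json``, ``manifest.json``, and per subject
    ``subjects/<id>/run-XX_timeseries.tsv`` plus ``run-XX_motion.txt``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if parc is None:
        parc = default_parcellation()
    networks = analysis_networks(parc)
    spec.validate(networks)

    root = np.random.default_rng(spec.seed)
    subjects, truth = simulate_metrics_cohort(spec, root, networks=tuple(networks))
    write_parcellation(parc, outdir / "parcellation.tsv")

    sexes = np.where(root.random(spec.n_subjects) < 138 / 227, "F", "M")
    covariates = pd.DataFrame(
        {"subject_id": subjects["subject_id"], "age": subjects["age"], "sex": sexes}
    )
    covariates.to_csv(outdir / "covariates.csv", index=False, float_format="%.6f")

    behavior_frames = []
    ss = np.random.SeedSequence(spec.seed)
    child_seeds = ss.spawn(spec.n_subjects)
    roi_header = "\t".join(parc["roi_id"])
    for i, row in subjects.iterrows():
        sid = row["subject_id"]
        srng = np.random.default_rng(child_seeds[i])
        subdir = outdir / "subjects" / sid
        subdir.mkdir(parents=True, exist_ok=True)
        wz_i = {k: row[f"w_{k}"] for k in networks}
        b_i = float(np.mean([row[f"b_{k}"] for k in networks]))
        runs = simulate_roi_timeseries(
            spec, parc, srng, within_z=wz_i, between_z=b_i
        )
        spike_rate = min(spec.motion_spike_rate * np.exp(0.6 * row["motion_factor"]), 0.3)
        for r, run in enumerate(runs, start=1):
            np.savetxt(
                subdir / f"run-{r:02d}_timeseries.tsv",
                run,
                delimiter="\t",
                fmt="%.6f",
                header=roi_header,
                comments="",
            )
            motion = simulate_motion(spec, spec.n_frames_per_run, srng, spike_rate)
            np.savetxt(
                subdir / f"run-{r:02d}_motion.txt",
                motion,
                fmt="%.8f",
                header="columns: rot_x rot_y rot_z (rad), trans_x trans_y trans_z (mm)",
            )
        behavior_frames.append(
            simulate_behavior(spec, sid, row["success_true"], srng)
        )
    pd.concat(behavior_frames, ignore_index=True).to_csv(
        outdir / "behavior.csv", index=False
    )

    keep = ["subject_id", "age", "success_true"] + [
        f"seg_true_{k}" for k in networks
    ]
    planted = {k: float(dict(spec.planted_beta_seg).get(k, 0.0)) for k in networks}
    gt = GroundTruth(
        planted_beta_seg=planted,
        age_beta_linear=spec.age_beta_linear,
        age_beta_quad=spec.age_beta_quad,
        subjects=subjects[keep].copy(),
    )
    gt.to_json(outdir / "ground_truth.json")

    spec_json = json.dumps(spec.to_dict(), sort_keys=True)
    manifest = {
        "seed": spec.seed,
        "n_subjects": spec.n_subjects,
        "subjects": subjects["subject_id"].tolist(),
        "spec": spec.to_dict(),
        "spec_sha256": hashlib.sha256(spec_json.encode()).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return gt
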