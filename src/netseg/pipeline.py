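"""End-to-end pipeline stages over an on-disk dataset.

Stages (each a plain function; the CLI wraps them): simulate, preprocess
(censoring + cleaning), connectivity (matrices + segregation metrics),
analyze (association models + selection stability), report (figures).
Every stage writes a manifest carrying the config, seed and package
version — reruns with the same seed are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behavior import reappraisal_success, standardize
from .censoring import censor_cascade
from .cleaning import clean_run
from .connectivity import subject_metrics, write_matrix
from .models import (
    bh_adjust,
    prepare_predictor,
    segregation_models,
    smd_between_model,
    within_between_models,
)
from .parcellation import analysis_networks, read_parcellation
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Numeric settings of the processing and modeling stages."""

    data_dir: str = "data"
    out_dir: str = "out"
    tr: float = 1.0
    head_radius_mm: float = 50.0
    fd_filter_hz: float = 0.1
    fd_threshold_mm: float = 0.2
    min_contig: int = 5
    min_run_frames: int = 50
    n_frames: int = 800
    band: tuple[float, float] = (0.009, 0.08)
    between_mode: str = "brainwide"  # or "labeled"
    focal_network: str = "SomatomotorDorsal"
    tau: float = 0.05
    n_boot: int = 1000
    quad_interactions: bool = False
    standardize_predictors: bool = True
    seed: int = 0

    def validate(self) -> None:
        if min(self.fd_threshold_mm, self.min_contig, self.min_run_frames, self.n_frames) <= 0:
            raise ValueError("censoring thresholds must be positive")
        lo, hi = self.band
        if not lo < hi:
            raise ValueError("band low must be below band high")
        if self.between_mode not in ("brainwide", "labeled"):
            raise ValueError("between_mode must be 'brainwide' or 'labeled'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "band" in raw:
            raw["band"] = tuple(raw["band"])
        return cls(**raw)


def _write_manifest(cfg: PipelineConfig, outdir: Path, stage: str, extra: dict | None = None):
    payload = {
        "stage": stage,
        "config": cfg.to_dict(),
        "seed": cfg.seed,
        "version": __version__,
    }
    if extra:
        payload.update(extra)
    blob = json.dumps(payload, indent=1, sort_keys=True)
    payload["manifest_sha256"] = hashlib.sha256(blob.encode()).hexdigest()
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def participant_flow(
    returned: int = 311,
    no_resting: int = 7,
    behavioral: int = 21,
    motion: int = 56,
) -> dict:
    """Participant exclusion-cascade arithmetic.

    Of the participants who returned for scanning, some could not complete
    the resting scans, some were excluded for behavioral-response issues,
    and some for inadequate resting data after censoring.  Retention is the
    final n as a percentage of the pool with usable resting + behavioral
    data (returned - no_resting - behavioral).
    """
    pool = returned - no_resting - behavioral
    final_n = pool - motion
    return {
        "returned": returned,
        "pool": pool,
        "final_n": final_n,
        "retention_pct": round(100.0 * final_n / pool, 1),
    }


def frames_to_minutes(n_frames: int, tr: float) -> float:
    """Scan minutes represented by *n_frames* at repetition time *tr* (s)."""
    return round(n_frames * tr / 60.0, 1)


# ---------------------------------------------------------------------------
# stages


def simulate_stage(cfg: PipelineConfig, spec: CohortSpec, parc=None):
    """Generate the synthetic dataset into ``cfg.data_dir``."""
    cfg.validate()
    data_dir = Path(cfg.data_dir)
    gt = generate_cohort(spec, data_dir, parc=parc)
    _write_manifest(cfg, data_dir, "simulate", {"n_subjects": spec.n_subjects})
    return gt


def _subject_dirs(data_dir: Path) -> list[Path]:
    return sorted((data_dir / "subjects").iterdir())


def _load_runs(subdir: Path) -> tuple[list[np.ndarray], list[np.ndarray]]:
    runs, motions = [], []
    for ts in sorted(subdir.glob("run-*_timeseries.tsv")):
        runs.append(np.loadtxt(ts, delimiter="\t", skiprows=1))
        motions.append(np.loadtxt(subdir / ts.name.replace("timeseries", "motion").replace(".tsv", ".txt")))
    return runs, motions


def preprocess_stage(cfg: PipelineConfig) -> pd.DataFrame:
    """Censoring cascade + cleaning for every subject.

    Writes per-subject cleaned runs, censor masks and a summary table;
    subjects under the frame floor appear in ``exclusions.json``.
    """
    cfg.validate()
    data_dir, out_dir = Path(cfg.data_dir), Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, exclusions = [], []
    for subdir in _subject_dirs(data_dir):
        sid = subdir.name
        runs, motions = _load_runs(subdir)
        plan, fd_traces, mean_fd = censor_cascade(
            motions,
            tr=cfg.tr,
            head_radius=cfg.head_radius_mm,
            fd_filter_hz=cfg.fd_filter_hz,
            threshold_mm=cfg.fd_threshold_mm,
            min_contig=cfg.min_contig,
            min_run_frames=cfg.min_run_frames,
            n_select=cfg.n_frames,
        )
        rows.append(
            {
                "subject_id": sid,
                "eligible": plan.eligible,
                "mean_fd": mean_fd,
                "n_retained": plan.n_retained_pre_selection,
                "n_selected": plan.n_selected,
            }
        )
        sub_out = out_dir / "preprocessed" / sid
        sub_out.mkdir(parents=True, exist_ok=True)
        np.savetxt(
            sub_out / "censor_masks.tsv",
            np.column_stack([m.astype(int) for m in plan.run_masks]),
            fmt="%d",
            delimiter="\t",
            header="\t".join(f"run-{i + 1:02d}" for i in range(len(plan.run_masks))),
            comments="",
        )
        if not plan.eligible:
            exclusions.append({"subject_id": sid, "n_retained": plan.n_retained_pre_selection})
            logger.warning("%s ineligible: %d retained frames", sid, plan.n_retained_pre_selection)
            continue
        for i, (run, motion, mask) in enumerate(zip(runs, motions, plan.run_masks), start=1):
            cleaned = clean_run(run, motion, mask, tr=cfg.tr, band=cfg.band)
            np.savetxt(sub_out / f"run-{i:02d}_cleaned.tsv", cleaned, delimiter="\t", fmt="%.6f")
    summary = pd.DataFrame(rows)
    summary.to_csv(out_dir / "preprocess_summary.csv", index=False, float_format="%.6f")
    (out_dir / "exclusions.json").write_text(json.dumps(exclusions, indent=1))
    _write_manifest(cfg, out_dir, "preprocess", {"n_excluded": len(exclusions)})
    return summary


def connectivity_stage(cfg: PipelineConfig) -> pd.DataFrame:
    """Correlation matrices and network metrics for eligible subjects."""
    cfg.validate()
    data_dir, out_dir = Path(cfg.data_dir), Path(cfg.out_dir)
    parc = read_parcellation(data_dir / "parcellation.tsv")
    summary = pd.read_csv(out_dir / "preprocess_summary.csv")
    nets = analysis_networks(parc)
    metric_rows, pair_rows = [], []
    conn_dir = out_dir / "connectivity"
    conn_dir.mkdir(parents=True, exist_ok=True)
    from .censoring import CensorPlan  # local import to avoid cycle at module load

    for _, rec in summary[summary["eligible"]].iterrows():
        sid = rec["subject_id"]
        sub_out = out_dir / "preprocessed" / sid
        masks_tab = np.loadtxt(sub_out / "censor_masks.tsv", skiprows=1, delimiter="\t")
        masks = [masks_tab[:, i].astype(bool) for i in range(masks_tab.shape[1])]
        runs = [
            np.loadtxt(f, delimiter="\t")
            for f in sorted(sub_out.glob("run-*_cleaned.tsv"))
        ]
        plan = CensorPlan(
            run_masks=masks,
            eligible=True,
            n_selected=int(sum(m.sum() for m in masks)),
            n_retained_pre_selection=int(sum(m.sum() for m in masks)),
            retained_per_run=[int(m.sum()) for m in masks],
        )
        metrics, z = subject_metrics(runs, plan, parc, between=cfg.between_mode)
        write_matrix(z, parc, conn_dir / f"{sid}_fisher_z.csv")
        row = {"subject_id": sid, "mean_fd": rec["mean_fd"]}
        for k in nets:
            row[f"W_{k}"] = metrics.per_network.loc[k, "W"]
            row[f"B_{k}"] = metrics.per_network.loc[k, "B"]
            row[f"S_{k}"] = metrics.per_network.loc[k, "S"]
        metric_rows.append(row)
        for j in nets:
            if j != cfg.focal_network:
                pair_rows.append(
                    {
                        "subject_id": sid,
                        "network": j,
                        "B_pair": metrics.pairwise.loc[cfg.focal_network, j],
                    }
                )
    metrics_df = pd.DataFrame(metric_rows)
    metrics_df.to_csv(out_dir / "network_metrics.csv", index=False, float_format="%.8f")
    pd.DataFrame(pair_rows).to_csv(out_dir / "focal_between_pairs.csv", index=False, float_format="%.8f")
    _write_manifest(cfg, out_dir, "connectivity", {"n_subjects": len(metric_rows)})
    return metrics_df


def analyze_stage(cfg: PipelineConfig) -> dict:
    """Behavior scoring, per-network segregation models with FDR,
    within/between models for FDR-significant networks, and the focal
    pairwise selection model with bootstrap stability."""
    cfg.validate()
    data_dir, out_dir = Path(cfg.data_dir), Path(cfg.out_dir)
    rng = np.random.default_rng(cfg.seed)
    metrics = pd.read_csv(out_dir / "network_metrics.csv")
    pairs = pd.read_csv(out_dir / "focal_between_pairs.csv")
    trials = pd.read_csv(data_dir / "behavior.csv")
    covars = pd.read_csv(data_dir / "covariates.csv")

    scored = reappraisal_success(trials)
    scored.to_csv(out_dir / "behavior_scored.csv", index=False, float_format="%.6f")
    keep = scored.loc[~scored["excluded"], ["subject_id", "success"]]
    df = metrics.merge(keep, on="subject_id").merge(
        covars[["subject_id", "age"]], on="subject_id"
    )
    n = len(df)
    if n < 10:
        logger.warning("only %d analyzable subjects; model tables will be unstable", n)
    success_z = standardize(df["success"].to_numpy())
    age_z = standardize(df["age"].to_numpy())
    fd = df["mean_fd"].to_numpy()
    nets = [c[2:] for c in df.columns if c.startswith("S_")]

    seg_resid = pd.DataFrame(
        {
            k: prepare_predictor(df[f"S_{k}"].to_numpy(), fd, cfg.standardize_predictors)
            for k in nets
        }
    )
    fits, seg_summary = segregation_models(success_z, seg_resid, age_z)
    seg_summary.to_csv(out_dir / "segregation_models.csv", float_format="%.6f")

    significant = seg_summary.index[seg_summary["significant"]].tolist()
    wb_tables = {}
    for net in significant:
        fit = within_between_models(
            success_z,
            prepare_predictor(df[f"W_{net}"].to_numpy(), fd, cfg.standardize_predictors),
            prepare_predictor(df[f"B_{net}"].to_numpy(), fd, cfg.standardize_predictors),
            age_z,
            quad_interactions=cfg.quad_interactions,
        )
        wb_tables[net] = fit.table()
        fit.table().to_csv(out_dir / f"within_between_{net}.csv", float_format="%.6f")

    focal = cfg.focal_network
    pair_wide = pairs.pivot(index="subject_id", columns="network", values="B_pair")
    pair_wide = pair_wide.loc[df["subject_id"]].reset_index(drop=True)
    n_candidates = pair_wide.shape[1] + 4  # within, age, age_sq, const
    report = None
    if n <= n_candidates + 5:
        logger.warning(
            "skipping focal pairwise selection: %d subjects cannot support %d candidates",
            n,
            n_candidates,
        )
    else:
        between_pairs = pd.DataFrame(
            {
                j: prepare_predictor(pair_wide[j].to_numpy(), fd, cfg.standardize_predictors)
                for j in pair_wide.columns
            }
        )
        report = smd_between_model(
            success_z,
            prepare_predictor(df[f"W_{focal}"].to_numpy(), fd, cfg.standardize_predictors),
            between_pairs,
            age_z,
            tau=cfg.tau,
            n_boot=cfg.n_boot,
            rng=rng,
        )
        report.to_csv(out_dir / "focal_selection_report.csv", float_format="%.6f")
    _write_manifest(
        cfg,
        out_dir,
        "analyze",
        {
            "n_subjects": n,
            "significant_networks": significant,
            "selected": report.attrs["selected"] if report is not None else None,
        },
    )
    return {
        "segregation": seg_summary,
        "within_between": wb_tables,
        "selection_report": report,
        "n_subjects": n,
    }


def report_stage(cfg: PipelineConfig) -> list[str]:
    """Summary figures: success vs age with quadratic fit, segregation vs
    success partials for significant networks, and (when ground truth is
    present) a recovery table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg.validate()
    data_dir, out_dir = Path(cfg.data_dir), Path(cfg.out_dir)
    fig_dir = out_dir / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    written = []

    scored = pd.read_csv(out_dir / "behavior_scored.csv")
    covars = pd.read_csv(data_dir / "covariates.csv")
    df = scored.merge(covars[["subject_id", "age"]], on="subject_id")
    df = df[~df["excluded"].astype(bool)]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df["age"], df["success"], s=12, alpha=0.6)
    coef = np.polyfit(df["age"], df["success"], 2)
    grid = np.linspace(df["age"].min(), df["age"].max(), 100)
    ax.plot(grid, np.polyval(coef, grid), color="crimson")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("reappraisal success")
    fig.tight_layout()
    path = fig_dir / "success_vs_age.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(str(path))

    seg = pd.read_csv(out_dir / "segregation_models.csv", index_col=0)
    metrics = pd.read_csv(out_dir / "network_metrics.csv")
    merged = metrics.merge(df[["subject_id", "success"]], on="subject_id")
    for net in seg.index[seg["significant"].astype(bool)]:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(merged[f"S_{net}"], merged["success"], s=12, alpha=0.6)
        ax.set_xlabel(f"{net} segregation")
        ax.set_ylabel("reappraisal success")
        fig.tight_layout()
        path = fig_dir / f"segregation_{net}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))

    truth_path = data_dir / "ground_truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        rows = [
            {"network": k, "planted_beta": v, "estimated_beta": seg.loc[k, "beta_seg"] if k in seg.index else np.nan}
            for k, v in truth["planted_beta_seg"].items()
        ]
        rec = pd.DataFrame(rows)
        rec_path = out_dir / "recovery_table.csv"
        rec.to_csv(rec_path, index=False, float_format="%.4f")
        written.append(str(rec_path))
    _write_manifest(cfg, out_dir, "report", {"outputs": written})
    return written


def run_all(cfg: PipelineConfig, spec: CohortSpec) -> dict:
    simulate_stage(cfg, spec)
    preprocess_stage(cfg)
    connectivity_stage(cfg)
    results = analyze_stage(cfg)
    report_stage(cfg)
    return results
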