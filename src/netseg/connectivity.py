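"""ROI correlation matrices, Fisher z, and network segregation metrics.

Segregation of network *k* is ``S_k = (W_k - B_k) / W_k`` where ``W_k`` is
the mean Fisher-z connectivity over within-network ROI pairs and ``B_k`` the
mean over pairs of network-k ROIs with ROIs outside the network.  Negative z
values are set to zero before averaging (global-signal regression can induce
spurious anticorrelations); unthresholded positive values are kept as-is.

``B_k`` comes in two flavours, selected by ``between``:

* ``"brainwide"`` (default): all ROIs outside network *k*, including
  Unassigned ROIs;
* ``"labeled"``: only ROIs belonging to the 13 analysis networks.

Network-pair means ``B_kj`` always use labeled networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .censoring import CensorPlan
from .parcellation import UNASSIGNED, analysis_networks


@dataclass
class NetworkMetrics:
    """Per-network within/between means and segregation for one subject."""

    per_network: pd.DataFrame  # index network; columns W, B, S
    pairwise: pd.DataFrame  # symmetric network x network B_kj

    @property
    def segregation(self) -> pd.Series:
        return self.per_network["S"]


def correlation_matrix(runs: list[np.ndarray], plan: CensorPlan) -> np.ndarray:
    """Pearson correlation over the selected retained frames of all runs.

    Frames are concatenated across runs in acquisition order; only the
    plan's retained frames contribute.  Raises for zero-variance ROIs.
    """
    if len(runs) != len(plan.run_masks):
        raise ValueError("number of runs does not match censor plan")
    if not plan.eligible:
        raise ValueError("subject is ineligible (insufficient retained frames)")
    pieces = []
    for run, mask in zip(runs, plan.run_masks):
        run = np.asarray(run, dtype=float)
        if run.shape[0] != mask.size:
            raise ValueError("run length does not match censor mask")
        if mask.any():
            pieces.append(run[mask])
    data = np.vstack(pieces)
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance ROI column(s) at index {dead.tolist()}")
    r = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r_matrix: np.ndarray) -> np.ndarray:
    """Fisher z-transform (atanh) of a correlation matrix; the diagonal is
    masked to NaN so it can never enter an average."""
    r = np.asarray(r_matrix, dtype=float)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        raise ValueError("off-diagonal |r| >= 1; cannot Fisher-transform")
    z = np.arctanh(np.where(off, r, 0.0))
    np.fill_diagonal(z, np.nan)
    return z


def threshold_negatives(z_matrix: np.ndarray) -> np.ndarray:
    """Set negative entries to zero; positives (and the NaN diagonal) pass
    through untouched."""
    z = np.asarray(z_matrix, dtype=float)
    return np.where(z < 0, 0.0, z)


def segregation(w: float, b: float) -> float:
    """``S = (W - B) / W``; NaN (with a warning) when W <= 0."""
    if not w > 0:
        warnings.warn("within-network mean W <= 0; segregation undefined for this network")
        return float("nan")
    return (w - b) / w


def within_between(
    z_matrix: np.ndarray,
    parc: pd.DataFrame,
    between: str = "brainwide",
) -> NetworkMetrics:
    """Within-network, between-network and pairwise mean z, plus segregation.

    *parc* rows must align with the matrix order.  Unassigned ROIs never
    anchor a network mean but are included in brain-wide ``B_k`` (default).
    """
    if between not in ("brainwide", "labeled"):
        raise ValueError("between must be 'brainwide' or 'labeled'")
    z = np.asarray(z_matrix, dtype=float)
    labels = parc["network"].to_numpy()
    if z.shape[0] != z.shape[1] or z.shape[0] != labels.size:
        raise ValueError("matrix shape does not match parcellation")
    if not np.allclose(z, z.T, equal_nan=True, atol=1e-12):
        raise ValueError("connectivity matrix is not symmetric")
    nets = analysis_networks(parc)
    idx = {k: np.flatnonzero(labels == k) for k in nets}
    labeled = np.isin(labels, nets)

    w_vals, b_vals, s_vals = {}, {}, {}
    pair = pd.DataFrame(np.nan, index=nets, columns=nets)
    for k in nets:
        ik = idx[k]
        if ik.size < 2:
            raise ValueError(f"network {k!r} has fewer than 2 ROIs; W undefined")
        sub = z[np.ix_(ik, ik)]
        iu = np.triu_indices(ik.size, k=1)
        w_vals[k] = float(sub[iu].mean())
        outside = np.ones(labels.size, dtype=bool)
        outside[ik] = False
        if between == "labeled":
            outside &= labeled
        b_vals[k] = float(z[np.ix_(ik, np.flatnonzero(outside))].mean())
        s_vals[k] = segregation(w_vals[k], b_vals[k])
        for j in nets:
            if j == k:
                continue
            pair.loc[k, j] = float(z[np.ix_(ik, idx[j])].mean())
    per_network = pd.DataFrame({"W": w_vals, "B": b_vals, "S": s_vals}).loc[nets]
    return NetworkMetrics(per_network=per_network, pairwise=pair)


def subject_metrics(
    runs: list[np.ndarray],
    plan: CensorPlan,
    parc: pd.DataFrame,
    between: str = "brainwide",
) -> tuple[NetworkMetrics, np.ndarray]:
    """Correlate, transform, threshold and summarize one subject.

    Returns the network metrics and the (unthresholded) Fisher-z matrix.
    """
    r = correlation_matrix(runs, plan)
    z = fisher_z(r)
    metrics = within_between(threshold_negatives(z), parc, between=between)
    return metrics, z


def write_matrix(matrix: np.ndarray, parc: pd.DataFrame, path) -> None:
    """Write an ROI x ROI matrix as CSV with ROI-id header row/column."""
    pd.DataFrame(matrix, index=parc["roi_id"], columns=parc["roi_id"]).to_csv(path)


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=float), df.index.tolist()
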