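"""Denoising of ROI time series.

Order of operations per run, fixed: demean/detrend, nuisance regression
(global signal, optional CSF/WM channels, and a 24-parameter motion block),
linear interpolation over censored frames, zero-phase band-pass
(0.009-0.08 Hz).  Interpolated frames exist only to stabilize the band-pass
filter; the censor mask is re-applied before any connectivity estimate.

The nuisance fit uses retained frames only, so high-motion frames cannot
leverage the regression; residuals are then computed for all frames.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal


def demean_detrend(run: np.ndarray) -> np.ndarray:
    """Remove per-ROI mean and least-squares linear trend."""
    x = np.asarray(run, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 frames to detrend")
    t = np.arange(n, dtype=float)
    design = np.column_stack([np.ones(n), t - t.mean()])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def build_nuisance(
    run: np.ndarray,
    realignment: np.ndarray,
    csf: np.ndarray | None = None,
    wm: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the nuisance design for one run.

    Global signal (ROI mean), optional CSF/WM channels, six rigid-body
    motion parameters, their first differences (first row 0), and the
    squares of those 12 — a 24-column motion block.  All columns demeaned.
    Returns (frames x k design, column names).
    """
    x = np.asarray(run, dtype=float)
    r = np.asarray(realignment, dtype=float)
    if r.shape[0] != x.shape[0]:
        raise ValueError("run and realignment must have the same number of frames")
    cols = [x.mean(axis=1)]
    names = ["global"]
    for name, sig in (("csf", csf), ("wm", wm)):
        if sig is not None:
            sig = np.asarray(sig, dtype=float)
            if sig.shape[0] != x.shape[0]:
                raise ValueError(f"{name} channel length mismatch")
            cols.append(sig)
            names.append(name)
    motion = r
    diffs = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    block = np.column_stack([motion, diffs])
    block = np.column_stack([block, block**2])  # Volterra squares of the 12
    design = np.column_stack(cols + [block])
    names += (
        [f"mot{i}" for i in range(6)]
        + [f"dmot{i}" for i in range(6)]
        + [f"mot{i}_sq" for i in range(6)]
        + [f"dmot{i}_sq" for i in range(6)]
    )
    design = design - design.mean(axis=0, keepdims=True)
    return design, names


def regress_nuisance(
    run: np.ndarray,
    nuisance: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Residualize each ROI column on the nuisance design plus intercept.

    The fit uses retained (mask-true) frames only; residuals are computed
    for all frames.  A rank-deficient design triggers a warning and a
    minimum-norm solution (equivalent to dropping dependent columns).
    """
    x = np.asarray(run, dtype=float)
    nuis = np.asarray(nuisance, dtype=float)
    n = x.shape[0]
    design = np.column_stack([np.ones(n), nuis])
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() <= design.shape[1]:
        warnings.warn("fewer retained frames than nuisance regressors; fit is saturated")
    beta, _, rank, _ = np.linalg.lstsq(design[mask], x[mask], rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            f"nuisance design is rank deficient (rank {rank} < {design.shape[1]}); "
            "dependent columns effectively dropped"
        )
    return x - design @ beta


def interpolate_censored(run: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Linearly interpolate censored frames between nearest retained
    neighbors; leading/trailing censored frames take the nearest retained
    value."""
    x = np.asarray(run, dtype=float).copy()
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        return x
    if not mask.any():
        raise ValueError("cannot interpolate a fully censored run (no anchor frames)")
    t = np.arange(x.shape[0])
    good = np.flatnonzero(mask)
    bad = np.flatnonzero(~mask)
    for j in range(x.shape[1]):
        x[bad, j] = np.interp(t[bad], good, x[good, j])
    return x


def bandpass(
    run: np.ndarray,
    tr: float,
    low: float = 0.009,
    high: float = 0.08,
) -> np.ndarray:
    """Zero-phase second-order Butterworth band-pass along time."""
    nyquist = 0.5 / tr
    if not (0.0 < low < high < nyquist):
        raise ValueError(f"invalid band ({low}, {high}) Hz for TR={tr}")
    x = np.asarray(run, dtype=float)
    sos = signal.butter(2, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def clean_run(
    run: np.ndarray,
    realignment: np.ndarray,
    mask: np.ndarray,
    tr: float,
    band: tuple[float, float] = (0.009, 0.08),
    csf: np.ndarray | None = None,
    wm: np.ndarray | None = None,
) -> np.ndarray:
    """Full per-run cleaning: detrend, nuisance regression (fit on retained
    frames), interpolation over censored frames, band-pass.

    The returned array still contains the interpolated frames; callers must
    re-apply *mask* before computing correlations.
    """
    x = demean_detrend(run)
    nuis, _ = build_nuisance(x, realignment, csf=csf, wm=wm)
    x = regress_nuisance(x, nuis, mask=mask)
    x = interpolate_censored(x, mask)
    return bandpass(x, tr=tr, low=band[0], high=band[1])
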