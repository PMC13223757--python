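"""Framewise displacement and the frame-censoring cascade.

Censoring proceeds in a fixed order per subject:

1. framewise displacement (FD) from the six realignment parameters,
2. zero-phase low-pass filtering of FD (multiband FD traces carry
   respiration-band noise),
3. censoring of frames with filtered FD strictly greater than the threshold
   (default 0.2 mm),
4. removal of retained segments shorter than five contiguous frames,
5. removal of runs with fewer than 50 retained frames,
6. selection of the first 800 retained frames in acquisition order; subjects
   with fewer than 800 retained frames are flagged ineligible.

Retained-frame counts can only shrink through the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

#: Assumed head radius (mm) converting rotations to displacements.
HEAD_RADIUS_MM = 50.0


@dataclass(frozen=True)
class FdTrace:
    """Per-frame framewise displacement (mm) for one run."""

    fd: np.ndarray
    tr: float
    filtered: bool = False

    def __post_init__(self):
        fd = np.asarray(self.fd, dtype=float)
        object.__setattr__(self, "fd", fd)
        if fd.ndim != 1 or fd.size == 0:
            raise ValueError("FD trace must be a non-empty 1-D array")

    def __len__(self) -> int:
        return self.fd.size


@dataclass
class CensorPlan:
    """Boolean retain-masks per run after the full cascade."""

    run_masks: list[np.ndarray]
    eligible: bool
    n_selected: int
    n_retained_pre_selection: int
    retained_per_run: list[int]

    @property
    def concat_mask(self) -> np.ndarray:
        return np.concatenate(self.run_masks)


def compute_fd(realignment: np.ndarray, tr: float, head_radius: float = HEAD_RADIUS_MM) -> FdTrace:
    """FD from a frames x 6 realignment trace (rotations rad, translations mm).

    ``FD[t] = sum_i |delta trans_i| + sum_i head_radius * |delta rot_i|``,
    with ``FD[0] = 0``.
    """
    r = np.asarray(realignment, dtype=float)
    if r.ndim != 2 or r.shape[1] != 6:
        raise ValueError(f"realignment must be frames x 6, got shape {r.shape}")
    if not np.all(np.isfinite(r)):
        raise ValueError("realignment trace contains non-finite values")
    d = np.abs(np.diff(r, axis=0))
    fd = np.concatenate([[0.0], head_radius * d[:, :3].sum(axis=1) + d[:, 3:].sum(axis=1)])
    return FdTrace(fd=fd, tr=tr, filtered=False)


def filter_fd(trace: FdTrace, cutoff_hz: float = 0.1) -> FdTrace:
    """Zero-phase second-order Butterworth low-pass of an FD trace.

    DC is preserved exactly; the first frame stays pinned at 0 (it is never
    censorable by definition).  Raises if the cutoff reaches the Nyquist
    frequency for the trace's TR.
    """
    nyquist = 0.5 / trace.tr
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz at TR={trace.tr}")
    if cutoff_hz <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(2, cutoff_hz, btype="lowpass", fs=1.0 / trace.tr, output="sos")
    padlen = min(len(trace) - 1, 3 * 6)
    fd = signal.sosfiltfilt(sos, trace.fd, padlen=padlen)
    fd = np.clip(fd, 0.0, None)
    fd[0] = 0.0
    return replace(trace, fd=fd, filtered=True)


def censor_frames(trace: FdTrace, threshold_mm: float = 0.2) -> np.ndarray:
    """Retain-mask: frames with FD strictly greater than the threshold are
    censored; FD exactly at the threshold is retained."""
    return trace.fd <= threshold_mm


def enforce_contiguity(mask: np.ndarray, min_contig: int = 5) -> np.ndarray:
    """Censor retained segments shorter than *min_contig* contiguous frames."""
    mask = np.asarray(mask, dtype=bool).copy()
    n = mask.size
    t = 0
    while t < n:
        if mask[t]:
            start = t
            while t < n and mask[t]:
                t += 1
            if t - start < min_contig:
                mask[start:t] = False
        else:
            t += 1
    return mask


def drop_short_runs(masks: list[np.ndarray], min_frames: int = 50) -> list[np.ndarray]:
    """Fully censor runs retaining fewer than *min_frames* frames."""
    out = []
    for m in masks:
        m = np.asarray(m, dtype=bool)
        out.append(m.copy() if m.sum() >= min_frames else np.zeros_like(m))
    return out


def select_first_n(masks: list[np.ndarray], n: int = 800) -> CensorPlan:
    """Keep the first *n* retained frames in acquisition order across runs.

    Subjects retaining fewer than *n* frames are flagged ineligible (their
    masks are left as-is, never silently processed downstream).
    """
    masks = [np.asarray(m, dtype=bool).copy() for m in masks]
    total = int(sum(m.sum() for m in masks))
    if total < n:
        return CensorPlan(
            run_masks=masks,
            eligible=False,
            n_selected=0,
            n_retained_pre_selection=total,
            retained_per_run=[int(m.sum()) for m in masks],
        )
    remaining = n
    for m in masks:
        retained_idx = np.flatnonzero(m)
        if remaining <= 0:
            m[:] = False
        elif retained_idx.size > remaining:
            m[retained_idx[remaining:]] = False
            remaining = 0
        else:
            remaining -= retained_idx.size
    return CensorPlan(
        run_masks=masks,
        eligible=True,
        n_selected=n,
        n_retained_pre_selection=total,
        retained_per_run=[int(m.sum()) for m in masks],
    )


def censor_cascade(
    realignments: list[np.ndarray],
    tr: float,
    head_radius: float = HEAD_RADIUS_MM,
    fd_filter_hz: float = 0.1,
    threshold_mm: float = 0.2,
    min_contig: int = 5,
    min_run_frames: int = 50,
    n_select: int = 800,
) -> tuple[CensorPlan, list[FdTrace], float]:
    """Full censoring cascade for one subject.

    Returns the censor plan, the *filtered* FD traces, and the mean-FD
    covariate (mean filtered FD over all acquired frames, pre-censoring).
    """
    filtered = [
        filter_fd(compute_fd(r, tr=tr, head_radius=head_radius), fd_filter_hz)
        for r in realignments
    ]
    masks = [enforce_contiguity(censor_frames(f, threshold_mm), min_contig) for f in filtered]
    masks = drop_short_runs(masks, min_run_frames)
    plan = select_first_n(masks, n_select)
    mean_fd = float(np.concatenate([f.fd for f in filtered]).mean())
    return plan, filtered, mean_fd
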