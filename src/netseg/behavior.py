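"""Scoring of the emotion-regulation task.

Reappraisal success is the difference in mean negativity ratings (1-5)
between natural viewing of negative images (LookNegative) and reappraisal
(Decrease) trials; positive values mean effective downregulation.
LookNeutral trials never enter the score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REQUIRED_CONDITIONS = ("LookNegative", "Decrease")


def reappraisal_success(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject condition means and reappraisal success.

    Parameters
    ----------
    trials
        Long table with columns ``subject_id``, ``condition``, ``rating``.
        Missing ratings (NaN) are dropped with a logged count.

    Returns
    -------
    pandas.DataFrame
        One row per subject: mean rating per condition, trials used,
        ``success`` = mean(LookNegative) - mean(Decrease), and an
        ``excluded`` flag for subjects with zero usable trials in a
        required condition (mirrors behavioral-exclusion handling).
    """
    for col in ("subject_id", "condition", "rating"):
        if col not in trials.columns:
            raise ValueError(f"trials table is missing column {col!r}")
    n_missing = int(trials["rating"].isna().sum())
    if n_missing:
        logger.info("dropping %d trials with missing ratings", n_missing)
    usable = trials.dropna(subset=["rating"])

    rows = []
    for sid, grp in usable.groupby("subject_id", sort=False):
        means = grp.groupby("condition")["rating"].mean()
        counts = grp.groupby("condition")["rating"].size()
        rec = {"subject_id": sid}
        for cond in ("LookNegative", "LookNeutral", "Decrease"):
            rec[f"mean_{cond}"] = float(means.get(cond, np.nan))
            rec[f"n_{cond}"] = int(counts.get(cond, 0))
        excluded = any(rec[f"n_{c}"] == 0 for c in REQUIRED_CONDITIONS)
        rec["excluded"] = excluded
        rec["success"] = (
            np.nan if excluded else rec["mean_LookNegative"] - rec["mean_Decrease"]
        )
        if excluded:
            logger.warning("subject %s excluded: no usable trials in a required condition", sid)
        rows.append(rec)
    return pd.DataFrame(rows)


def standardize(values) -> np.ndarray:
    """z-score with sample SD (ddof=1); errors on n < 2 or zero variance.

    The quadratic age regressor is the square of this z-score.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("standardize requires a 1-D vector with n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (x - x.mean()) / sd
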