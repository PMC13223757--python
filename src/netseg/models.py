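"""Association models: FD residualization, per-network segregation models
with BH-FDR, within/between interaction models, AIC-driven augmented
backward elimination with bootstrap stability, and network-level contrast
t-tests.

Ordinary least squares, F/t statistics, AIC and the Benjamini-Hochberg
adjustment go through statsmodels; the selection machinery (augmented
backward elimination with a change-in-estimate veto, and the bootstrap
stability report) is implemented here with a fast numpy OLS in the inner
loop (its AIC matches statsmodels' Gaussian-likelihood AIC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .parcellation import analysis_networks

logger = logging.getLogger(__name__)


@dataclass
class ModelFit:
    """Summary of one OLS fit, in the layout of a standard model table."""

    response: str
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fvalue: float
    f_pvalue: float
    rsquared: float
    aic: float
    df_resid: int
    nobs: int
    conf_int: pd.DataFrame = field(repr=False, default=None)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"B": self.params, "SE": self.bse, "t": self.tvalues, "p": self.pvalues}
        )


def fit_linear_model(y, X: pd.DataFrame, response: str = "y", add_const: bool = True) -> ModelFit:
    """OLS with two-sided t p-values, overall F vs intercept-only, and AIC.

    Raises on rank-deficient designs, listing the collinear columns.
    """
    X = pd.DataFrame(X).astype(float)
    if add_const and "const" not in X.columns:
        X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        if X.shape[0] < X.shape[1]:
            raise ValueError(
                f"rank-deficient design: {X.shape[0]} rows < {X.shape[1]} columns"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.abs(np.corrcoef(X.to_numpy(), rowvar=False))
        np.fill_diagonal(corr, 0.0)
        suspects = [
            X.columns[i]
            for i in range(X.shape[1])
            if np.nanmax(corr[i]) > 1 - 1e-10 or X.iloc[:, i].std() == 0
        ]
        raise ValueError(f"rank-deficient design; collinear columns include {suspects}")
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return ModelFit(
        response=response,
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        fvalue=float(res.fvalue),
        f_pvalue=float(res.f_pvalue),
        rsquared=float(res.rsquared),
        aic=float(res.aic),
        df_resid=int(res.df_resid),
        nobs=int(res.nobs),
        conf_int=res.conf_int(),
    )


def residualize_on_fd(values, mean_fd) -> np.ndarray:
    """Residuals of an intercept + mean-FD least-squares fit.

    Applied cohort-wide to every RSFC measure before modeling, removing
    linear motion contamination; residuals are orthogonal to mean FD.
    """
    y = np.asarray(values, dtype=float)
    fd = np.asarray(mean_fd, dtype=float)
    if y.shape != fd.shape or y.ndim != 1:
        raise ValueError("values and mean_fd must be aligned 1-D vectors")
    if y.size < 3:
        raise ValueError("need at least 3 subjects to residualize")
    design = np.column_stack([np.ones_like(fd), fd])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / x.std(ddof=1)


def prepare_predictor(values, mean_fd, standardize: bool = True) -> np.ndarray:
    """FD-residualize an RSFC measure and (by default) z-score the residuals."""
    resid = residualize_on_fd(values, mean_fd)
    return _zscore(resid) if standardize else resid


def segregation_models(
    success_z: np.ndarray,
    seg_resid: pd.DataFrame,
    age_z: np.ndarray,
) -> tuple[dict[str, ModelFit], pd.DataFrame]:
    """Separate models ``success_z ~ segregation + age + age^2`` per network.

    *seg_resid* holds one FD-residualized segregation column per network.
    Overall-model F p-values are BH-adjusted across the networks; the
    per-coefficient p-values are reported unadjusted.
    """
    fits: dict[str, ModelFit] = {}
    rows = []
    for net in seg_resid.columns:
        X = pd.DataFrame(
            {
                "segregation": np.asarray(seg_resid[net], dtype=float),
                "age": age_z,
                "age_sq": age_z**2,
            }
        )
        fit = fit_linear_model(success_z, X, response="success")
        fits[net] = fit
        rows.append(
            {
                "network": net,
                "beta_seg": fit.params["segregation"],
                "se_seg": fit.bse["segregation"],
                "t_seg": fit.tvalues["segregation"],
                "p_seg": fit.pvalues["segregation"],
                "F": fit.fvalue,
                "p_model": fit.f_pvalue,
                "R2": fit.rsquared,
            }
        )
    summary = pd.DataFrame(rows).set_index("network")
    summary["p_model_fdr"] = bh_adjust(summary["p_model"].to_numpy())
    # a network "shows a segregation effect" when its overall model survives
    # FDR *and* the segregation coefficient is itself significant (every model
    # shares the age terms, so the overall F alone cannot attribute the fit
    # to segregation)
    summary["significant"] = (summary["p_model_fdr"] < 0.05) & (summary["p_seg"] < 0.05)
    return fits, summary


def within_between_models(
    success_z: np.ndarray,
    within_resid: np.ndarray,
    between_resid: np.ndarray,
    age_z: np.ndarray,
    quad_interactions: bool = False,
) -> ModelFit:
    """``success_z ~ between + within + age + age^2 + between*age + within*age``.

    Interactions use the linear age term; ``quad_interactions`` adds the
    quadratic-age interactions as well.
    """
    w = np.asarray(within_resid, dtype=float)
    b = np.asarray(between_resid, dtype=float)
    X = {
        "between": b,
        "within": w,
        "age": age_z,
        "age_sq": age_z**2,
        "between_x_age": b * age_z,
        "within_x_age": w * age_z,
    }
    if quad_interactions:
        X["between_x_age_sq"] = b * age_z**2
        X["within_x_age_sq"] = w * age_z**2
    return fit_linear_model(success_z, pd.DataFrame(X), response="success")


# ---------------------------------------------------------------------------
# augmented backward elimination + bootstrap stability


def _ols_quick(y: np.ndarray, X: np.ndarray):
    """(beta, se, aic) via normal equations; AIC matches the Gaussian
    log-likelihood convention aic = n*(log(2*pi*ssr/n) + 1) + 2k."""
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    aic = n * (np.log(2.0 * np.pi * ssr / n) + 1.0) + 2.0 * k
    dof = n - k
    sigma2 = ssr / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    return beta, se, aic, rank


@dataclass
class ABEResult:
    selected: list[str]
    aic: float
    full_aic: float
    fit: ModelFit
    steps: list[dict]


def abe_select(
    y,
    X: pd.DataFrame,
    passive: tuple[str, ...] = ("const",),
    tau: float = 0.05,
) -> ABEResult:
    """Augmented backward elimination driven by AIC.

    At each step the candidate whose removal most decreases AIC is dropped,
    unless the drop changes a remaining candidate's coefficient by more
    than ``tau`` times its magnitude — the change-in-estimate veto that
    "augments" plain backward elimination and protects confounders.  The
    veto is evaluated only for remaining coefficients distinguishable from
    zero (|beta| > 2 SE): a relative change in an estimate that is itself
    noise carries no confounding information and would otherwise stall
    elimination.  Passive terms (the intercept) are never dropped.
    ``tau = inf`` reduces the procedure to plain AIC backward elimination.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    missing = [p for p in passive if p not in X.columns]
    if missing:
        raise ValueError(f"passive terms not in design: {missing}")
    cols = list(X.columns)
    arr = {c: X[c].to_numpy() for c in cols}

    def fit_cols(cs):
        return _ols_quick(y, np.column_stack([arr[c] for c in cs]))

    current = list(cols)
    beta, se, aic, _ = fit_cols(current)
    full_aic = aic
    steps: list[dict] = []
    while True:
        active = [c for c in current if c not in passive]
        if not active:
            break
        trials = []
        for c in active:
            reduced = [x for x in current if x != c]
            b_r, se_r, aic_r, _ = fit_cols(reduced)
            trials.append((aic_r, c, reduced, b_r, se_r))
        trials.sort(key=lambda t: t[0])
        dropped = None
        for aic_r, c, reduced, b_r, se_r in trials:
            if aic_r >= aic:
                break  # no remaining drop lowers AIC
            if np.isfinite(tau):
                vetoed = False
                for j, name in enumerate(reduced):
                    if name in passive:
                        continue
                    i_before = current.index(name)
                    if abs(beta[i_before]) <= 2.0 * se[i_before]:
                        continue  # estimate indistinguishable from zero
                    change = abs(b_r[j] - beta[i_before])
                    if change > tau * abs(beta[i_before]):
                        vetoed = True
                        break
                if vetoed:
                    steps.append({"action": "veto", "candidate": c, "aic": aic_r})
                    continue
            dropped = (c, reduced, b_r, se_r, aic_r)
            break
        if dropped is None:
            break
        c, current, beta, se, aic = (
            dropped[0],
            dropped[1],
            dropped[2],
            dropped[3],
            dropped[4],
        )
        steps.append({"action": "drop", "candidate": c, "aic": aic})
    fit = fit_linear_model(y, X[current], response="y", add_const=False)
    return ABEResult(selected=current, aic=aic, full_aic=full_aic, fit=fit, steps=steps)


def bootstrap_stability(
    y,
    X: pd.DataFrame,
    passive: tuple[str, ...] = ("const",),
    tau: float = 0.05,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Subject-level bootstrap of the ABE selection (stability report).

    For each resample with replacement, selection is rerun and the
    coefficient of every candidate recorded (0 when not selected).  The
    report gives, per candidate: full-model estimate and SE, bootstrap
    inclusion frequency (%), selected-model estimate and SE on the original
    data, RMSD ratio (RMSD of bootstrap estimates around the full-model
    estimate, divided by the full-model SE), relative conditional bias
    (percent difference of the mean estimate conditional on selection from
    the full-model estimate), and the bootstrap median and 2.5th/97.5th
    percentiles.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    cols = list(X.columns)
    Xa = X.to_numpy()

    full_fit = fit_linear_model(y, X, add_const=False)
    original = abe_select(y, X, passive=passive, tau=tau)

    est = np.zeros((n_boot, len(cols)))
    included = np.zeros((n_boot, len(cols)), dtype=bool)
    n_redrawn = 0
    for b in range(n_boot):
        for _ in range(100):
            idx = rng.integers(0, n, n)
            Xb = Xa[idx]
            if np.linalg.matrix_rank(Xb) == len(cols):
                break
            n_redrawn += 1
        else:
            raise RuntimeError("could not draw a full-rank bootstrap resample")
        res = abe_select(y[idx], pd.DataFrame(Xb, columns=cols), passive=passive, tau=tau)
        for name, val in zip(res.selected, res.fit.params):
            j = cols.index(name)
            est[b, j] = val
            included[b, j] = True
    if n_redrawn:
        logger.info("redrew %d rank-deficient bootstrap resamples", n_redrawn)

    rows = []
    for j, name in enumerate(cols):
        full_b = float(full_fit.params[name])
        full_se = float(full_fit.bse[name])
        inc = included[:, j]
        sel = name in original.selected
        rmsd = float(np.sqrt(np.mean((est[:, j] - full_b) ** 2)))
        if inc.any() and abs(full_b) > 0:
            rel_bias = 100.0 * (est[inc, j].mean() - full_b) / full_b
        else:
            rel_bias = np.nan
        rows.append(
            {
                "candidate": name,
                "full_estimate": full_b,
                "full_se": full_se,
                "inclusion_pct": 100.0 * inc.mean(),
                "selected_estimate": float(original.fit.params[name]) if sel else 0.0,
                "selected_se": float(original.fit.bse[name]) if sel else 0.0,
                "rmsd_ratio": rmsd / full_se if full_se > 0 else np.nan,
                "rel_cond_bias_pct": rel_bias,
                "boot_median": float(np.median(est[:, j])),
                "boot_p2_5": float(np.percentile(est[:, j], 2.5)),
                "boot_p97_5": float(np.percentile(est[:, j], 97.5)),
            }
        )
    report = pd.DataFrame(rows).set_index("candidate")
    report.attrs["selected"] = original.selected
    report.attrs["aic_selected"] = original.aic
    report.attrs["aic_full"] = original.full_aic
    return report


def smd_between_model(
    success_z: np.ndarray,
    within_resid: np.ndarray,
    between_pairs: pd.DataFrame,
    age_z: np.ndarray,
    tau: float = 0.05,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Pairwise between-network model for a focal network.

    Candidates: the focal network's within connectivity, its between
    connectivity to each other network (columns of *between_pairs*), and
    linear + quadratic age; the intercept is passive.  Runs ABE plus the
    bootstrap stability report.
    """
    X = {"const": np.ones_like(age_z), "within": np.asarray(within_resid, dtype=float)}
    for col in between_pairs.columns:
        X[f"b_{col}"] = np.asarray(between_pairs[col], dtype=float)
    X["age"] = age_z
    X["age_sq"] = age_z**2
    return bootstrap_stability(
        success_z, pd.DataFrame(X), passive=("const",), tau=tau, n_boot=n_boot, rng=rng
    )


def network_contrast_ttest(
    roi_betas: pd.DataFrame,
    parc: pd.DataFrame,
    networks: list[str] | None = None,
    axis: str = "subjects",
) -> pd.DataFrame:
    """One-sample t-tests of task-contrast values per network.

    *roi_betas* is subjects x ROIs (columns = ROI ids).  With
    ``axis="subjects"`` (default) the ROI betas are averaged within each
    network per subject and tested across subjects (df = n_subjects - 1);
    with ``axis="rois"`` the subject-mean beta per ROI is tested across the
    network's ROIs (df = n_rois - 1).
    """
    if axis not in ("subjects", "rois"):
        raise ValueError("axis must be 'subjects' or 'rois'")
    if networks is None:
        networks = analysis_networks(parc)
    rows = []
    for net in networks:
        rois = parc.loc[parc["network"] == net, "roi_id"]
        missing = [r for r in rois if r not in roi_betas.columns]
        if missing:
            raise ValueError(f"ROI betas missing columns for {net}: {missing[:3]}...")
        block = roi_betas[list(rois)].to_numpy(dtype=float)
        values = block.mean(axis=1) if axis == "subjects" else block.mean(axis=0)
        if np.allclose(values.std(ddof=1), 0.0) and np.allclose(values.mean(), 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_1samp(values, 0.0)
        rows.append({"network": net, "t": float(t), "df": values.size - 1, "p": float(p)})
    return pd.DataFrame(rows).set_index("network")
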