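"""Naive reference implementations used as independent oracles.

Everything here is deliberately written frame-by-frame / pair-by-pair with
plain loops, independent of the package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np


def cascade_reference(fd_runs, threshold, min_contig, min_run, n_select):
    """Frame-by-frame censoring cascade over a list of FD arrays.

    Returns the list of boolean retain masks and the eligibility flag.
    """
    masks = []
    for fd in fd_runs:
        mask = [v <= threshold for v in fd]
        # remove retained islands shorter than min_contig
        i = 0
        while i < len(mask):
            if mask[i]:
                j = i
                while j < len(mask) and mask[j]:
                    j += 1
                if j - i < min_contig:
                    for t in range(i, j):
                        mask[t] = False
                i = j
            else:
                i += 1
        if sum(mask) < min_run:
            mask = [False] * len(mask)
        masks.append(mask)
    total = sum(sum(m) for m in masks)
    if total < n_select:
        return [np.array(m) for m in masks], False
    seen = 0
    out = []
    for mask in masks:
        new = []
        for v in mask:
            if v and seen < n_select:
                new.append(True)
                seen += 1
            else:
                new.append(False)
        out.append(np.array(new))
    return out, True


def correlation_reference(data):
    """Pairwise-loop Pearson correlation of columns."""
    n, p = data.shape
    r = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            x = data[:, i] - data[:, i].mean()
            y = data[:, j] - data[:, j].mean()
            r[i, j] = r[j, i] = (x @ y) / np.sqrt((x @ x) * (y @ y))
    return r


def within_between_reference(z, labels, analysis_nets, brainwide=True):
    """Double-loop within/between/pairwise means and segregation."""
    p = len(labels)
    W, B, S, pair = {}, {}, {}, {}
    for k in analysis_nets:
        within_vals, between_vals = [], []
        for i in range(p):
            if labels[i] != k:
                continue
            for j in range(p):
                if j == i:
                    continue
                if labels[j] == k:
                    if j > i:
                        within_vals.append(z[i, j])
                elif brainwide or labels[j] in analysis_nets:
                    between_vals.append(z[i, j])
        W[k] = np.mean(within_vals)
        B[k] = np.mean(between_vals)
        S[k] = (W[k] - B[k]) / W[k]
        for k2 in analysis_nets:
            if k2 == k:
                continue
            vals = [
                z[i, j]
                for i in range(p)
                if labels[i] == k
                for j in range(p)
                if labels[j] == k2
            ]
            pair[(k, k2)] = np.mean(vals)
    return W, B, S, pair


def ols_reference(y, X):
    """Normal-equations OLS: beta, residual SS, R^2, AIC (Gaussian)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ssr = float(resid @ resid)
    n, k = X.shape
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1 - ssr / tss
    aic = n * (np.log(2 * np.pi * ssr / n) + 1) + 2 * k
    return beta, ssr, r2, aic


def bh_reference(pvals):
    """Step-up Benjamini-Hochberg adjusted p-values, by the definition."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


def backward_aic_reference(y, X_cols: dict, passive: tuple):
    """Greedy backward elimination on AIC with exhaustive single-drop search
    at every step (no veto).  Returns (selected names, aic)."""
    current = list(X_cols)

    def aic_of(cols):
        X = np.column_stack([X_cols[c] for c in cols])
        return ols_reference(y, X)[3]

    aic = aic_of(current)
    while True:
        active = [c for c in current if c not in passive]
        if not active:
            return current, aic
        options = [(aic_of([c for c in current if c != d]), d) for d in active]
        best_aic, best_drop = min(options)
        if best_aic >= aic:
            return current, aic
        current = [c for c in current if c != best_drop]
        aic = best_aic
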