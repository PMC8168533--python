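"""Independent oracles used by the test suite.

Each oracle computes the same quantity as a package routine by a different
route — explicit numerical integration, exhaustive enumeration, or a
separately coded optimizer — and never shares code with the path it checks.
"""
from __future__ import annotations

import numpy as np


def euler_delta_m(f, att, t1_tissue, m0, t_end, tau, alpha, t1_blood, h=0.1):
    """ΔM by forward-Euler integration of the tracer mass balance.

    dΔM/dt = delivery(t) − ΔM/T1app, with delivery equal to
    2·α·m0·(f/6000)·exp(−att/t1_blood) while att ≤ t < att+τ and zero
    otherwise.  Vectorized over points; each point is read out at its own
    t_end (rounded to the step grid).
    """
    f = np.atleast_1d(np.asarray(f, float))
    att = np.atleast_1d(np.asarray(att, float))
    t1 = np.atleast_1d(np.asarray(t1_tissue, float))
    m0 = np.broadcast_to(np.asarray(m0, float), f.shape)
    t_end = np.atleast_1d(np.asarray(t_end, float))
    rate = 2.0 * alpha * m0 * (f / 6000.0) * np.exp(-att / t1_blood)
    n_target = np.round(t_end / h).astype(int)
    n_max = int(n_target.max())
    m = np.zeros_like(f)
    out = np.zeros_like(f)
    out = np.where(n_target == 0, m, out)
    for n in range(n_max):
        t = n * h
        delivering = (t >= att) & (t < att + tau)
        m = m + h * (np.where(delivering, rate, 0.0) - m / t1)
        out = np.where(n_target == n + 1, m, out)
    return out


def pair_count_auc(scores, labels):
    """AUC as the tie-corrected concordant-pair proportion, by enumeration."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def anova_mean_squares(matrix):
    """Two-way ANOVA mean squares by explicit cell-by-cell accumulation."""
    m = np.asarray(matrix, float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    ss_rows = 0.0
    for i in range(n):
        ss_rows += k * (m[i].mean() - grand) ** 2
    ss_cols = 0.0
    for j in range(k):
        ss_cols += n * (m[:, j].mean() - grand) ** 2
    ss_err = 0.0
    for i in range(n):
        for j in range(k):
            resid = m[i, j] - m[i].mean() - m[:, j].mean() + grand
            ss_err += resid**2
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


def icc21_from_mean_squares(ms_rows, ms_cols, ms_err, n, k):
    return (ms_rows - ms_err) / (
        ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    )


def newton_logistic(X, y, tol=1e-12, max_iter=200):
    """Plain Newton-Raphson on the analytic logistic log-likelihood.

    X must already include its intercept column.  Returns the coefficient
    vector at the maximum-likelihood solution.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(-(X @ beta)))
        grad = X.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            break
        hess = -(X * (p * (1 - p))[:, None]).T @ X
        beta = beta - np.linalg.solve(hess, grad)
    return beta
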