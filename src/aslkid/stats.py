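"""Reproducibility and diagnostic statistics.

The statistical layer of the study design: a paired t-test compares two
scan sessions, a two-way random-effects ICC quantifies test-retest
agreement, Student's t compares MVI+ and MVI− perfusion, ROC/AUC with a
Youden-index cutoff summarizes diagnostic power, a confusion matrix yields
sensitivity/specificity/PPV/NPV with Wilson confidence intervals, and
logistic regression identifies independent predictors as odds ratios.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_curve
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "paired_t",
    "icc_two_way",
    "ICCResult",
    "student_t",
    "roc_auc",
    "ROCResult",
    "ConfusionMatrix",
    "diagnostic_indices",
    "DiagnosticIndices",
    "logistic_fit",
    "LogisticModel",
]


def paired_t(x, y) -> Tuple[float, float]:
    """Paired t-test of two equal-length measurement vectors.

    t = mean(d)/(sd(d)/sqrt(n)) on the differences d = x − y with df = n−1;
    two-sided p.  Zero-variance differences leave the statistic undefined
    and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    d = x - y
    if np.std(d, ddof=1) == 0.0:
        raise ValueError("differences have zero variance; paired t undefined")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), float(res.pvalue)


def student_t(group_a, group_b, equal_var: bool = True) -> Tuple[float, float]:
    """Two-sample t-test, pooled-variance by default (Welch via flag).

    df = n_a + n_b − 2 for the pooled form; two-sided p.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        raise ValueError("zero pooled variance; t undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_subjects: int
    n_sessions: int
    form: str = "ICC(2,1)"


def icc_two_way(matrix, form: str = "ICC(2,1)") -> ICCResult:
    """Intraclass correlation from a complete subjects × sessions matrix.

    Default is the two-way random-effects, absolute-agreement,
    single-measurement form — the standard for test-retest of a
    quantitative measurement::

        ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)·(MS_C − MS_E))

    with MS_R the between-subjects, MS_C the between-sessions and MS_E the
    residual mean square of the two-way decomposition.  ``form="ICC(3,1)"``
    gives the consistency version, which drops the session-variance term.
    Identical sessions give exactly 1; a constant matrix raises.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects × sessions)")
    n, k = m.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 sessions")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix has missing or non-finite cells")
    grand = m.mean()
    if np.all(m == m.flat[0]):
        raise ValueError("constant matrix: all mean squares zero, ICC undefined")
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    if form == "ICC(2,1)":
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    elif form == "ICC(3,1)":
        denom = ms_r + (k - 1) * ms_e
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    icc = (ms_r - ms_e) / denom
    return ICCResult(
        icc=float(icc),
        ms_rows=ms_r,
        ms_cols=ms_c,
        ms_error=ms_e,
        n_subjects=n,
        n_sessions=k,
        form=form,
    )


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sens_curve: np.ndarray
    one_minus_spec_curve: np.ndarray
    auc: float
    youden_cutoff: float


def roc_auc(scores, labels) -> ROCResult:
    """Empirical ROC curve, trapezoidal AUC and Youden-index cutoff.

    A case is called positive when its score is at or above the threshold;
    the curve visits every unique score, ties contribute half to the AUC
    (so the trapezoidal area equals the tie-corrected concordant-pair
    probability).  The Youden cutoff maximizes sens + spec − 1, breaking
    ties toward the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    # sklearn reports +inf as the first threshold (nothing called positive)
    thr = thr.copy()
    thr[0] = scores.max()
    j = tpr - fpr
    best = int(np.flatnonzero(j == j.max())[-1])  # last index = smallest threshold
    return ROCResult(
        thresholds=thr,
        sens_curve=tpr,
        one_minus_spec_curve=fpr,
        auc=auc,
        youden_cutoff=float(thr[best]),
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @classmethod
    def from_predictions(cls, scores, labels, cutoff: float) -> "ConfusionMatrix":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels).astype(bool)
        pred = scores >= cutoff
        return cls(
            tp=int(np.sum(pred & labels)),
            fp=int(np.sum(pred & ~labels)),
            tn=int(np.sum(~pred & ~labels)),
            fn=int(np.sum(~pred & labels)),
        )


@dataclass(frozen=True)
class DiagnosticIndices:
    sensitivity: float
    specificity: float
    ppv: Optional[float]  # None when no positive calls were made
    npv: Optional[float]
    sensitivity_ci: Tuple[float, float]
    specificity_ci: Tuple[float, float]
    ppv_ci: Optional[Tuple[float, float]]
    npv_ci: Optional[Tuple[float, float]]


def _wilson(count: int, nobs: int) -> Tuple[float, float]:
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def diagnostic_indices(cm: ConfusionMatrix) -> DiagnosticIndices:
    """Sensitivity, specificity, PPV and NPV with 95% Wilson intervals.

    Wilson score intervals stay well-behaved at proportions of 0 and 1
    (needed when specificity is exactly 100%).  PPV/NPV are reported as
    not-applicable (None) when no positive/negative calls were made.
    """
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    if pos == 0 or neg == 0:
        raise ValueError("need at least one true positive-class and negative-class case")
    sens = cm.tp / pos
    spec = cm.tn / neg
    called_pos = cm.tp + cm.fp
    called_neg = cm.tn + cm.fn
    ppv = cm.tp / called_pos if called_pos else None
    npv = cm.tn / called_neg if called_neg else None
    return DiagnosticIndices(
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        sensitivity_ci=_wilson(cm.tp, pos),
        specificity_ci=_wilson(cm.tn, neg),
        ppv_ci=_wilson(cm.tp, called_pos) if called_pos else None,
        npv_ci=_wilson(cm.tn, called_neg) if called_neg else None,
    )


@dataclass
class LogisticModel:
    names: List[str]  # intercept first
    coefficients: np.ndarray
    odds_ratios: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray
    converged: bool
    n_iterations: int
    message: str = ""


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> List[str]:
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    return [names[i] for i in np.nonzero(bad)[0]]


def _fallback_newton(X: np.ndarray, y: np.ndarray, max_iter: int) -> Tuple[np.ndarray, int]:
    """Damped Newton iterations used when the standard fit diverges."""
    beta = np.zeros(X.shape[1])
    for it in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-10, None)
        g = X.T @ (y - p)
        h = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            break
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(g)) < 1e-8:
            break
    return beta, it + 1


def logistic_fit(
    design,
    labels,
    names: Optional[Sequence[str]] = None,
    standardize: bool = False,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Maximum-likelihood logistic regression with separation detection.

    Fits by Newton/IRLS (an intercept is added internally) and reports
    coefficients, odds ratios exp(β), Wald standard errors and p-values.
    Convergence requires max |score| < ``tol``.  Quasi-complete separation
    — a diverging coefficient norm (> 15 on standardized predictors) or a
    singular observed information — is flagged via ``converged = False``
    with an explanatory message rather than an exception.

    With ``standardize=True``, predictors are z-scored first and the
    reported coefficients are on the standardized scale.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design must be (n, p) aligned with labels")
    n, p = X.shape
    if n < p + 1:
        raise ValueError("need more observations than parameters")
    if names is None:
        names = [f"x{i + 1}" for i in range(p)]
    names = list(names)
    col_sd = X.std(axis=0, ddof=0)
    if standardize:
        if np.any(col_sd == 0):
            zero = [names[i] for i in np.nonzero(col_sd == 0)[0]]
            raise ValueError(f"cannot standardize constant columns: {zero}")
        X = (X - X.mean(axis=0)) / col_sd
        col_sd = np.ones(p)
    # a design that already carries a constant column supplies its own
    # intercept; adding another would be spuriously rank-deficient
    has_const = bool(np.any((col_sd == 0) & (X[0] != 0)))
    if has_const:
        Xd = X
        all_names = names
        slope_idx = np.nonzero(col_sd != 0)[0]
    else:
        Xd = np.column_stack([np.ones(n), X])
        all_names = ["intercept"] + names
        slope_idx = np.arange(1, p + 1)
    bad = _collinear_columns(Xd, all_names)
    if bad:
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    message = ""
    converged = False
    n_iter = 0
    try:
        import warnings

        with warnings.catch_warnings():
            # convergence is re-assessed below from the score equations
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xd).fit(method="newton", maxiter=max_iter, tol=1e-12, disp=0)
        beta = np.asarray(res.params)
        se = np.asarray(res.bse)
        pvals = np.asarray(res.pvalues)
        n_iter = int(res.mle_retvals.get("iterations", max_iter))
        mle_conv = bool(res.mle_retvals.get("converged", False))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        beta, n_iter = _fallback_newton(Xd, y, max_iter)
        se = np.full(Xd.shape[1], np.nan)
        pvals = np.full(Xd.shape[1], np.nan)
        mle_conv = False
        message = "perfect or quasi-complete separation detected during fitting"

    eta = Xd @ beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    score = Xd.T @ (y - prob)
    score_ok = float(np.max(np.abs(score))) < tol
    # separation check on the standardized slope norm
    x_col_of = (lambda i: i) if has_const else (lambda i: i - 1)
    slope_scale = np.array([col_sd[x_col_of(i)] for i in slope_idx])
    std_slopes = beta[slope_idx] * slope_scale
    if np.linalg.norm(std_slopes) > 15.0:
        converged = False
        if not message:
            message = (
                "coefficient norm exceeds 15 on standardized predictors: "
                "quasi-complete separation suspected"
            )
    else:
        converged = mle_conv and score_ok
        if not converged and not message:
            message = "score equations not solved to tolerance"
    return LogisticModel(
        names=all_names,
        coefficients=beta,
        odds_ratios=np.exp(beta),
        standard_errors=se,
        p_values=pvals,
        converged=converged,
        n_iterations=n_iter,
        message=message,
    )
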