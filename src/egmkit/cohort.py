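"""Cohort-level discrimination and group-comparison statistics.

AUC here is the two-sample concordance probability: for an index oriented so
that higher values point to termination, the AUC equals the probability that
a randomly chosen terminating patient scores above a randomly chosen
non-terminating one (ties counting one half).  Confidence intervals come
from a class-stratified nonparametric percentile bootstrap; robustness is
probed by repeatedly removing a handful of random patients (leave-k-out)
and by per-group outlier removal (3 SD for normal-looking groups, 1.5 IQR
fences otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = [
    "ROCResult",
    "roc_auc",
    "bootstrap_auc_ci",
    "sensitivity_leave_k_out",
    "remove_outliers",
    "group_compare",
    "adjusted_logistic_check",
    "LogisticCheckResult",
]

_ORIENTATIONS = ("higher_is_term", "lower_is_term")


@dataclass(frozen=True)
class ROCResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    orientation: str
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0


def _validate(scores, labels, orientation) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray([1 if lab == "Term" else 0 for lab in labels])
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D sequences")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.min() == y.max():
        raise ValueError("need patients from both classes")
    if orientation not in _ORIENTATIONS:
        raise ValueError(f"orientation must be one of {_ORIENTATIONS}")
    return s, y


def _oriented(s: np.ndarray, orientation: str) -> np.ndarray:
    return s if orientation == "higher_is_term" else -s


def _fast_auc(s: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney form of the AUC; ties contribute one half."""
    n1 = int(y.sum())
    n0 = y.size - n1
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(scores, labels, orientation: str = "higher_is_term") -> ROCResult:
    """ROC curve and AUC for discriminating Term from NonTerm patients.

    The AUC is the trapezoidal area under the empirical ROC, identical to
    the pairwise concordance probability with ties at one half.
    """
    s, y = _validate(scores, labels, orientation)
    s = _oriented(s, orientation)
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return ROCResult(auc=float(np.trapezoid(tpr, fpr)), fpr=fpr, tpr=tpr,
                     orientation=orientation)


def bootstrap_auc_ci(scores, labels, orientation: str = "higher_is_term",
                     n_boot: int = 10_000, seed: int = 0,
                     ci: float = 0.95) -> tuple[float, float]:
    """Class-stratified percentile bootstrap CI of the AUC.

    Patients are resampled with replacement within each class, so every
    replicate retains both classes at the original sizes.
    """
    s, y = _validate(scores, labels, orientation)
    s = _oriented(s, orientation)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need >= 2 patients per class to bootstrap")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate([rng.choice(idx1, idx1.size, replace=True),
                               rng.choice(idx0, idx0.size, replace=True)])
        aucs[b] = _fast_auc(s[take], y[take])
    lo = (1.0 - ci) / 2.0
    return (float(np.quantile(aucs, lo)), float(np.quantile(aucs, 1.0 - lo)))


def sensitivity_leave_k_out(scores, labels, orientation: str = "higher_is_term",
                            k: int = 5, n_iter: int = 5000,
                            seed: int = 0) -> tuple[float, tuple[float, float]]:
    """AUC stability under random removal of ``k`` patients per iteration.

    Returns the median AUC and its (Q1, Q3) over ``n_iter`` iterations; a
    removal set that wipes out a class is redrawn.
    """
    s, y = _validate(scores, labels, orientation)
    s = _oriented(s, orientation)
    n = s.size
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the cohort ({n})")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_iter)
    for it in range(n_iter):
        while True:
            keep = np.ones(n, dtype=bool)
            if k > 0:
                keep[rng.choice(n, k, replace=False)] = False
            if 0 < y[keep].sum() < keep.sum():
                break
        aucs[it] = _fast_auc(s[keep], y[keep])
    q1, med, q3 = np.quantile(aucs, [0.25, 0.5, 0.75])
    return float(med), (float(q1), float(q3))


def remove_outliers(values, labels, method: str = "auto", ids=None,
                    alpha: float = 0.05):
    """Per-group outlier removal.

    ``sd3`` drops values beyond 3 group standard deviations from the group
    mean; ``iqr15`` drops values beyond 1.5 IQR outside the group quartiles.
    ``auto`` picks per group by a Shapiro-Wilk normality test at ``alpha``
    (normal-looking -> sd3, otherwise iqr15).  Returns
    ``(kept_values, kept_labels, kept_ids, removed_ids)``.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if ids is None:
        ids = np.arange(v.size)
    ids = np.asarray(ids)
    if method not in {"auto", "sd3", "iqr15"}:
        raise ValueError(f"unknown outlier method: {method!r}")
    keep = np.ones(v.size, dtype=bool)
    for g in np.unique(lab):
        m = lab == g
        x = v[m]
        if x.size < 4:
            raise ValueError(f"group {g!r} has fewer than 4 values")
        rule = method
        if method == "auto":
            rule = "sd3" if (np.ptp(x) > 0
                             and stats.shapiro(x).pvalue >= alpha) else "iqr15"
        if np.ptp(x) == 0:
            continue  # zero spread: nothing can be an outlier
        if rule == "sd3":
            mu, sd = x.mean(), x.std(ddof=1)
            bad = np.abs(x - mu) > 3 * sd
        else:
            q1, q3 = np.quantile(x, [0.25, 0.75])
            iqr = q3 - q1
            bad = (x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)
        keep[np.flatnonzero(m)[bad]] = False
    if not keep.any():
        raise ValueError("outlier rule removed every value")
    return v[keep], lab[keep], ids[keep], ids[~keep]


def group_compare(values, labels, test: str = "ranksum"):
    """Two-sided Term vs NonTerm comparison with the matching summary style.

    ``welch_t`` reports per-group ``mean +- SD``; ``ranksum`` (Wilcoxon
    rank-sum / Mann-Whitney, exact for small tie-free groups, tie- and
    continuity-corrected normal approximation otherwise) reports
    ``median (Q1-Q3)``.  Returns ``(statistic, p_value, summaries)`` where
    ``summaries`` maps group name to its formatted string.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    groups = {g: v[lab == g] for g in ("Term", "NonTerm")}
    if any(x.size < 2 for x in groups.values()):
        raise ValueError("need >= 2 patients per group")
    a, b = groups["Term"], groups["NonTerm"]
    summaries = {}
    if test == "welch_t":
        stat, p = stats.ttest_ind(a, b, equal_var=False)
        for g, x in groups.items():
            summaries[g] = f"{x.mean():.3g} ± {x.std(ddof=1):.3g}"
    elif test == "ranksum":
        small = max(a.size, b.size) <= 10 and np.unique(v).size == v.size
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="exact" if small else "asymptotic",
                                     use_continuity=True)
        for g, x in groups.items():
            q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
            summaries[g] = f"{med:.3g} ({q1:.3g}-{q3:.3g})"
    else:
        raise ValueError(f"test must be 'welch_t' or 'ranksum', got {test!r}")
    return float(stat), float(p), summaries


@dataclass(frozen=True)
class LogisticCheckResult:
    p_value: float | None
    coef: float | None
    separation: bool


def adjusted_logistic_check(index_values, labels,
                            covariate_values) -> LogisticCheckResult:
    """Wald p of the index in a logistic fit of label on {index, covariate}.

    A convenience check that index significance survives single-covariate
    adjustment.  Perfect separation is flagged and no p-value reported.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(index_values, dtype=float)
    z = np.asarray(covariate_values, dtype=float)
    y = np.asarray([1 if lab == "Term" else 0 for lab in labels])
    if np.ptp(x) == 0:  # constant index carries no information
        return LogisticCheckResult(1.0, 0.0, separation=False)
    X = sm.add_constant(np.column_stack([x, z]))
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticCheckResult(None, None, separation=True)
    coef = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or se > 1e3 * max(1.0, abs(coef)):
        return LogisticCheckResult(None, None, separation=True)
    return LogisticCheckResult(float(fit.pvalues[1]), coef, separation=False)
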