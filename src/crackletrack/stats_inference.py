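"""Statistical chain for the honeycombing vs non-honeycombing contrast.

Covers the cohort-level inference pipeline: median [IQR] summaries,
Mann-Whitney U and chi-squared group comparisons, Gwet's AC1 inter-rater
agreement, univariate-to-multivariate logistic regression with unit-scaled
odds ratios (OR per 100 Hz of F99, per 5 crackles, etc.), correlated-
variable pruning, ROC analysis with the upper-left-corner cutoff, and
dichotomization at a chosen cutoff.

Wald confidence intervals at alpha = 0.05 throughout; complete-case
handling per model; no multiple-testing correction (mirroring common
clinical practice for exploratory acoustic features).
"""

from __future__ import annotations

import decimal
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

Z95 = 1.96  # Wald 95% multiplier as conventionally printed


def _safe_exp(v: float) -> float:
    try:
        return math.exp(v)
    except OverflowError:
        return math.inf


# ---------------------------------------------------------------------------
# descriptive summaries

def summarize_group(values) -> tuple[float, float, float]:
    """(median, q1, q3) with linear interpolation of order statistics."""
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q1), float(q3)


def format_median_iqr(values, fmt: str = "{:.1f}") -> str:
    med, q1, q3 = summarize_group(values)
    return f"{fmt.format(med)} [{fmt.format(q1)}–{fmt.format(q3)}]"


def counts_pct(k: int, n: int) -> str:
    """Render ``k (pct)`` with the percentage rounded half-up to 1 decimal."""
    if n < 1:
        raise ValueError("denominator must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("numerator must lie in [0, n]")
    pct = decimal.Decimal(100 * k) / decimal.Decimal(n)
    pct = pct.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP)
    return f"{k} ({pct})"


# ---------------------------------------------------------------------------
# group comparisons

def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; (U of x, p).

    U counts pairs with x > y (ties half-weighted).  The exact null
    distribution is used for small tie-free samples (n_x * n_y <= 400),
    the normal approximation with tie and continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if x.size * y.size <= 400 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def chi_squared(table, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared on an r x k count table; (statistic, df, p)."""
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or np.any(tab < 0):
        raise ValueError("need a 2-D table of non-negative counts")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("every row and column margin must be positive")
    res = stats.chi2_contingency(tab, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# ---------------------------------------------------------------------------
# Gwet's AC1

@dataclass(frozen=True)
class AgreementResult:
    ac1: float
    ci_low: float
    ci_high: float
    n_items: int
    n_raters: int


def gwet_ac1(ratings) -> AgreementResult:
    """Gwet's AC1 chance-corrected agreement for categorical ratings.

    ``ratings`` is an items x raters array-like (complete data).  AC1 is
    (p_a - p_e) / (1 - p_e) with p_a the mean pairwise observed agreement
    per item and p_e = sum_c pi_c (1 - pi_c) / (C - 1), pi_c the mean
    category proportion across raters.  Unlike kappa, p_e stays away from
    1 under extreme prevalence, so AC1 is stable for rare findings.  The
    95% CI is Wald on the standard item-level variance estimator,
    truncated above at 1.
    """
    mat = np.asarray(pd.DataFrame(ratings))
    n, r = mat.shape
    if r < 2 or n < 2:
        raise ValueError("need at least 2 raters and 2 items")
    cats = np.unique(mat)
    c = max(len(cats), 2)
    # item x category rating counts
    counts = np.stack([(mat == cat).sum(axis=1) for cat in cats], axis=1)

    pa_i = (counts * (counts - 1)).sum(axis=1) / (r * (r - 1))
    pa = pa_i.mean()
    pi_c = (counts / r).mean(axis=0)
    pe = float((pi_c * (1 - pi_c)).sum() / (c - 1))
    ac1 = (pa - pe) / (1 - pe)

    # item-level variance (jackknife-style linearization)
    ac1_i = (pa_i - pe) / (1 - pe)
    pe_i = (counts / r) @ (1 - pi_c) / (c - 1)
    ac1_star = ac1_i - 2 * (1 - ac1) * (pe_i - pe) / (1 - pe)
    var = float(((ac1_star - ac1) ** 2).sum() / (n * (n - 1)))
    se = math.sqrt(max(var, 0.0))
    return AgreementResult(ac1=float(ac1),
                           ci_low=float(ac1 - Z95 * se),
                           ci_high=float(min(ac1 + Z95 * se, 1.0)),
                           n_items=n, n_raters=r)


# ---------------------------------------------------------------------------
# logistic regression with unit-scaled odds ratios

@dataclass(frozen=True)
class TermSpec:
    """One model term: column name and the unit the OR is expressed per
    (e.g. unit_scale=100 reports the OR per 100 Hz of F99)."""

    name: str
    unit_scale: float = 1.0


@dataclass
class TermFit:
    name: str
    unit_scale: float
    beta: float
    se: float
    or_value: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class LogisticFit:
    terms: list[TermFit]
    n_used: int
    converged: bool
    log_likelihood: float

    def term(self, name: str) -> TermFit:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def fit_logistic(records: pd.DataFrame, outcome: str,
                 terms: list[TermSpec]) -> LogisticFit:
    """Maximum-likelihood logistic fit with unit-scaled odds ratios.

    Complete cases only; outcome must be 0/1 with both classes present.
    OR per term = exp(beta * unit_scale); 95% CI =
    exp((beta +/- 1.96 se) * unit_scale).  Perfect separation is flagged
    via ``converged=False`` rather than returning silent estimates.
    """
    cols = [outcome] + [t.name for t in terms]
    data = records[cols].dropna()
    y = data[outcome].astype(float).to_numpy()
    if y.size == 0 or y.min() == y.max():
        raise ValueError("need at least one event and one non-event")
    X = sm.add_constant(data[[t.name for t in terms]].astype(float),
                        has_constant="add")

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=100, tol=1e-8)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            res = None
            converged = False
        if res is None:  # singular Hessian under (quasi-)separation:
            try:  # quasi-Newton still yields finite, flagged estimates
                res = model.fit(disp=0, method="bfgs", maxiter=200)
            except Exception:
                res = None
    if res is not None and np.abs(np.asarray(res.params)).max() > 30:
        converged = False  # numeric signature of separation

    fits: list[TermFit] = []
    for t in terms:
        if res is None:
            fits.append(TermFit(t.name, t.unit_scale, *(float("nan"),) * 6))
            continue
        b = float(res.params[t.name])
        se = float(res.bse[t.name])
        s = t.unit_scale
        fits.append(TermFit(
            name=t.name, unit_scale=s, beta=b, se=se,
            or_value=_safe_exp(b * s),
            ci_low=_safe_exp((b - Z95 * se) * s),
            ci_high=_safe_exp((b + Z95 * se) * s),
            p=float(res.pvalues[t.name])))
    return LogisticFit(terms=fits, n_used=int(len(data)),
                       converged=converged,
                       log_likelihood=float(res.llf) if res is not None
                       else float("nan"))


def select_multivariate_terms(records: pd.DataFrame, outcome: str,
                              candidates: list[TermSpec],
                              p_enter: float = 0.05,
                              corr_threshold: float = 0.7,
                              representatives: tuple[str, ...] = ("f99_hz",),
                              ) -> list[TermSpec]:
    """Univariate screen then correlated-cluster pruning.

    Keeps candidates with univariate p < ``p_enter``; within any cluster
    of kept continuous variables with pairwise |Spearman rho| >
    ``corr_threshold``, only the designated representative (default F99
    for the frequency cluster) is retained — otherwise the cluster member
    with the smallest univariate p.  Returns an empty list (with a
    warning) when nothing is significant.
    """
    kept: list[tuple[TermSpec, float]] = []
    for t in candidates:
        fit = fit_logistic(records, outcome, [t])
        p = fit.term(t.name).p
        if fit.converged and p < p_enter:
            kept.append((t, p))
    if not kept:
        warnings.warn("no candidate reached the univariate threshold")
        return []

    names = [t.name for t, _ in kept]
    numeric = [n for n in names
               if pd.api.types.is_numeric_dtype(records[n])
               and records[n].nunique() > 2]
    rho = records[numeric].corr(method="spearman").abs() if numeric else None

    # greedy clustering on the |rho| > threshold graph
    clusters: list[set[str]] = []
    for n in numeric:
        home = None
        for cl in clusters:
            if any(rho.loc[n, m] > corr_threshold for m in cl):
                home = cl
                break
        (home.add(n) if home is not None else clusters.append({n}))

    drop: set[str] = set()
    pv = dict((t.name, p) for t, p in kept)
    for cl in clusters:
        if len(cl) < 2:
            continue
        rep = next((r for r in representatives if r in cl), None)
        if rep is None:
            rep = min(cl, key=lambda n: pv[n])
        drop |= cl - {rep}
    return [t for t, _ in kept if t.name not in drop]


# ---------------------------------------------------------------------------
# ROC with upper-left-corner cutoff

@dataclass
class RocResult:
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    cutoff: float
    cutoff_sens: float
    cutoff_spec: float


def roc_analysis(scores, labels) -> RocResult:
    """ROC over all distinct thresholds; cutoff closest to (0, 1).

    Positive calls are ``score >= threshold``.  Candidate thresholds are
    midpoints between adjacent distinct scores plus sentinels below and
    above the score range; AUC by the trapezoid rule; the reported cutoff
    minimizes sqrt((1-sens)^2 + (1-spec)^2), ties broken toward higher
    specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.size != y.size or s.size == 0:
        raise ValueError("scores and labels must align and be non-empty")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2
    thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])

    sens = np.array([(s[y == 1] >= t).mean() for t in thresholds])
    spec = np.array([(s[y == 0] < t).mean() for t in thresholds])

    # integrate along the ROC path (descending threshold: fpr and sens
    # both nondecreasing), which makes the trapezoid rule exact for the
    # empirical staircase
    fpr = 1 - spec
    order = np.argsort(-thresholds)
    auc = float(np.trapezoid(sens[order], fpr[order]))

    dist = np.hypot(1 - sens, 1 - spec)
    best = np.flatnonzero(dist <= dist.min() + 1e-12)
    i = best[np.argmax(spec[best])]
    return RocResult(thresholds=thresholds, sens=sens, spec=spec, auc=auc,
                     cutoff=float(thresholds[i]),
                     cutoff_sens=float(sens[i]), cutoff_spec=float(spec[i]))


def auc_bootstrap_ci(scores: np.ndarray, labels: np.ndarray,
                     n_boot: int = 1000, seed: int = 0,
                     alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI for the ROC AUC (resampling patients)."""
    rng = np.random.default_rng(seed)
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = s.size
    aucs = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        aucs.append(roc_analysis(s[idx], yb).auc)
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def dichotomize(records: pd.DataFrame, variable: str, cutoff: float,
                new_name: str | None = None) -> pd.DataFrame:
    """Add an indicator column: 1 when value >= cutoff, NaN propagates."""
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    out = records.copy()
    col = records[variable]
    out[new_name or f"{variable}_ge_cutoff"] = (col >= cutoff).astype(float).where(col.notna())
    return out
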