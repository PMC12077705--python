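"""Cross-method aggregation, descriptive summaries and nonparametric tests.

PFS distributions from EHR-derived endpoints are strongly right-skewed
(long-term survivors), so comparisons use rank statistics: a
Kruskal–Wallis omnibus test across methods on the complete-case subset,
and pairwise Wilcoxon signed-rank tests with Bonferroni correction on
each pair's own complete cases.  The signed-rank test is implemented here
because the variant used — exact two-sided p by sign-pattern enumeration
for n <= 12 even with tied magnitudes, normal approximation with tie and
continuity correction otherwise — is not available off the shelf.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import EndpointResult, Method

#: Largest pair count for which the exact enumeration p-value is used.
EXACT_ENUMERATION_MAX_N = 12

#: Default Bonferroni family size: three methods vs clinical plus the three
#: method-method pairs.
DEFAULT_BONFERRONI_M = 6


@dataclass(frozen=True)
class MethodSummary:
    method: Method
    cohort_n: int
    n_progressed: int
    percent_progressed: int  # integer % of cohort_n
    mean_pfs: Optional[float]
    sd_pfs: Optional[float]
    median_pfs: Optional[float]
    range_pfs: Optional[tuple[float, float]]


@dataclass(frozen=True)
class DifferenceSummary:
    """Paired (method - clinical) PFS differences in months.

    Negative values mean the automated date fell before the clinical
    standard date.
    """

    method: Method
    n_pairs: int
    mean_diff: float
    sd_diff: float
    median_diff: float
    range_diff: tuple[float, float]


@dataclass(frozen=True)
class OmnibusTest:
    statistic: float  # Kruskal-Wallis H, chi-square scale
    df: int
    p_value: float
    n_total: int


@dataclass(frozen=True)
class PairwiseTest:
    method_a: str
    method_b: str
    statistic: Optional[float]  # signed-rank W
    p_value: Optional[float]
    p_adjusted: Optional[float]
    n_pairs: int
    degenerate: bool = False  # all differences zero


def aggregate(results: Iterable[EndpointResult]) -> pd.DataFrame:
    """Per-patient wide table of PFS months by method.

    Missing entries (no progression, or method not evaluable) are NaN.
    Duplicate (patient, method) rows raise.
    """
    rows = list(results)
    seen = set()
    for r in rows:
        key = (r.patient_id, r.method)
        if key in seen:
            raise ValueError(f"duplicate result for {key}")
        seen.add(key)
    frame = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in rows],
            "method": [r.method.value for r in rows],
            "pfs_months": [r.pfs_months for r in rows],
        }
    )
    wide = frame.pivot(index="patient_id", columns="method", values="pfs_months")
    wide.columns.name = None
    return wide


def summarize(results: Sequence[EndpointResult], cohort_n: int) -> MethodSummary:
    """Table-style descriptive statistics for one method.

    Moments are over progressed patients only; the percentage is over the
    full cohort, rounded to the nearest integer.
    """
    if cohort_n <= 0:
        raise ValueError("cohort_n must be positive")
    methods = {r.method for r in results}
    if len(methods) > 1:
        raise ValueError("summarize expects results from a single method")
    pfs = np.array([r.pfs_months for r in results if r.progressed], dtype=float)
    n_prog = len(pfs)
    percent = int(round(100.0 * n_prog / cohort_n))
    if n_prog == 0:
        return MethodSummary(
            method=next(iter(methods)) if methods else Method.CLINICAL,
            cohort_n=cohort_n,
            n_progressed=0,
            percent_progressed=0,
            mean_pfs=None,
            sd_pfs=None,
            median_pfs=None,
            range_pfs=None,
        )
    return MethodSummary(
        method=next(iter(methods)),
        cohort_n=cohort_n,
        n_progressed=n_prog,
        percent_progressed=percent,
        mean_pfs=float(np.mean(pfs)),
        sd_pfs=float(np.std(pfs, ddof=1)) if n_prog > 1 else 0.0,
        median_pfs=float(np.median(pfs)),
        range_pfs=(float(np.min(pfs)), float(np.max(pfs))),
    )


def _paired_diffs(
    method_results: Sequence[EndpointResult],
    clinical_results: Sequence[EndpointResult],
) -> np.ndarray:
    m = {r.patient_id: r.pfs_months for r in method_results if r.progressed}
    c = {r.patient_id: r.pfs_months for r in clinical_results if r.progressed}
    common = sorted(set(m) & set(c))
    return np.array([m[p] - c[p] for p in common], dtype=float)


def difference_stats(
    method_results: Sequence[EndpointResult],
    clinical_results: Sequence[EndpointResult],
) -> Optional[DifferenceSummary]:
    """Paired (method - clinical) differences over patients with both
    dates; None when no patient overlaps."""
    diffs = _paired_diffs(method_results, clinical_results)
    if diffs.size == 0:
        return None
    methods = {r.method for r in method_results}
    return DifferenceSummary(
        method=next(iter(methods)),
        n_pairs=int(diffs.size),
        mean_diff=float(np.mean(diffs)),
        sd_diff=float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0,
        median_diff=float(np.median(diffs)),
        range_diff=(float(np.min(diffs)), float(np.max(diffs))),
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> OmnibusTest:
    """Kruskal-Wallis H (tie-corrected) with chi-square p on k-1 df."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    df = len(groups) - 1
    if np.all(pooled == pooled[0]):
        return OmnibusTest(statistic=0.0, df=df, p_value=1.0, n_total=len(pooled))
    h, p = stats.kruskal(*groups)
    return OmnibusTest(
        statistic=float(h), df=df, p_value=float(p), n_total=len(pooled)
    )


def _signed_rank_parts(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nonzero differences and the ranks of their magnitudes (average ties)."""
    nonzero = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(nonzero))
    return nonzero, ranks


def wilcoxon_signed_rank(
    diffs: Sequence[float], exact_max_n: int = EXACT_ENUMERATION_MAX_N
) -> tuple[Optional[float], Optional[float], int, bool]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are discarded before ranking.  Returns
    ``(W, p, n_used, degenerate)`` with W the rank sum of the less
    frequent sign (ties between sign counts resolve to min(W+, W-)).  The
    p-value is exact by enumeration of all 2**n sign patterns for
    n <= exact_max_n, else a normal approximation with tie and continuity
    corrections.
    """
    nonzero, ranks = _signed_rank_parts(np.asarray(diffs, dtype=float))
    n = len(nonzero)
    if n == 0:
        return None, None, 0, True
    w_plus = float(ranks[nonzero > 0].sum())
    w_minus = float(ranks[nonzero < 0].sum())
    n_pos = int((nonzero > 0).sum())
    n_neg = n - n_pos
    if n_pos < n_neg:
        w = w_plus
    elif n_neg < n_pos:
        w = w_minus
    else:
        w = min(w_plus, w_minus)
    t_obs = min(w_plus, w_minus)

    if n <= exact_max_n:
        total = ranks.sum()
        count = 0
        for pattern in itertools.product((0.0, 1.0), repeat=n):
            s_plus = float(np.dot(pattern, ranks))
            if min(s_plus, total - s_plus) <= t_obs + 1e-9:
                count += 1
        p = count / 2.0**n
    else:
        mu = n * (n + 1) / 4.0
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        # average ranks: a magnitude tied t times contributes (t^3 - t)/48
        sigma2 -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
        sigma = math.sqrt(sigma2)
        z = (abs(w_plus - mu) - 0.5) / sigma
        p = 2.0 * stats.norm.sf(max(z, 0.0))
    return w, min(float(p), 1.0), n, False


def bonferroni(p: float, m: int) -> float:
    return min(1.0, p * m)


def wilcoxon_pairwise(
    pairs: Mapping[tuple[str, str], tuple[Sequence[float], Sequence[float]]],
    m: int = DEFAULT_BONFERRONI_M,
) -> list[PairwiseTest]:
    """Wilcoxon signed-rank tests over named method pairs with Bonferroni
    adjustment (family size *m*).

    *pairs* maps (method_a, method_b) to equal-length paired PFS vectors.
    A pair whose differences are all zero is reported degenerate rather
    than raised.
    """
    tests = []
    for (name_a, name_b), (x, y) in pairs.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError(f"{name_a}/{name_b}: unequal pair lengths")
        w, p, n_used, degenerate = wilcoxon_signed_rank(x - y)
        tests.append(
            PairwiseTest(
                method_a=name_a,
                method_b=name_b,
                statistic=w,
                p_value=p,
                p_adjusted=None if p is None else bonferroni(p, m),
                n_pairs=n_used,
                degenerate=degenerate,
            )
        )
    return tests


def agreement_within(
    method_results: Sequence[EndpointResult],
    clinical_results: Sequence[EndpointResult],
    window: float = 2.0,
) -> Optional[float]:
    """Fraction of paired dates with |method - clinical| <= window months
    (boundary inclusive); None when no pairs exist."""
    if window < 0:
        raise ValueError("window must be non-negative")
    diffs = _paired_diffs(method_results, clinical_results)
    if diffs.size == 0:
        return None
    return float(np.mean(np.abs(diffs) <= window))


def ols_trend(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, float, float, float]:
    """Ordinary least squares of y on x.

    Returns (slope, intercept, R^2, F, p).  Used for method-vs-clinical
    trendlines and the treatment-year trend.  Raises on constant x.
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.all(x == x[0]):
        raise ValueError("x is constant; fit undefined")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    # constant y gives 0/0 statistics; report a flat, uninformative fit
    r2 = float(model.rsquared) if np.isfinite(model.rsquared) else 0.0
    f = float(model.fvalue) if np.isfinite(model.fvalue) else 0.0
    p = float(model.f_pvalue) if np.isfinite(model.f_pvalue) else 1.0
    return (float(model.params[1]), float(model.params[0]), r2, f, p)
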