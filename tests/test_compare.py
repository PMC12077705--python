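"""Comparative statistics: summaries, rank tests vs enumeration oracles, OLS."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ehrpfs.compare import (
    agreement_within,
    aggregate,
    bonferroni,
    difference_stats,
    kruskal_wallis,
    ols_trend,
    summarize,
    wilcoxon_pairwise,
    wilcoxon_signed_rank,
)
from ehrpfs.records import EndpointResult, Method

from conftest import make_date


def _result(pid, method, pfs=None):
    if pfs is None:
        return EndpointResult(pid, method, progressed=False)
    return EndpointResult(
        pid,
        method,
        progressed=True,
        progression_date=make_date(int(pfs * 30.4375)),
        pfs_months=pfs,
    )


# ---------------------------------------------------------------- aggregation

def test_aggregate_wide_table_with_gaps():
    results = [
        _result("A", Method.CLINICAL, 6.0),
        _result("A", Method.STEROID, 8.0),
        _result("B", Method.CLINICAL, 4.0),
        _result("B", Method.STEROID),  # no progression: empty cell
    ]
    wide = aggregate(results)
    assert wide.loc["A", "steroid"] == 8.0
    assert np.isnan(wide.loc["B", "steroid"])
    assert wide.shape == (2, 2)


def test_aggregate_rejects_duplicates():
    with pytest.raises(ValueError, match="duplicate"):
        aggregate([_result("A", Method.NLP, 1.0), _result("A", Method.NLP, 2.0)])


# ----------------------------------------------------------------- summaries

def test_summary_percent_and_moments():
    results = [_result(f"P{i}", Method.STEROID, 2.0 + 2 * (i % 3)) for i in range(58)]
    summary = summarize(results, cohort_n=92)
    assert summary.percent_progressed == 63  # 58 of 92
    three = summarize(
        [_result("A", Method.NLP, 2.0), _result("B", Method.NLP, 4.0),
         _result("C", Method.NLP, 6.0)],
        cohort_n=3,
    )
    assert three.mean_pfs == pytest.approx(4.0)
    assert three.median_pfs == pytest.approx(4.0)
    assert three.range_pfs == (2.0, 6.0)


def test_summary_with_no_progressed_patients():
    summary = summarize([_result("A", Method.NLP)], cohort_n=10)
    assert summary.percent_progressed == 0 and summary.mean_pfs is None


def test_difference_stats_sign_convention():
    method = [_result("A", Method.NLP, 4.0), _result("B", Method.NLP, 2.0)]
    clinical = [_result("A", Method.CLINICAL, 6.0), _result("B", Method.CLINICAL, 3.0)]
    diff = difference_stats(method, clinical)
    # automated earlier than clinical => negative
    assert diff.mean_diff == pytest.approx(-1.5)
    assert diff.range_diff == (-2.0, -1.0)
    assert difference_stats(method, [_result("Z", Method.CLINICAL, 1.0)]) is None


def test_difference_stats_symmetric_cases():
    same = [_result("A", Method.NLP, 4.0)]
    clin = [_result("A", Method.CLINICAL, 4.0)]
    diff = difference_stats(same, clin)
    assert diff.mean_diff == 0.0 and diff.sd_diff == 0.0


# ------------------------------------------------------------ Kruskal-Wallis

def _kw_oracle(groups):
    """Independent H computation: tie-averaged ranks by hand."""
    pooled = [(v, gi) for gi, g in enumerate(groups) for v in g]
    values = sorted(v for v, _ in pooled)
    ranks = {}
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and values[j] == values[i]:
            j += 1
        ranks[values[i]] = (i + 1 + j) / 2.0
        i = j
    n = len(values)
    h = 0.0
    for g in groups:
        r = sum(ranks[v] for v in g)
        h += r * r / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    tie = 0.0
    i = 0
    while i < len(values):
        j = i
        while j < len(values) and values[j] == values[i]:
            j += 1
        t = j - i
        tie += t**3 - t
        i = j
    denom = 1.0 - tie / (n**3 - n)
    return h / denom if denom > 0 else 0.0


def test_kruskal_identical_groups_gives_zero():
    result = kruskal_wallis([[5.0, 5.0], [5.0, 5.0], [5.0]])
    assert result.statistic == 0.0 and result.p_value == 1.0
    two_copies = kruskal_wallis([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert two_copies.statistic == pytest.approx(0.0, abs=1e-12)


def test_kruskal_matches_rank_formula_oracle():
    groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
    result = kruskal_wallis(groups)
    assert result.statistic == pytest.approx(_kw_oracle(groups), abs=1e-10)
    assert result.df == 2


@settings(max_examples=60)
@given(
    st.lists(
        st.lists(st.integers(min_value=0, max_value=6).map(float), min_size=1, max_size=8),
        min_size=2,
        max_size=4,
    )
)
def test_kruskal_matches_oracle_on_random_small_inputs(groups):
    result = kruskal_wallis(groups)
    assert result.statistic == pytest.approx(_kw_oracle(groups), abs=1e-9)


def test_kruskal_invariant_under_monotone_transform():
    rng = np.random.default_rng(4)
    groups = [list(rng.uniform(0, 10, 5)) for _ in range(3)]
    h1 = kruskal_wallis(groups).statistic
    h2 = kruskal_wallis([[np.exp(v) for v in g] for g in groups]).statistic
    assert h1 == pytest.approx(h2, abs=1e-9)


# ------------------------------------------------------- Wilcoxon signed-rank

def _wilcoxon_oracle(diffs):
    """Exact two-sided p via the full null distribution of W+."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    total = ranks.sum()
    w_plus = ranks[d > 0].sum()
    t_obs = min(w_plus, total - w_plus)
    hits = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        s_plus = sum(r for r, s in zip(ranks, signs) if s)
        if min(s_plus, total - s_plus) <= t_obs + 1e-9:
            hits += 1
    return hits / 2.0 ** len(d)


def test_wilcoxon_exact_example():
    w, p, n, degenerate = wilcoxon_signed_rank([1.0, 2.0, -3.0])
    assert not degenerate and n == 3
    assert w == 3.0 and p == 1.0  # min(W+, W-) = 3 is the distribution maximum


def test_wilcoxon_all_zero_differences_is_degenerate():
    w, p, n, degenerate = wilcoxon_signed_rank([0.0, 0.0])
    assert degenerate and w is None and p is None and n == 0


@settings(max_examples=80)
@given(
    st.lists(
        st.integers(min_value=-5, max_value=5).map(float), min_size=1, max_size=8
    ).filter(lambda d: any(v != 0 for v in d))
)
def test_wilcoxon_exact_matches_enumeration_oracle(diffs):
    w, p, n, degenerate = wilcoxon_signed_rank(diffs)
    assert not degenerate
    assert p == pytest.approx(_wilcoxon_oracle(diffs), abs=1e-12)


@settings(max_examples=30)
@given(st.integers(min_value=0, max_value=10_000))
def test_wilcoxon_exact_agrees_with_scipy_on_tie_free_data(seed):
    rng = np.random.default_rng(seed)
    diffs = rng.normal(0.3, 1.0, size=9)
    while len(np.unique(np.abs(diffs))) < len(diffs) or np.any(diffs == 0):
        diffs = rng.normal(0.3, 1.0, size=9)
    _, p, _, _ = wilcoxon_signed_rank(diffs)
    expected = stats.wilcoxon(diffs, mode="exact").pvalue
    assert p == pytest.approx(float(expected), abs=1e-10)


def test_wilcoxon_large_n_uses_normal_approximation():
    rng = np.random.default_rng(1)
    diffs = rng.normal(1.0, 1.0, size=40)
    _, p, n, _ = wilcoxon_signed_rank(diffs)
    assert n == 40
    expected = stats.wilcoxon(diffs, correction=True, mode="approx").pvalue
    assert p == pytest.approx(float(expected), rel=1e-6)


def test_pairwise_bonferroni_adjustment():
    assert bonferroni(0.01, 6) == pytest.approx(0.06)
    assert bonferroni(0.5, 6) == 1.0
    tests = wilcoxon_pairwise(
        {("nlp", "clinical"): ([1.0, 2.0, 3.0], [2.0, 3.0, 5.0])}, m=6
    )
    (t,) = tests
    assert t.p_adjusted == pytest.approx(min(1.0, t.p_value * 6))
    degenerate = wilcoxon_pairwise({("a", "b"): ([1.0, 2.0], [1.0, 2.0])})[0]
    assert degenerate.degenerate


# ------------------------------------------------------------------ agreement

def test_agreement_within_inclusive_window():
    method = [
        _result("A", Method.NLP, 4.0),
        _result("B", Method.NLP, 5.9),
        _result("C", Method.NLP, 8.1),
    ]
    clinical = [
        _result("A", Method.CLINICAL, 4.0),
        _result("B", Method.CLINICAL, 4.0),
        _result("C", Method.CLINICAL, 6.0),
    ]
    assert agreement_within(method, clinical, 2.0) == pytest.approx(2 / 3)
    assert agreement_within(method, clinical, 0.0) == pytest.approx(1 / 3)
    assert agreement_within([], clinical, 2.0) is None


def test_agreement_monotone_in_window():
    rng = np.random.default_rng(2)
    method = [_result(f"P{i}", Method.NLP, float(v)) for i, v in enumerate(rng.uniform(1, 20, 20))]
    clinical = [
        _result(f"P{i}", Method.CLINICAL, float(v))
        for i, v in enumerate(rng.uniform(1, 20, 20))
    ]
    fractions = [agreement_within(method, clinical, w) for w in (0.5, 1, 2, 4, 8, 50)]
    assert fractions == sorted(fractions)
    assert fractions[-1] == 1.0


# ------------------------------------------------------------------------ OLS

def test_ols_exact_line_and_constant_response():
    slope, intercept, r2, _, _ = ols_trend([1, 2, 3, 4], [2, 4, 6, 8])
    assert slope == pytest.approx(2.0) and r2 == pytest.approx(1.0)
    slope0, _, r20, f0, _ = ols_trend([1, 2, 3, 4], [5, 5, 5, 5])
    assert slope0 == pytest.approx(0.0, abs=1e-12) and r20 == 0.0 and f0 == 0.0


def test_ols_matches_normal_equations_oracle():
    x = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
    y = np.array([1.0, 2.2, 2.9, 4.5, 6.1])
    slope, intercept, r2, _, _ = ols_trend(x, y)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    r2_oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
    assert intercept == pytest.approx(beta[0], abs=1e-10)
    assert slope == pytest.approx(beta[1], abs=1e-10)
    assert r2 == pytest.approx(r2_oracle, abs=1e-10)


def test_ols_rejects_constant_predictor():
    with pytest.raises(ValueError):
        ols_trend([2, 2, 2, 2], [1, 2, 3, 4])
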