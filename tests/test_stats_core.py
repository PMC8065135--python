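import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myomethix import stats_core
from myomethix.errors import (
    CollinearInputError,
    DegenerateInputError,
    ValidationError,
)


# ---------------------------------------------------------------------------
# oracles (kept independent of the implementations they check)
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Sort ascending, scale by m/rank, cumulative min from the tail."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q

def wilcoxon_enumeration_p(d):
    """Two-sided exact p by full 2**n enumeration of sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    absd = np.abs(d)
    # midranks computed directly from the definition
    ranks = np.array([((absd < v).sum() + 1 + (absd <= v).sum()) / 2.0
                      for v in absd])
    w_obs = ranks[d > 0].sum()
    sums = [sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)]
    sums = np.array(sums)
    total = sums.size
    cdf = (sums <= w_obs).sum()
    sf = (sums >= w_obs).sum()
    return min(1.0, 2.0 * min(cdf, sf) / total)


# ---------------------------------------------------------------------------
# bh_fdr
# ---------------------------------------------------------------------------

def test_bh_fdr_worked_example():
    res = stats_core.bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(res.q, [0.04, 0.04, 0.04, 0.04])


def test_bh_fdr_single_value_identity():
    assert stats_core.bh_fdr([0.5]).q.tolist() == [0.5]


def test_bh_fdr_empty_and_invalid():
    assert stats_core.bh_fdr([]).q.size == 0
    with pytest.raises(ValidationError):
        stats_core.bh_fdr([0.5, 1.2])


def test_bh_fdr_matches_oracle_on_random_vectors():
    rng = np.random.default_rng(7)
    for _ in range(200):
        p = rng.random(int(rng.integers(1, 80)))
        assert np.array_equal(stats_core.bh_fdr(p).q, bh_oracle(p))


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_fdr_invariants(p):
    res = stats_core.bh_fdr(p)
    assert np.all(res.q >= res.p - 1e-12)
    assert np.all(res.q <= 1.0)
    order = np.argsort(res.p, kind="mergesort")
    assert np.all(np.diff(res.q[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def test_ttest_identical_vectors():
    res = stats_core.two_sample_ttest([1, 2, 3], [1, 2, 3], "pooled")
    assert res.statistic == 0.0 and res.p == 1.0


def test_ttest_closed_form_pooled():
    res = stats_core.two_sample_ttest([1, 2, 3], [4, 5, 6], "pooled")
    expected_t = -3.0 / np.sqrt(1.0 * (1 / 3 + 1 / 3))   # textbook formula
    assert res.statistic == pytest.approx(expected_t, abs=1e-12)
    assert res.df == 4


def test_ttest_antisymmetry():
    rng = np.random.default_rng(0)
    x, y = rng.normal(0, 1, 8), rng.normal(0.5, 1, 9)
    a = stats_core.two_sample_ttest(x, y, "welch")
    b = stats_core.two_sample_ttest(y, x, "welch")
    assert a.statistic == pytest.approx(-b.statistic)
    assert a.p == pytest.approx(b.p)


def test_ttest_zero_variance_conventions():
    res = stats_core.two_sample_ttest([2, 2, 2], [2.0, 2, 2], "welch")
    assert res.p == 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats_core.two_sample_ttest([2, 2, 2], [3.0, 3, 3], "welch")
    assert res.p == 0.0


# ---------------------------------------------------------------------------
# linear model group test
# ---------------------------------------------------------------------------

def test_linear_model_equals_pooled_ttest():
    rng = np.random.default_rng(1)
    y = rng.normal(0, 1, 20)
    g = np.repeat([0.0, 1.0], 10)
    lm = stats_core.linear_model_group_test(y, g)
    tt = stats_core.two_sample_ttest(y[g == 1], y[g == 0], "pooled")
    assert lm.statistic == pytest.approx(tt.statistic, abs=1e-10)
    assert lm.p == pytest.approx(tt.p, abs=1e-10)


def test_linear_model_covariate_determined_response():
    rng = np.random.default_rng(2)
    age = rng.normal(50, 5, 20)
    y = 0.5 * age
    g = rng.integers(0, 2, 20).astype(float)
    res = stats_core.linear_model_group_test(y, g, {"age": age})
    # residuals are float noise, so the coefficient vanishes and p is large
    assert res.p > 0.5
    assert abs(res.estimate) < 1e-8


def test_linear_model_parameter_recovery():
    rng = np.random.default_rng(3)
    g = np.repeat([0.0, 1.0], 14)
    age = rng.normal(55, 7, 28)
    y = 1.0 * g + 0.1 * age + rng.normal(0, 0.01, 28)
    res = stats_core.linear_model_group_test(y, g, {"age": age})
    assert abs(res.estimate - 1.0) < 0.05


def test_linear_model_collinear_design_named():
    rng = np.random.default_rng(4)
    g = np.repeat([0.0, 1.0], 6)
    cov = {"dup": g.copy()}
    with pytest.raises(CollinearInputError, match="dup|group"):
        stats_core.linear_model_group_test(rng.normal(0, 1, 12), g, cov)


def test_vectorised_matches_scalar():
    rng = np.random.default_rng(5)
    g = np.repeat([0.0, 1.0], 10)
    cov = {"age": rng.normal(50, 5, 20), "sex": rng.integers(0, 2, 20).astype(float)}
    Y = rng.normal(0, 1, (30, 20))
    coef, t, p, df, degenerate = stats_core.linear_model_group_tests(Y, g, cov)
    assert not degenerate.any()
    for i in range(30):
        res = stats_core.linear_model_group_test(Y[i], g, cov)
        assert coef[i] == pytest.approx(res.estimate, abs=1e-10)
        assert t[i] == pytest.approx(res.statistic, abs=1e-10)
        assert p[i] == pytest.approx(res.p, abs=1e-10)


def test_vectorised_flags_constant_rows():
    g = np.repeat([0.0, 1.0], 5)
    Y = np.vstack([np.full(10, 3.0), np.random.default_rng(0).normal(size=10)])
    _, t, p, _, degenerate = stats_core.linear_model_group_tests(Y, g)
    assert degenerate.tolist() == [True, False]
    assert np.isnan(t[0]) and np.isnan(p[0])


def test_global_null_calibration():
    # fraction of p < 0.05 under the null within binomial tolerance
    rng = np.random.default_rng(6)
    n = 28
    g = np.repeat([0.0, 1.0], n // 2)
    cov = {"age": rng.normal(55, 7, n), "sex": rng.integers(0, 2, n).astype(float)}
    Y = rng.normal(0, 1, (20000, n))
    _, _, p, _, _ = stats_core.linear_model_group_tests(Y, g, cov)
    frac = float((p < 0.05).mean())
    assert 0.04 <= frac <= 0.06


# ---------------------------------------------------------------------------
# wilcoxon signed rank
# ---------------------------------------------------------------------------

def test_wilcoxon_small_exact_example():
    res = stats_core.wilcoxon_signed_rank([1.0, 2.0, 3.0], mode="exact")
    assert res.statistic == 6.0
    assert res.p == pytest.approx(0.25)


def test_wilcoxon_sign_symmetry():
    rng = np.random.default_rng(8)
    d = rng.normal(0.3, 1, 12)
    a = stats_core.wilcoxon_signed_rank(d, mode="exact")
    b = stats_core.wilcoxon_signed_rank(-d, mode="exact")
    assert a.p == pytest.approx(b.p)


def test_wilcoxon_matches_enumeration_small_n():
    rng = np.random.default_rng(9)
    for n in range(1, 11):
        for _ in range(4):
            d = rng.normal(0.2, 1, n)
            res = stats_core.wilcoxon_signed_rank(d, mode="exact")
            assert res.p == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)


def test_wilcoxon_all_zero_differences():
    with pytest.warns(UserWarning):
        res = stats_core.wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
    assert res.p == 1.0


def test_wilcoxon_ties_use_midranks():
    d = np.array([1.0, 1.0, -1.0, 2.0, 3.0])
    res = stats_core.wilcoxon_signed_rank(d, mode="exact")
    assert res.p == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)


def test_paired_matrix_matches_scalar():
    rng = np.random.default_rng(10)
    X = rng.normal(0.5, 1, (40, 12))
    Y = rng.normal(0.0, 1, (40, 12))
    X[3] = Y[3]                        # all-zero differences row
    X[5, :4] = Y[5, :4]                # some zeros
    X[7, 1] = Y[7, 1] + (X[7, 0] - Y[7, 0])   # tie in |d|
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        W, P = stats_core.paired_signed_rank_tests(X, Y)
        for i in range(40):
            res = stats_core.wilcoxon_signed_rank(X[i], Y[i])
            assert W[i] == pytest.approx(res.statistic)
            assert P[i] == pytest.approx(res.p)


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------

def test_chi2_worked_2x2():
    res = stats_core.chi2_test([[10, 90], [30, 70]], "independence")
    assert res.statistic == pytest.approx(12.5)
    assert res.df == 1


def test_chi2_observed_equals_expected():
    res = stats_core.chi2_test([25, 25, 25, 25], "uniform")
    assert res.statistic == 0.0 and res.p == pytest.approx(1.0)


def test_chi2_low_expected_flagged_not_fatal():
    res = stats_core.chi2_test([1, 0], [0.5, 1.5])
    assert "expected-cell-below-1" in res.notes


def test_chi2_zero_total_errors():
    with pytest.raises(ValidationError):
        stats_core.chi2_test([[0, 0], [0, 0]], "independence")


def test_chi2_null_p_uniform():
    rng = np.random.default_rng(11)
    pr = np.array([0.3, 0.7])
    pc = np.array([0.4, 0.6])
    probs = np.outer(pr, pc).ravel()
    tables = rng.multinomial(2000, probs, size=5000).reshape(-1, 2, 2)
    ps = np.array([stats_core.chi2_test(t, "independence").p for t in tables])
    grid = np.sort(ps)
    ks = np.max(np.abs(grid - np.arange(1, ps.size + 1) / ps.size))
    assert ks < 0.05


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def test_correlation_perfect_anticorrelation():
    x = np.arange(10, dtype=float)
    for method in ("pearson", "spearman"):
        res = stats_core.correlation(x, -x, method)
        assert res.estimate == pytest.approx(-1.0)
        assert res.p == 0.0


def test_correlation_rank_invariance():
    x = np.linspace(0.1, 3, 12)
    y = np.exp(x)                       # monotone nonlinear
    assert stats_core.correlation(x, y, "spearman").estimate == pytest.approx(1.0)
    assert stats_core.correlation(x, y, "pearson").estimate < 1.0


def test_spearman_equals_pearson_on_midranks():
    from scipy.stats import rankdata
    rng = np.random.default_rng(12)
    x, y = rng.normal(0, 1, 14), rng.normal(0, 1, 14)
    s = stats_core.correlation(x, y, "spearman")
    p = stats_core.correlation(rankdata(x), rankdata(y), "pearson")
    assert s.estimate == pytest.approx(p.estimate, abs=1e-12)


def test_correlation_zero_variance_raises():
    with pytest.raises(DegenerateInputError):
        stats_core.correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_rank_one_matrix():
    u = np.arange(1, 6, dtype=float)
    v = np.array([1.0, -2.0, 0.5, 3.0])
    X = np.outer(u, v)
    _, evr = stats_core.pca_top_components(X, 2)
    assert evr[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_orthogonal_scores_and_variance_conservation():
    rng = np.random.default_rng(13)
    X = rng.normal(0, 1, (30, 8))
    k = 7
    scores, evr = stats_core.pca_top_components(X, k)
    gram = scores.T @ scores
    off = gram - np.diag(np.diag(gram))
    assert np.max(np.abs(off)) < 1e-8
    _, full_evr = stats_core.pca_top_components(X, min(X.shape))
    assert full_evr.sum() == pytest.approx(1.0, abs=1e-8)


def test_pca_constant_matrix_errors():
    with pytest.raises(ValidationError):
        stats_core.pca_top_components(np.full((5, 4), 2.0), 2)
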