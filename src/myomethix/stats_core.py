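"""Core statistical primitives.

Every routine used downstream (BH step-up FDR, t-tests, covariate-adjusted
group regression, exact/approximate Wilcoxon signed-rank, chi-square,
rank/linear correlation, PCA) is implemented here directly so that each can
be validated against an independent brute-force or closed-form oracle in
the test suite.  SciPy supplies only distribution tail functions.

All p-values are two-sided unless a function states otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr_pivot
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm_dist
from scipy.stats import rankdata as _rankdata
from scipy.stats import t as _t_dist

from .errors import CollinearInputError, DegenerateInputError, ValidationError

__all__ = [
    "TestResult",
    "FDRVector",
    "bh_fdr",
    "two_sample_ttest",
    "linear_model_group_test",
    "linear_model_group_tests",
    "wilcoxon_signed_rank",
    "paired_signed_rank_tests",
    "chi2_test",
    "correlation",
    "pca_top_components",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    ``statistic`` is labeled by ``statistic_name`` (t, W, chi2, r or z);
    ``estimate`` carries the effect estimate when one exists (regression
    coefficient, correlation coefficient).  ``notes`` collects non-fatal
    warnings raised while computing the result.
    """

    statistic: float
    p: float
    df: float | None = None
    two_sided: bool = True
    statistic_name: str = "statistic"
    estimate: float | None = None
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValidationError(f"p-value {self.p} outside [0, 1]")


@dataclass(frozen=True)
class FDRVector:
    """Paired vectors of raw p-values and BH-adjusted q-values."""

    p: np.ndarray
    q: np.ndarray


def bh_fdr(p) -> FDRVector:
    """Benjamini-Hochberg step-up adjustment, input order preserved.

    q_i = min_{j: p_j >= p_i} (m * p_j / rank_j), clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return FDRVector(p=p, q=p.copy())
    if np.any(~np.isfinite(p)) or np.any((p < 0.0) | (p > 1.0)):
        raise ValidationError("p-values must be finite and within [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(scaled[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return FDRVector(p=p, q=q)


def two_sample_ttest(x, y, variant: str = "welch") -> TestResult:
    """Two-sided two-sample t-test (``pooled`` or ``welch`` variant)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if variant not in ("pooled", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs n >= 2")
    mx, my = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    notes: tuple[str, ...] = ()
    if v1 == 0.0 and v2 == 0.0:
        if mx == my:
            return TestResult(0.0, 1.0, df=float(n1 + n2 - 2), statistic_name="t",
                              estimate=0.0)
        warnings.warn("zero variance in both groups with unequal means; p -> 0")
        stat = np.inf if mx > my else -np.inf
        return TestResult(stat, 0.0, df=float(n1 + n2 - 2), statistic_name="t",
                          estimate=mx - my, notes=("zero-variance",))
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = float(n1 + n2 - 2)
    else:
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = (mx - my) / se
    p = float(min(1.0, 2.0 * _t_dist.sf(abs(t), df)))
    return TestResult(float(t), p, df=float(df), statistic_name="t",
                      estimate=float(mx - my), notes=notes)


def _build_design(group, covariates) -> tuple[np.ndarray, list[str]]:
    g = np.asarray(group, dtype=float).ravel()
    columns = [np.ones_like(g), g]
    names = ["intercept", "group"]
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            for name in covariates.columns:
                columns.append(np.asarray(covariates[name], dtype=float))
                names.append(str(name))
        elif isinstance(covariates, dict):
            for name, col in covariates.items():
                columns.append(np.asarray(col, dtype=float))
                names.append(str(name))
        else:
            cov = np.atleast_2d(np.asarray(covariates, dtype=float))
            if cov.shape[0] == g.size and cov.shape[1] != g.size:
                cov = cov.T
            for i in range(cov.shape[0]):
                columns.append(cov[i])
                names.append(f"cov{i}")
    X = np.column_stack(columns)
    if not np.all(np.isfinite(X)):
        raise ValidationError("design matrix contains non-finite values")
    return X, names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = _qr_pivot(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = [names[piv[i]] for i in range(len(piv))
               if i >= len(diag) or diag[i] <= tol]
        raise CollinearInputError(
            f"rank-deficient design; collinear columns: {', '.join(bad) or 'unknown'}"
        )


def linear_model_group_test(y, group, covariates=None) -> TestResult:
    """OLS of ``y`` on intercept + group + covariates; tests the group term.

    Returns the group coefficient as ``estimate`` with t = coef/SE on
    n - rank residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    X, names = _build_design(group, covariates)
    n, k = X.shape
    if y.size != n:
        raise ValidationError("response length does not match design")
    if n <= k:
        raise ValidationError(f"n={n} too small for {k} fitted parameters")
    _check_full_rank(X, names)
    if np.ptp(y) == 0.0:
        return TestResult(0.0, 1.0, df=float(n - k), statistic_name="t",
                          estimate=0.0, notes=("constant-response",))
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    if se == 0.0:
        return TestResult(0.0, 1.0, df=float(df), statistic_name="t",
                          estimate=float(beta[1]), notes=("zero-residual-variance",))
    t = float(beta[1] / se)
    p = float(min(1.0, 2.0 * _t_dist.sf(abs(t), df)))
    return TestResult(t, p, df=float(df), statistic_name="t",
                      estimate=float(beta[1]))


def linear_model_group_tests(Y, group, covariates=None):
    """Vectorised form of :func:`linear_model_group_test` over feature rows.

    ``Y`` is features x samples.  Returns ``(coef, t, p, df, degenerate)``
    where ``degenerate`` marks rows constant across samples (skipped by
    callers, t and p are NaN there).
    """
    Y = np.asarray(Y, dtype=float)
    X, names = _build_design(group, covariates)
    n, k = X.shape
    if Y.ndim != 2 or Y.shape[1] != n:
        raise ValidationError("Y must be features x samples matching the design")
    if n <= k:
        raise ValidationError(f"n={n} too small for {k} fitted parameters")
    _check_full_rank(X, names)
    pinv = np.linalg.pinv(X)
    B = Y @ pinv.T                       # features x k
    resid = Y - B @ X.T
    df = n - k
    rss = np.einsum("ij,ij->i", resid, resid)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 0.0))
    degenerate = np.ptp(Y, axis=1) == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = B[:, 1] / se
    p = np.minimum(1.0, 2.0 * _t_dist.sf(np.abs(t), df))
    t[degenerate] = np.nan
    p[degenerate] = np.nan
    return B[:, 1], t, p, float(df), degenerate


@lru_cache(maxsize=256)
def _signed_rank_counts(scaled_ranks: tuple[int, ...]) -> tuple[np.ndarray, int]:
    """Exact null distribution of the positive signed-rank sum.

    ``scaled_ranks`` are (possibly midrank) ranks multiplied by 2 so they
    are integers.  Returns (counts over achievable sums, total = 2**n).
    """
    total_sum = int(sum(scaled_ranks))
    counts = np.zeros(total_sum + 1, dtype=float)
    counts[0] = 1.0
    for r in scaled_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total_sum + 1 - r]
        counts = counts + shifted
    return counts, 2 ** len(scaled_ranks)


def _exact_two_sided_p(scaled_ranks: tuple[int, ...], w_scaled: int) -> float:
    counts, total = _signed_rank_counts(scaled_ranks)
    cdf = counts[: w_scaled + 1].sum()
    sf = counts[w_scaled:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf) / total))


@lru_cache(maxsize=64)
def _exact_p_table(n: int) -> np.ndarray:
    """Two-sided p for every integer W in 0..n(n+1)/2, tie-free case."""
    ranks = tuple(2 * r for r in range(1, n + 1))
    counts, total = _signed_rank_counts(ranks)
    counts = counts[::2]                 # achievable sums are even multiples
    cdf = np.cumsum(counts)
    sf = np.cumsum(counts[::-1])[::-1]
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf) / total)


def wilcoxon_signed_rank(x, y=None, mode: str = "auto") -> TestResult:
    """Wilcoxon signed-rank test on paired samples (d = x - y).

    W is the sum of ranks of positive differences.  ``exact`` enumerates
    the signed-rank sum distribution by dynamic programming; ``auto`` uses
    the exact distribution for n <= 25 without ties, otherwise a normal
    approximation with midrank tie correction and 0.5 continuity
    correction.  Zero differences are dropped (Wilcoxon's treatment).
    """
    if mode not in ("exact", "normal", "auto"):
        raise ValidationError(f"unknown wilcoxon mode {mode!r}")
    x = np.asarray(x, dtype=float).ravel()
    if y is None:
        d = x
    else:
        y = np.asarray(y, dtype=float).ravel()
        if y.size != x.size:
            raise ValidationError("paired vectors must have equal length")
        d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return TestResult(0.0, 1.0, statistic_name="W", notes=("all-zero-differences",))
    absd = np.abs(d)
    ranks = _rankdata(absd)
    w = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n
    use_exact = mode == "exact" or (mode == "auto" and n <= 25 and not has_ties)
    if use_exact:
        scaled = tuple(int(round(2 * r)) for r in sorted(ranks))
        p = _exact_two_sided_p(scaled, int(round(2 * w)))
        return TestResult(w, p, statistic_name="W")
    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(absd, return_counts=True)
    sigma2 -= float(((tie_counts ** 3 - tie_counts) / 48.0).sum())
    if sigma2 <= 0.0:
        return TestResult(w, 1.0, statistic_name="W", notes=("zero-variance",))
    shift = w - mu
    z = (shift - 0.5 * np.sign(shift)) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * _norm_dist.sf(abs(z))))
    return TestResult(w, p, statistic_name="W", notes=("normal-approx",))


def paired_signed_rank_tests(X, Y, mode: str = "auto"):
    """Row-wise Wilcoxon signed-rank tests for many features at once.

    ``X`` and ``Y`` are features x subjects paired matrices.  Tie-free
    rows with no zero differences share a cached exact distribution
    (n <= 25); remaining rows fall back to the scalar routine.  Returns
    (W, p) arrays.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValidationError("paired matrices must have equal shape")
    D = X - Y
    nfeat, n = D.shape
    W = np.empty(nfeat)
    P = np.empty(nfeat)
    A = np.abs(D)
    has_zero = (D == 0.0).any(axis=1)
    sortedA = np.sort(A, axis=1)
    has_tie = (np.diff(sortedA, axis=1) == 0.0).any(axis=1)
    clean = ~(has_zero | has_tie)
    if n <= 25 and mode in ("auto", "exact") and clean.any():
        idx = np.flatnonzero(clean)
        order = np.argsort(A[idx], axis=1)
        ranks = np.empty_like(order)
        arange = np.arange(1, n + 1)
        rows = np.arange(idx.size)[:, None]
        ranks[rows, order] = arange
        w = (ranks * (D[idx] > 0)).sum(axis=1)
        table = _exact_p_table(n)
        W[idx] = w
        P[idx] = table[w]
        rest = np.flatnonzero(~clean)
    else:
        rest = np.arange(nfeat)
    for i in rest:
        res = wilcoxon_signed_rank(X[i], Y[i], mode=mode)
        W[i] = res.statistic
        P[i] = res.p
    return W, P


def chi2_test(observed, expected="independence") -> TestResult:
    """Pearson chi-square test without continuity correction.

    ``observed`` is an r x c table (``expected='independence'``) or a
    count vector compared against ``expected`` counts or ``'uniform'``.
    Expected cells below 1 are flagged in ``notes`` rather than fatal.
    """
    O = np.asarray(observed, dtype=float)
    if np.any(O < 0):
        raise ValidationError("counts must be non-negative")
    total = O.sum()
    if total == 0:
        raise ValidationError("zero-total table")
    notes: list[str] = []
    if isinstance(expected, str) and expected == "independence":
        if O.ndim != 2:
            raise ValidationError("independence test needs a 2-D table")
        rows = O.sum(axis=1, keepdims=True)
        cols = O.sum(axis=0, keepdims=True)
        E = rows @ cols / total
        df = (O.shape[0] - 1) * (O.shape[1] - 1)
    elif isinstance(expected, str) and expected == "uniform":
        O = O.ravel()
        E = np.full_like(O, total / O.size)
        df = O.size - 1
    else:
        E = np.asarray(expected, dtype=float)
        if E.shape != O.shape:
            raise ValidationError("expected counts must match observed shape")
        if E.sum() > 0:
            E = E * (total / E.sum())
        df = O.size - 1
    if np.any(E <= 0):
        raise ValidationError("expected counts must be positive in every cell")
    if np.any(E < 1.0):
        notes.append("expected-cell-below-1")
    stat = float(((O - E) ** 2 / E).sum())
    if df <= 0:
        return TestResult(stat, 1.0, df=float(df), statistic_name="chi2",
                          notes=tuple(notes))
    p = float(_chi2_dist.sf(stat, df))
    return TestResult(stat, p, df=float(df), statistic_name="chi2",
                      notes=tuple(notes))


def correlation(x, y, method: str = "spearman") -> TestResult:
    """Correlation with t-approximation p-value (n - 2 df).

    ``spearman`` applies midranks to both vectors and then the Pearson
    formula.  Zero variance raises :class:`DegenerateInputError` so
    callers can skip the record with a warning.
    """
    if method not in ("spearman", "pearson"):
        raise ValidationError(f"unknown correlation method {method!r}")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError("vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("correlation inputs must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateInputError("zero variance; correlation undefined")
    if method == "spearman":
        x = _rankdata(x)
        y = _rankdata(y)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            raise DegenerateInputError("zero rank variance; correlation undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(min(1.0, 2.0 * _t_dist.sf(abs(t), n - 2)))
    return TestResult(r, p, df=float(n - 2), statistic_name="r", estimate=r)


def pca_top_components(X, k: int):
    """PCA of a feature x sample matrix after per-feature centering.

    Returns (sample scores of shape samples x k, explained-variance
    fractions over the first k components).  Scores carry a deterministic
    sign convention (largest-magnitude loading positive).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D (features x samples)")
    k = int(k)
    if k < 1 or k > min(X.shape):
        raise ValidationError(f"k={k} outside 1..min(dims)")
    Xc = X - X.mean(axis=1, keepdims=True)
    if np.allclose(Xc, 0.0):
        raise ValidationError("constant matrix; PCA undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: make the largest-|loading| entry of each left vector positive
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = (Vt[:k].T * S[:k])
    var = S ** 2
    evr = var[:k] / var.sum()
    return scores, evr
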