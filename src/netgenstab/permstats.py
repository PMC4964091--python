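"""Rank and permutation statistics used throughout the analysis.

Self-contained implementations with exact small-sample branches: the
two-sample Wilcoxon rank-sum test (exact null enumeration for small
tie-free samples, otherwise a tie- and continuity-corrected normal
approximation), Spearman and Pearson correlation, and the Mantel test of
association between two distance matrices (simultaneous row/column
permutations, exhaustive when the permutation group is small enough).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy.stats import norm, rankdata

EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class RankSumResult:
    W: float  # Mann-Whitney U of the first sample (R's W convention)
    p: float
    method: str  # "exact" or "normal-approx"
    n_a: int
    n_b: int
    alternative: str = "two-sided"

    def to_dict(self) -> dict:
        return {"W": self.W, "p": self.p, "method": self.method,
                "n_a": self.n_a, "n_b": self.n_b,
                "alternative": self.alternative}


@dataclass(frozen=True)
class MantelResult:
    rho: float
    p: float
    n_perm: int
    seed: int
    alternative: str = "greater"
    method: str = "permutation"  # "permutation" or "exact"

    def to_dict(self) -> dict:
        return {"rho": self.rho, "p": self.p, "n_perm": self.n_perm,
                "seed": self.seed, "alternative": self.alternative,
                "method": self.method}


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    rx = rankdata(x)
    ry = rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(rx, ry)[0, 1])


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def _exact_u_pvalue(ranks_a_sum: float, n_a: int, n_b: int, ranks: np.ndarray,
                    alternative: str) -> float:
    """Exact p by enumerating all assignments of ranks to the first sample."""
    n = n_a + n_b
    u_obs = ranks_a_sum - n_a * (n_a + 1) / 2
    total = math.comb(n, n_a)
    le = ge = 0
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    if alternative == "greater":
        return ge / total
    if alternative == "less":
        return le / total
    return min(1.0, 2.0 * min(le, ge) / total)


def rank_sum_test(a, b, alternative: str = "two-sided") -> RankSumResult:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null enumeration when n_a + n_b <= 12 with no ties; otherwise a
    normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    u = r_a - n_a * (n_a + 1) / 2
    has_ties = np.unique(pooled).size < n
    if n <= EXACT_RANKSUM_MAX_N and not has_ties:
        p = _exact_u_pvalue(r_a, n_a, n_b, ranks, alternative)
        return RankSumResult(u, p, "exact", n_a, n_b, alternative)
    mu = n_a * n_b / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    sigma = math.sqrt(max(sigma2, 1e-300))
    if alternative == "greater":
        z = (u - mu - 0.5) / sigma
        p = float(norm.sf(z))
    elif alternative == "less":
        z = (u - mu + 0.5) / sigma
        p = float(norm.cdf(z))
    else:
        cc = 0.5 * np.sign(u - mu)
        z = (u - mu - cc) / sigma if u != mu else 0.0
        p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return RankSumResult(u, p, "normal-approx", n_a, n_b, alternative)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diagonal(d), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def mantel_test(
    d1,
    d2,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    max_exact: int = 40320,
) -> MantelResult:
    """Mantel test: Spearman correlation of two distance matrices.

    The correlation is taken over the off-diagonal upper triangle, and the
    null distribution is built by permuting the rows and columns of one
    matrix simultaneously — this respects the network-like dependence of
    pairwise comparisons among the same set of years.  When the full
    permutation group is no larger than ``n_perm`` (and ``max_exact``), it
    is enumerated exhaustively; otherwise ``n_perm`` random permutations
    are drawn and the observed configuration is counted among them, so
    p >= 1 / (n_perm + 1).
    """
    d1 = _check_distance_matrix(d1, "d1")
    d2 = _check_distance_matrix(d2, "d2")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices must have the same shape")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n = d1.shape[0]
    iu = np.triu_indices(n, 1)
    v1 = d1[iu]
    rho_obs = spearman_rho(v1, d2[iu])

    def count_extreme(rho_p, ge, le, two):
        if rho_p >= rho_obs - 1e-12:
            ge += 1
        if rho_p <= rho_obs + 1e-12:
            le += 1
        if abs(rho_p) >= abs(rho_obs) - 1e-12:
            two += 1
        return ge, le, two

    n_fact = math.factorial(n)
    ge = le = two = 0
    if n_fact <= min(n_perm, max_exact):
        for perm in permutations(range(n)):
            idx = np.array(perm)
            rho_p = spearman_rho(v1, d2[np.ix_(idx, idx)][iu])
            ge, le, two = count_extreme(rho_p, ge, le, two)
        total = n_fact
        method = "exact"
    else:
        rng = np.random.default_rng(seed)
        ge, le, two = 1, 1, 1  # observed configuration counted in
        for _ in range(n_perm):
            idx = rng.permutation(n)
            rho_p = spearman_rho(v1, d2[np.ix_(idx, idx)][iu])
            ge, le, two = count_extreme(rho_p, ge, le, two)
        total = n_perm + 1
        method = "permutation"
    if alternative == "greater":
        p = ge / total
    elif alternative == "less":
        p = le / total
    else:
        p = two / total
    return MantelResult(rho_obs, min(1.0, p), n_perm, seed, alternative, method)
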