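"""Nonparametric statistics used throughout the pipeline.

All tests are implemented directly (hypergeometric enumeration, exact
permutation/sign-flip enumeration for small samples, tie-corrected normal
approximations otherwise) so that the exact/approximate switch, the
two-sided definition and the tie handling are explicit and testable.

Conventions
-----------
* Two-sided exact p for rank statistics: the probability, under the
  enumeration null, of an outcome at least as extreme as observed in
  ``|statistic - null mean|`` (the definition used by common biostatistics
  packages for small-sample rank tests).
* Ties receive midranks; variances are tie-corrected.
* Degenerate inputs (no variation) return p = 1 with ``degenerate=True``
  rather than raising, so batch screens do not abort.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import t as _tdist

from .errors import AnalysisError

__all__ = [
    "TestResult",
    "FdrResult",
    "PairwiseResult",
    "fisher_exact_2x2",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "kruskal_wallis",
    "friedman",
    "dunn_posthoc",
    "pearson",
    "bh_fdr",
]

_REL_TOL = 1e-12


@dataclass(frozen=True)
class TestResult:
    """Uniform record returned by every hypothesis test.

    Attributes
    ----------
    statistic : float
        U, W, H, Q, odds ratio or r depending on ``method``.
    p_value : float
        Two-sided p in [0, 1].
    method : str
        Label identifying the test.
    n_per_group : tuple of int
        Group sizes entering the test.
    exact : bool
        True when the p-value came from full enumeration rather than a
        large-sample approximation.
    degenerate : bool
        True when the data carried no information for the test (for
        example all paired differences zero); such results report p = 1.
    """

    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]
    exact: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (math.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise AnalysisError(f"p_value {self.p_value} outside [0, 1]")

    def as_record(self) -> dict:
        """Flat dict for TSV serialization."""
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p": self.p_value,
            "exact": self.exact,
            "degenerate": self.degenerate,
            "n_per_group": ";".join(str(n) for n in self.n_per_group),
        }


@dataclass(frozen=True)
class FdrResult:
    """Benjamini-Hochberg adjustment of a family of p-values."""

    p_values: tuple[float, ...]
    q_values: tuple[float, ...]


@dataclass(frozen=True)
class PairwiseResult:
    """One Dunn post-hoc comparison."""

    group_i: int
    group_j: int
    z: float
    p_value: float


def _as_1d(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise AnalysisError(f"{name} must be one-dimensional")
    if arr.size and not np.all(np.isfinite(arr)):
        raise AnalysisError(f"{name} contains non-finite values")
    return arr


def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(values.size, dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < values.size:
        j = i
        while j + 1 < values.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_sizes(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(values, return_counts=True)
    return counts[counts > 1]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose point probability does not exceed that of
    the observed table (within relative tolerance 1e-12). The statistic is
    the sample odds ratio ``ad / bc`` (infinite when ``bc == 0`` and
    ``ad > 0``).
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise AnalysisError("contingency cells must be nonnegative integers")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        raise AnalysisError("all four contingency cells are zero")
    r1, c1 = a + b, a + c
    # Support of the hypergeometric: feasible values of the top-left cell.
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    denom = math.comb(n, c1)
    probs = {
        k: math.comb(r1, k) * math.comb(n - r1, c1 - k) / denom
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    p = sum(pk for pk in probs.values() if pk <= p_obs * (1.0 + _REL_TOL))
    if p >= 1.0 - 1e-12:  # all tables included; absorb summation error
        p = 1.0
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return TestResult(
        statistic=odds,
        p_value=min(p, 1.0),
        method="fisher_exact",
        n_per_group=(r1, n - r1),
        exact=True,
    )


def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x, counting ties as 1/2."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    exact_threshold: int = 8,
    continuity_correction: bool = True,
) -> TestResult:
    """Two-sided Mann-Whitney U test for two unpaired groups.

    Exact by enumeration over all ``C(n+m, n)`` group assignments when both
    groups have at most ``exact_threshold`` observations and the pooled
    data are tie-free; otherwise a normal approximation with midranks,
    tie-corrected variance and (optionally) a 0.5 continuity correction.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    n, m = xa.size, ya.size
    if n == 0 or m == 0:
        raise AnalysisError("mann_whitney requires two nonempty groups")
    pooled = np.concatenate([xa, ya])
    ties = _tie_sizes(pooled)
    u = _mw_u(xa, ya)
    mu = n * m / 2.0

    if np.all(pooled == pooled[0]):
        return TestResult(u, 1.0, "mann_whitney", (n, m), exact=False, degenerate=True)

    if n <= exact_threshold and m <= exact_threshold and ties.size == 0:
        dev = abs(u - mu)
        count = 0
        total = 0
        idx = np.arange(n + m)
        for combo in itertools.combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(combo)] = True
            u_perm = _mw_u(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= dev - _REL_TOL:
                count += 1
        return TestResult(u, count / total, "mann_whitney", (n, m), exact=True)

    big_n = n + m
    tie_term = float(np.sum(ties**3 - ties))
    var = (n * m / 12.0) * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        return TestResult(u, 1.0, "mann_whitney", (n, m), exact=False, degenerate=True)
    dev = abs(u - mu)
    if continuity_correction:
        dev = max(dev - 0.5, 0.0)
    z = dev / math.sqrt(var)
    p = min(2.0 * _norm.sf(z), 1.0)
    return TestResult(u, p, "mann_whitney", (n, m), exact=False)


def wilcoxon_signed_rank(
    paired_a: Sequence[float],
    paired_b: Sequence[float],
    exact_threshold: int = 12,
    continuity_correction: bool = True,
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped before ranking. With at most
    ``exact_threshold`` nonzero differences the null distribution is
    enumerated over all sign patterns (midranks make this valid under
    magnitude ties); otherwise a tie-corrected normal approximation is
    used. If every difference is zero the result is p = 1 with the
    degenerate flag set.
    """
    a, b = _as_1d(paired_a, "paired_a"), _as_1d(paired_b, "paired_b")
    if a.size != b.size:
        raise AnalysisError("paired samples differ in length")
    if a.size < 2:
        raise AnalysisError("wilcoxon_signed_rank needs at least 2 pairs")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    n = nonzero.size
    n_pairs = a.size
    if n == 0:
        return TestResult(
            0.0, 1.0, "wilcoxon_signed_rank", (n_pairs,), exact=True, degenerate=True
        )
    ranks = _midranks(np.abs(nonzero))
    w = float(ranks[nonzero > 0].sum())
    total = float(ranks.sum())
    mu = total / 2.0

    if n <= exact_threshold:
        dev = abs(w - mu)
        # Vectorized sign-flip enumeration: rows of bits -> W values.
        patterns = np.arange(2**n)[:, None] >> np.arange(n)[None, :] & 1
        w_all = patterns @ ranks
        p = float(np.mean(np.abs(w_all - mu) >= dev - _REL_TOL))
        return TestResult(w, p, "wilcoxon_signed_rank", (n_pairs,), exact=True)

    var = float(np.sum(ranks**2)) / 4.0
    dev = abs(w - mu)
    if continuity_correction:
        dev = max(dev - 0.5, 0.0)
    z = dev / math.sqrt(var)
    # One-term Edgeworth refinement: the sign-flip null of W has excess
    # kurtosis kappa4/kappa2^2 = -2 sum(r^4) / (sum(r^2))^2, noticeable for
    # n just above the exact-enumeration threshold.
    gamma2 = -2.0 * float(np.sum(ranks**4)) / float(np.sum(ranks**2)) ** 2
    tail = _norm.sf(z) + _norm.pdf(z) * (gamma2 / 24.0) * (z**3 - 3.0 * z)
    p = min(max(2.0 * tail, 0.0), 1.0)
    return TestResult(w, p, "wilcoxon_signed_rank", (n_pairs,), exact=False)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction; p from chi-square(k-1)."""
    if len(groups) < 2:
        raise AnalysisError("kruskal_wallis needs at least 2 groups")
    arrs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if any(a.size == 0 for a in arrs):
        raise AnalysisError("kruskal_wallis groups must be nonempty")
    sizes = tuple(a.size for a in arrs)
    pooled = np.concatenate(arrs)
    big_n = pooled.size
    ranks = _midranks(pooled)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, 1.0, "kruskal_wallis", sizes, exact=False, degenerate=True)
    h = 0.0
    start = 0
    for sz in sizes:
        r_sum = ranks[start : start + sz].sum()
        h += r_sum**2 / sz
        start += sz
    h = 12.0 / (big_n * (big_n + 1)) * h - 3.0 * (big_n + 1)
    ties = _tie_sizes(pooled)
    correction = 1.0 - float(np.sum(ties**3 - ties)) / (big_n**3 - big_n)
    h /= correction
    p = float(_chi2.sf(h, len(sizes) - 1))
    return TestResult(h, p, "kruskal_wallis", sizes, exact=False)


def _friedman_q(rank_sums: np.ndarray, sq_sum: float, n: int, k: int) -> np.ndarray:
    """Tie-corrected Friedman statistic from column rank sums."""
    denom = sq_sum - n * k * (k + 1) ** 2 / 4.0
    num = (k - 1) * np.sum((rank_sums - n * (k + 1) / 2.0) ** 2, axis=-1)
    return num / denom


def friedman(blocks: Sequence[Sequence[float]], exact_bound: int = 12) -> TestResult:
    """Friedman test on a subjects x conditions matrix.

    Within-row midranks with tie correction; p from chi-square(k-1), or by
    full enumeration over all within-row rank permutations when
    ``n_subjects * n_conditions <= exact_bound``.
    """
    mat = np.asarray(blocks, dtype=float)
    if mat.ndim != 2:
        raise AnalysisError("friedman expects a 2-D subjects x conditions matrix")
    if not np.all(np.isfinite(mat)):
        raise AnalysisError("friedman matrix has missing or non-finite cells")
    n, k = mat.shape
    if n < 2 or k < 2:
        raise AnalysisError("friedman needs >= 2 subjects and >= 2 conditions")
    ranks = np.vstack([_midranks(row) for row in mat])
    sq_sum = float(np.sum(ranks**2))
    denom = sq_sum - n * k * (k + 1) ** 2 / 4.0
    if denom <= 0:  # every row constant
        return TestResult(0.0, 1.0, "friedman", (n, k), exact=False, degenerate=True)
    q = float(_friedman_q(ranks.sum(axis=0), sq_sum, n, k))

    if n * k <= exact_bound:
        # Enumerate all products of within-row permutations of the observed
        # row rank vectors; squared-rank sum is permutation-invariant.
        partial = np.zeros((1, k))
        for row in ranks:
            perms = np.array(list(set(itertools.permutations(row))))
            partial = (partial[:, None, :] + perms[None, :, :]).reshape(-1, k)
        q_all = _friedman_q(partial, sq_sum, n, k)
        p = float(np.mean(q_all >= q - _REL_TOL))
        return TestResult(q, p, "friedman", (n, k), exact=True)

    p = float(_chi2.sf(q, k - 1))
    return TestResult(q, p, "friedman", (n, k), exact=False)


def dunn_posthoc(
    groups: Sequence[Sequence[float]],
    comparisons: Sequence[tuple[int, int]],
    paired: bool = False,
) -> list[PairwiseResult]:
    """Dunn's post-hoc pairwise comparisons after an omnibus rank test.

    Unpaired: z-statistics on pooled-midrank means with tie-corrected
    variance (the Kruskal-Wallis follow-up). Paired: the Friedman-rank
    analogue on within-row ranks. Each two-sided p is multiplied by the
    number of requested comparisons (capped at 1).
    """
    if len(groups) < 2:
        raise AnalysisError("dunn_posthoc needs at least 2 groups")
    n_groups = len(groups)
    for i, j in comparisons:
        if not (0 <= i < n_groups and 0 <= j < n_groups):
            raise AnalysisError(f"comparison ({i}, {j}) names an unknown group")
    m = len(comparisons)
    results: list[PairwiseResult] = []

    if paired:
        # groups are per-condition vectors over the same subjects
        arrs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
        if len({a.size for a in arrs}) != 1:
            raise AnalysisError("paired groups must share subjects")
        mat = np.vstack(arrs).T
        n, k = mat.shape
        ranks = np.vstack([_midranks(row) for row in mat])
        mean_ranks = ranks.mean(axis=0)
        se = math.sqrt(k * (k + 1) / (6.0 * n))
        for i, j in comparisons:
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = min(2.0 * _norm.sf(abs(z)) * m, 1.0)
            results.append(PairwiseResult(i, j, z, p))
        return results

    arrs = [_as_1d(g, f"group {i}") for i, g in enumerate(groups)]
    if any(a.size == 0 for a in arrs):
        raise AnalysisError("dunn_posthoc groups must be nonempty")
    pooled = np.concatenate(arrs)
    big_n = pooled.size
    ranks = _midranks(pooled)
    ties = _tie_sizes(pooled)
    tie_term = float(np.sum(ties**3 - ties)) / (12.0 * (big_n - 1))
    base_var = big_n * (big_n + 1) / 12.0 - tie_term
    mean_ranks = []
    start = 0
    for a in arrs:
        mean_ranks.append(ranks[start : start + a.size].mean())
        start += a.size
    for i, j in comparisons:
        var = base_var * (1.0 / arrs[i].size + 1.0 / arrs[j].size)
        if var <= 0:
            results.append(PairwiseResult(i, j, 0.0, 1.0))
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / math.sqrt(var)
        p = min(2.0 * _norm.sf(abs(z)) * m, 1.0)
        results.append(PairwiseResult(i, j, z, p))
    return results


def pearson(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with a two-sided t-test p-value on n-2 df."""
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise AnalysisError("pearson inputs differ in length")
    n = xa.size
    if n < 3:
        raise AnalysisError("pearson needs n >= 3")
    sx, sy = xa.std(ddof=1), ya.std(ddof=1)
    if sx == 0 or sy == 0:
        return TestResult(math.nan, 1.0, "pearson", (n,), exact=False, degenerate=True)
    r = float(np.clip(np.corrcoef(xa, ya)[0, 1], -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _tdist.sf(abs(t), n - 2))
    return TestResult(r, min(p, 1.0), "pearson", (n,), exact=False)


def bh_fdr(p_values: Sequence[float]) -> FdrResult:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise AnalysisError("bh_fdr expects a nonempty 1-D p-value list")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise AnalysisError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return FdrResult(tuple(float(v) for v in p), tuple(float(v) for v in q))
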