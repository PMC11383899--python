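"""Shared fixtures and brute-force oracles for the test suite.

The oracles enumerate null distributions directly (all tables with fixed
margins, all group assignments, all sign patterns) and are kept independent
of the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from chemoscreen.simulate import SimulationConfig


# ---------------------------------------------------------------- oracles


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Enumerate every 2x2 table with the observed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    total = math.comb(n, c1)
    probs = []
    for k in range(0, min(r1, c1) + 1):
        if c1 - k > n - r1 or c1 - k < 0:
            continue
        probs.append((k, math.comb(r1, k) * math.comb(n - r1, c1 - k) / total))
    p_obs = dict(probs)[a]
    return sum(p for _, p in probs if p <= p_obs * (1 + 1e-12))


def oracle_mann_whitney_exact(x, y) -> float:
    """Enumerate all C(n+m, n) assignments of the pooled values to groups."""
    x, y = list(x), list(y)
    pooled = x + y
    n = len(x)

    def u_stat(xs, ys):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys)

    mu = n * len(y) / 2.0
    dev = abs(u_stat(x, y) - mu)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(combo)]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= dev - 1e-12:
            count += 1
    return count / total


def _midranks(vals):
    order = sorted(range(len(vals)), key=lambda i: vals[i])
    ranks = [0.0] * len(vals)
    i = 0
    while i < len(vals):
        j = i
        while j + 1 < len(vals) and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        for k in range(i, j + 1):
            ranks[order[k]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def oracle_wilcoxon_exact(diffs) -> float:
    """Enumerate all 2^n sign patterns over the nonzero differences."""
    d = [v for v in diffs if v != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = _midranks([abs(v) for v in d])
    w = sum(r for r, v in zip(ranks, d) if v > 0)
    mu = sum(ranks) / 2.0
    dev = abs(w - mu)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w_perm = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w_perm - mu) >= dev - 1e-12:
            count += 1
    return count / 2**n


def oracle_friedman_exact(matrix) -> float:
    """Enumerate products of within-row permutations of observed rank rows."""
    mat = [list(row) for row in matrix]
    n, k = len(mat), len(mat[0])
    rank_rows = [_midranks(row) for row in mat]
    sq = sum(r * r for row in rank_rows for r in row)
    denom = sq - n * k * (k + 1) ** 2 / 4.0

    def q_of(rows):
        sums = [sum(r[j] for r in rows) for j in range(k)]
        num = (k - 1) * sum((s - n * (k + 1) / 2.0) ** 2 for s in sums)
        return num / denom

    q_obs = q_of(rank_rows)
    count = total = 0
    perm_sets = [sorted(set(itertools.permutations(row))) for row in rank_rows]
    for combo in itertools.product(*perm_sets):
        total += 1
        if q_of(combo) >= q_obs - 1e-12:
            count += 1
    return count / total


def oracle_bh(pvals):
    """Step-up BH evaluated directly from its definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_idx, i in enumerate(order, start=1):
        candidates = [
            pvals[j] * m / (rank_j + 1)
            for rank_j, j in enumerate(order)
            if pvals[j] >= pvals[i] - 1e-15
        ]
        q[i] = min(1.0, min(candidates))
    return q


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=2024)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Scaled-down study for fast IO/pipeline tests."""
    return SimulationConfig(
        seed=11, n_tme_samples=10, n_cell_lines=5, n_hpv_positive=2,
        panel_size=20, n_genes=300, genes_per_signature=10,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
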