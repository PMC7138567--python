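"""Slow, independent reference implementations used to validate the package.

These deliberately use naive algorithms (triple loops, exhaustive path
enumeration, full hypergeometric-support enumeration) so they share no
code path with the implementations they check.
"""

from __future__ import annotations

import itertools
from math import comb, inf

import numpy as np


def tom_oracle(a: np.ndarray) -> np.ndarray:
    """Triple-loop topological overlap of an adjacency matrix."""
    a = np.asarray(a, dtype=float).copy()
    n = a.shape[0]
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1.0 - a[i, j])
    return tom


def _all_shortest_paths(costs: np.ndarray, s: int, t: int):
    """All minimum-cost simple paths s -> t by exhaustive enumeration."""
    n = costs.shape[0]
    best = inf
    paths: list[tuple[int, ...]] = []
    others = [v for v in range(n) if v not in (s, t)]
    for r in range(len(others) + 1):
        for mid in itertools.permutations(others, r):
            path = (s, *mid, t)
            cost = 0.0
            ok = True
            for u, v in zip(path[:-1], path[1:]):
                if costs[u, v] <= 0:
                    ok = False
                    break
                cost += costs[u, v]
            if not ok:
                continue
            if cost < best - 1e-12:
                best = cost
                paths = [path]
            elif abs(cost - best) <= 1e-12:
                paths.append(path)
    return best, paths


def betweenness_closeness_oracle(costs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive-path betweenness (pair-fraction sum, unordered pairs)
    and closeness 1/sum(dist) over reachable nodes."""
    n = costs.shape[0]
    betweenness = np.zeros(n)
    dist = np.full((n, n), inf)
    np.fill_diagonal(dist, 0.0)
    for s in range(n):
        for t in range(s + 1, n):
            best, paths = _all_shortest_paths(costs, s, t)
            if not paths:
                continue
            dist[s, t] = dist[t, s] = best
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                betweenness[v] += through / len(paths)
    closeness = np.zeros(n)
    for i in range(n):
        tot = sum(dist[i, j] for j in range(n) if j != i and np.isfinite(dist[i, j]))
        closeness[i] = 1.0 / tot if tot > 0 else 0.0
    return betweenness, closeness


def hypergeom_upper_tail_oracle(k: int, n_bg: int, big_k: int, n_q: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N=n_bg, K=big_k, n=n_q), by enumeration."""
    denom = comb(n_bg, n_q)
    total = 0
    for x in range(k, min(big_k, n_q) + 1):
        if n_q - x <= n_bg - big_k:
            total += comb(big_k, x) * comb(n_bg - big_k, n_q - x)
    return total / denom


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Probability-mass two-sided Fisher p by full support enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def exact_rank_p(scores: np.ndarray) -> np.ndarray:
    """Limit of the label-relabelling permutation p-value.

    Relabelling permutes the score vector, so for gene i,
    P(permuted score at i > observed_i) = #(genes with strictly higher
    score) / n_genes.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    out = np.zeros_like(scores)
    for j in range(scores.shape[1]):
        for i in range(n):
            out[i, j] = np.sum(scores[:, j] > scores[i, j]) / n
    return out


def hub_permutation_enumeration(scores: np.ndarray) -> np.ndarray:
    """Average the relabelling indicator over ALL n! permutations (n <= 7)."""
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    counts = np.zeros_like(scores)
    total = 0
    for perm in itertools.permutations(range(n)):
        counts += scores[list(perm)] > scores
        total += 1
    return counts / total


def preservation_stats_oracle(
    x_disc: np.ndarray, x_test: np.ndarray, a_disc: np.ndarray, a_test: np.ndarray
) -> dict[str, float]:
    """Direct recomputation of the seven preservation statistics.

    Takes raw (module genes x samples) expression of the module in each
    cohort plus the module's adjacency submatrices; uses SVD for the
    eigengene rather than the eigen-decomposition shortcut of the
    implementation under test.
    """

    def zscore(x):
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        return (x - mu) / sd

    def contribs(x):
        z = zscore(x)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        eig = vt[0]
        if eig @ z.mean(axis=0) < 0:
            eig = -eig
        return np.array([np.corrcoef(row, eig)[0, 1] for row in z])

    m = x_disc.shape[0]
    iu = np.triu_indices(m, k=1)
    cor_d = np.corrcoef(x_disc)[iu]
    cor_t = np.corrcoef(x_test)[iu]
    ad = a_disc.copy()
    at = a_test.copy()
    np.fill_diagonal(ad, 0.0)
    np.fill_diagonal(at, 0.0)
    k_d, k_t = ad.sum(axis=1), at.sum(axis=1)
    contrib_d = contribs(x_disc)
    contrib_t = contribs(x_test)
    return {
        "avg_weight": at[iu].mean(),
        "coherence": np.mean(contrib_t**2),
        "cor_cor": np.corrcoef(cor_d, cor_t)[0, 1],
        "cor_degree": np.corrcoef(k_d, k_t)[0, 1],
        "cor_contrib": np.corrcoef(contrib_d, contrib_t)[0, 1],
        "avg_cor": np.mean(cor_t * np.sign(cor_d)),
        "avg_contrib": np.mean(contrib_t * np.sign(contrib_d)),
    }
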