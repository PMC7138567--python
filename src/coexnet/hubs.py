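"""Hub-gene scoring and label-permutation significance testing.

Genes in a module are scored by five hub metrics: module membership
(correlation with the module eigengene), betweenness centrality,
closeness centrality, PageRank and Kleinberg's hub centrality, all
computed on the module's weighted adjacency submatrix without
normalization. Significance comes from a label-relabelling null: the
gene labels of the adjacency matrix are uniformly permuted and each
gene's score re-read at its label's new position, so
p(gene, score) = #(permuted score > observed) / n_perm (strict
inequality, no add-one term). Because relabelling conjugates the
adjacency matrix, the permuted score multiset equals the observed one,
and the p-value converges to the within-module rank of the gene's score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra
from scipy.sparse import csr_matrix
import networkx as nx

from .core import EigengeneProfile, ExpressionDataset

__all__ = [
    "ModuleGraph",
    "HubScoreTable",
    "hub_scores",
    "hub_permutation_test",
    "significant_hubs",
    "export_threshold_graph",
    "total_pairs",
]

SCORE_NAMES = ("mm", "betweenness", "closeness", "pagerank", "kleinberg")


@dataclass
class ModuleGraph:
    """Weighted module subnetwork (adjacency rows/columns of one module).

    ``edge_interpretation`` controls how weights enter path-based
    centralities: ``weight_as_cost`` uses the adjacency value directly
    as the edge cost (the default behaviour of common graph libraries
    when an adjacency is passed as weights), ``weight_as_strength``
    uses cost = 1/weight. Zero-weight edges are absent. Diagonal is
    ignored.
    """

    genes: list[str]
    weights: np.ndarray
    edge_interpretation: str = "weight_as_cost"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.genes)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square over genes")
        if not np.allclose(self.weights, self.weights.T, atol=1e-10):
            raise ValueError("weights must be symmetric")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if self.edge_interpretation not in ("weight_as_cost", "weight_as_strength"):
            raise ValueError(f"unknown edge_interpretation {self.edge_interpretation!r}")

    def off_diagonal(self) -> np.ndarray:
        w = self.weights.copy()
        np.fill_diagonal(w, 0.0)
        return w

    def costs(self) -> np.ndarray:
        """Edge-cost matrix for path metrics; 0 marks an absent edge."""
        w = self.off_diagonal()
        if self.edge_interpretation == "weight_as_cost":
            return w
        with np.errstate(divide="ignore"):
            c = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
        return c


@dataclass
class HubScoreTable:
    """Per-gene hub scores, permutation p-values and significance flags."""

    table: pd.DataFrame  # index gene_id; columns SCORE_NAMES, p_<score>, significant
    alpha: float = 0.01
    notes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def scores(self) -> np.ndarray:
        return self.table[list(SCORE_NAMES)].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def _path_metrics(g: ModuleGraph) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized betweenness and closeness on the weighted graph.

    Betweenness is Brandes shortest-path betweenness with edge costs;
    closeness(i) = 1 / sum_j dist(i, j). On a disconnected graph both
    are computed per connected component (with a warning).
    """
    n = len(g.genes)
    costs = g.costs()
    dist = dijkstra(csr_matrix(costs), directed=False)
    finite = np.isfinite(dist)
    if not finite.all():
        warnings.warn("module graph is disconnected; closeness computed per component", stacklevel=2)
    closeness = np.zeros(n)
    for i in range(n):
        s = dist[i][finite[i]].sum()
        closeness[i] = 1.0 / s if s > 0 else 0.0
    gx = nx.Graph()
    gx.add_nodes_from(range(n))
    ii, jj = np.where(np.triu(costs, k=1) > 0)
    gx.add_weighted_edges_from(
        (int(i), int(j), float(costs[i, j])) for i, j in zip(ii, jj)
    )
    bc = nx.betweenness_centrality(gx, weight="weight", normalized=False)
    betweenness = np.array([bc[i] for i in range(n)])
    return betweenness, closeness


def _pagerank(g: ModuleGraph, damping: float = 0.85) -> np.ndarray:
    w = g.off_diagonal()
    n = len(g.genes)
    gx = nx.Graph()
    gx.add_nodes_from(range(n))
    ii, jj = np.where(np.triu(w, k=1) > 0)
    gx.add_weighted_edges_from((int(i), int(j), float(w[i, j])) for i, j in zip(ii, jj))
    pr = nx.pagerank(gx, alpha=damping, weight="weight")
    return np.array([pr[i] for i in range(n)])


def _kleinberg(g: ModuleGraph) -> np.ndarray:
    """Hub score: principal eigenvector of the weight matrix, max scaled to 1.

    For an undirected graph hub and authority scores coincide.
    """
    w = g.off_diagonal()
    vals, vecs = np.linalg.eigh(w)
    v = vecs[:, -1]
    v = np.abs(v)
    m = v.max()
    return v / m if m > 0 else v


def hub_scores(
    g: ModuleGraph, ds: ExpressionDataset, eig: EigengeneProfile
) -> HubScoreTable:
    """Five hub scores for every gene of the module (p-values unfilled)."""
    if len(g.genes) < 3:
        raise ValueError("module must have >= 3 genes")
    sub = ds.subset(g.genes)
    z = sub.zscored()
    e = eig.values - eig.values.mean()
    en = np.linalg.norm(e)
    zn = np.linalg.norm(z, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mm = (z @ e) / (zn * en)
    mm = np.nan_to_num(mm, nan=0.0)
    betweenness, closeness = _path_metrics(g)
    pagerank = _pagerank(g)
    kleinberg = _kleinberg(g)
    table = pd.DataFrame(
        {
            "mm": mm,
            "betweenness": betweenness,
            "closeness": closeness,
            "pagerank": pagerank,
            "kleinberg": kleinberg,
        },
        index=pd.Index(g.genes, name="gene_id"),
    )
    for s in SCORE_NAMES:
        table[f"p_{s}"] = np.nan
    table["significant"] = False
    return HubScoreTable(table=table, notes=[f"edge_interpretation={g.edge_interpretation}"])


def hub_permutation_test(
    g: ModuleGraph,
    scores: HubScoreTable,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.01,
) -> HubScoreTable:
    """Label-relabelling permutation p-values for all five scores.

    Per permutation the gene labels of the adjacency are uniformly
    permuted; relabelling conjugates the matrix, so each score vector is
    simply permuted, and the observed score of gene i is compared to the
    score landing at its position. p = #(permuted > observed) / n_perm,
    strict inequality and no add-one term; a gene holding the unique
    maximum therefore gets p = 0 (reported as "< 1/n_perm" in
    human-readable output). Deterministic given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    s = scores.scores()  # genes x 5
    n = s.shape[0]
    # an all-tied score column (e.g. any centrality on a complete
    # equal-weight graph) yields p = 0 everywhere under the strict
    # inequality; tolerate numerical jitter when detecting the tie
    scale = np.maximum(np.abs(s).max(axis=0), 1.0)
    tied_cols = np.ptp(s, axis=0) <= 1e-10 * scale
    if tied_cols.any():
        tied = [SCORE_NAMES[j] for j in np.where(tied_cols)[0]]
        warnings.warn(f"all scores tied for {tied}; their p-values are all 0", stacklevel=2)
    rng = np.random.default_rng(seed)
    counts = np.zeros_like(s)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        counts += s[perm] > s
    p = counts / n_perm
    p[:, tied_cols] = 0.0
    table = scores.table.copy()
    for j, name in enumerate(SCORE_NAMES):
        table[f"p_{name}"] = p[:, j]
    table["significant"] = p.min(axis=1) < alpha
    return HubScoreTable(table=table, alpha=alpha, notes=list(scores.notes))


def significant_hubs(table: HubScoreTable, alpha: float = 0.01) -> list[str]:
    """Genes with any score p-value below ``alpha``, sorted by min p then ID."""
    if len(table.table) == 0:
        return []
    pcols = [f"p_{s}" for s in SCORE_NAMES]
    p = table.table[pcols].to_numpy(dtype=float)
    if np.isnan(p).all():
        raise ValueError("p-values not filled; run hub_permutation_test first")
    min_p = np.nanmin(p, axis=1)
    hits = [
        (mp, g) for mp, g in zip(min_p, table.table.index) if mp < alpha
    ]
    return [g for _, g in sorted(hits)]


def total_pairs(n: int, convention: str = "upper_with_diagonal") -> int:
    """Total pair count of an n-node module under a stated convention.

    ``upper_with_diagonal``: n(n+1)/2 unordered pairs including self
    pairs; ``ordered``: n^2 ordered pairs.
    """
    if convention == "upper_with_diagonal":
        return n * (n + 1) // 2
    if convention == "ordered":
        return n * n
    raise ValueError(f"unknown convention {convention!r}")


def export_threshold_graph(
    am_values: np.ndarray,
    genes: list[str],
    cutoff: float,
    path,
    convention: str = "upper_with_diagonal",
) -> dict:
    """Write an edge list of adjacency entries above ``cutoff``.

    The summary line counts kept edges against the module's total pair
    count under the stated convention (default upper triangle including
    the diagonal, n(n+1)/2).
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    am_values = np.asarray(am_values, dtype=float)
    n = len(genes)
    total = total_pairs(n, convention)
    kept = 0
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for i in range(n):
            for j in range(i + 1, n):
                if am_values[i, j] > cutoff:
                    fh.write(f"{genes[i]}\t{genes[j]}\t{am_values[i, j]:.6g}\n")
                    kept += 1
        fh.write(f"# kept {kept} of {total} edges ({convention}); {n} nodes\n")
    return {"kept": kept, "total": total, "n_nodes": n, "convention": convention}
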