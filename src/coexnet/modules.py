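"""Module detection on the topological overlap network.

Modules are detected by average-linkage hierarchical clustering of the
TOM dissimilarity (1 - TOM), followed by a dynamic hybrid tree cut
(branch carving controlled by ``deep_split`` and ``min_module_size``),
eigengene-based merging of near-identical modules, and a k-means style
refinement that reassigns genes to the nearest module eigengene.

The hybrid cut here is a contract-level reimplementation of the standard
dynamic tree cut: branches qualify as modules when their internal merge
heights (core scatter) are low and the gap to the height at which they
join the rest of the tree is large, with the sensitivity thresholds
interpolated from ``deep_split`` exactly as in the reference method.
Unassigned genes are then attached to the closest module by average TOM
dissimilarity if they are as close as the module's own core; otherwise
they stay unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import (
    UNASSIGNED,
    EigengeneProfile,
    ExpressionDataset,
    ModuleAssignment,
    TOMMatrix,
)

__all__ = [
    "Dendrogram",
    "hierarchical_tree",
    "dynamic_hybrid_cut",
    "module_eigengene",
    "merge_close_modules",
    "kmeans_refine",
]

# deep_split in 0..4 -> maximum relative core scatter of an acceptable branch;
# the minimum relative gap is (1 - max core scatter) * 3/4. Higher deep_split
# tolerates looser branches and so produces more, smaller modules.
_MAX_CORE_SCATTER = (0.64, 0.73, 0.82, 0.91, 0.95)


@dataclass
class Dendrogram:
    """Agglomerative merge tree in scipy linkage form.

    ``linkage_matrix`` has one row per merge: (cluster_i, cluster_j,
    height, size). Heights are non-decreasing for average linkage on a
    metric dissimilarity.
    """

    genes: list[str]
    linkage_matrix: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.genes)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def merges(self) -> list[tuple[int, int, float]]:
        return [
            (int(a), int(b), float(h))
            for a, b, h, _ in self.linkage_matrix
        ]


def hierarchical_tree(tom: TOMMatrix) -> Dendrogram:
    """Average-linkage clustering of TOM dissimilarity (1 - TOM)."""
    if tom.n_genes < 2:
        raise ValueError("need >= 2 genes to build a dendrogram")
    d = tom.dissimilarity()
    z = linkage(squareform(d, checks=False), method="average")
    return Dendrogram(genes=list(tom.genes), linkage_matrix=z)


class _Tree:
    """Flattened subtree bookkeeping for the hybrid cut."""

    def __init__(self, dend: Dendrogram):
        n = dend.n_leaves
        z = dend.linkage_matrix
        self.n = n
        self.height = np.zeros(2 * n - 1)
        self.children: list[tuple[int, int] | None] = [None] * (2 * n - 1)
        self.leaves: list[list[int]] = [[i] for i in range(n)] + [[] for _ in range(n - 1)]
        # sum/count of internal merge heights per subtree, for core scatter
        self._hsum = np.zeros(2 * n - 1)
        self._hcnt = np.zeros(2 * n - 1, dtype=int)
        for m in range(n - 1):
            a, b, h = int(z[m, 0]), int(z[m, 1]), float(z[m, 2])
            node = n + m
            self.height[node] = h
            self.children[node] = (a, b)
            self.leaves[node] = self.leaves[a] + self.leaves[b]
            self._hsum[node] = self._hsum[a] + self._hsum[b] + h
            self._hcnt[node] = self._hcnt[a] + self._hcnt[b] + 1
        self.root = 2 * n - 2

    def size(self, node: int) -> int:
        return len(self.leaves[node])

    def core_scatter(self, node: int) -> float:
        """Mean internal merge height of the subtree; 0 for a leaf."""
        if self._hcnt[node] == 0:
            return 0.0
        return float(self._hsum[node] / self._hcnt[node])


def dynamic_hybrid_cut(
    dend: Dendrogram,
    tom: TOMMatrix,
    deep_split: int = 3,
    min_module_size: int = 10,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Two-stage dynamic hybrid cut of the TOM dendrogram.

    Stage 1 carves branches whose core scatter is below, and whose gap to
    the joining height is above, thresholds interpolated from
    ``deep_split``; branches smaller than ``min_module_size`` are
    dissolved. Stage 2 attaches leftover genes to the nearest module by
    average TOM dissimilarity when they lie within the module's own
    scatter; the rest stay unassigned.
    """
    if not 0 <= deep_split <= 4:
        raise ValueError(f"deep_split must be in 0..4, got {deep_split}")
    if min_module_size < 2:
        raise ValueError(f"min_module_size must be >= 2, got {min_module_size}")
    if list(dend.genes) != list(tom.genes):
        raise ValueError("dendrogram and TOM gene lists differ")

    tree = _Tree(dend)
    heights = dend.heights
    hmax = float(heights.max())
    ref = float(np.quantile(heights, 0.05))
    if cut_height is None:
        cut_height = ref + 0.99 * (hmax - ref)
    span = cut_height - ref
    if span <= 0 or np.ptp(heights) == 0:
        warnings.warn("no height structure in dendrogram: all genes unassigned", stacklevel=2)
        return ModuleAssignment(
            labels={g: UNASSIGNED for g in dend.genes}, provenance="initial"
        )
    mcs = _MAX_CORE_SCATTER[deep_split]
    max_abs_core_scatter = ref + mcs * span
    min_abs_gap = (1.0 - mcs) * 0.75 * span

    clusters: list[list[int]] = []

    def carve(node: int, join_height: float) -> list[list[int]]:
        """Return accepted clusters (leaf-index lists) within ``node``."""
        if tree.size(node) < min_module_size:
            return []
        cs = tree.core_scatter(node)
        gap = join_height - cs
        kids = tree.children[node]
        if cs <= max_abs_core_scatter and gap >= min_abs_gap and gap > 0:
            # qualifying branch; split further only if both children
            # independently qualify at this node's own merge height
            if kids is not None:
                a, b = kids
                if (
                    tree.size(a) >= min_module_size
                    and tree.size(b) >= min_module_size
                ):
                    left = carve(a, tree.height[node])
                    right = carve(b, tree.height[node])
                    if left and right:
                        return left + right
            return [list(tree.leaves[node])]
        if kids is None:
            return []
        a, b = kids
        h = tree.height[node]
        return carve(a, h) + carve(b, h)

    # components below the static cut, each carved with its joining height
    def components(node: int, parent_height: float):
        if tree.height[node] <= cut_height:
            clusters.extend(carve(node, parent_height))
        else:
            a, b = tree.children[node]
            components(a, tree.height[node])
            components(b, tree.height[node])

    components(tree.root, hmax)

    labels = {g: UNASSIGNED for g in dend.genes}
    # label clusters in decreasing-size order for stability
    clusters.sort(key=lambda c: (-len(c), c[0]))
    for m, members in enumerate(clusters):
        for i in members:
            labels[dend.genes[i]] = f"M{m + 1}"

    # stage 2: attach leftover genes that lie within a module's own scatter
    if clusters:
        d = tom.dissimilarity()
        cluster_idx = [np.array(c) for c in clusters]
        thresholds = []
        for c in cluster_idx:
            sub = d[np.ix_(c, c)]
            within = sub[np.triu_indices(len(c), k=1)]
            thresholds.append(
                min(float(within.mean() + 3.0 * within.std()), max_abs_core_scatter)
            )
        assigned = set(i for c in clusters for i in c)
        for i in range(tree.n):
            if i in assigned:
                continue
            dists = np.array([d[i, c].mean() for c in cluster_idx])
            best = int(np.argmin(dists))
            if dists[best] <= thresholds[best]:
                labels[dend.genes[i]] = f"M{best + 1}"

    return ModuleAssignment(labels=labels, provenance="initial")


def module_eigengene(ds: ExpressionDataset, genes: list[str], module: str = "") -> EigengeneProfile:
    """First principal component of the module's z-scored expression.

    Genes are standardized across samples; the eigengene is the leading
    right singular vector (one value per sample, unit norm), oriented so
    its correlation with the mean standardized profile is non-negative.
    ``variance_explained`` is the leading squared singular value over the
    total. Zero-variance genes are dropped with a warning.
    """
    if len(genes) < 2:
        raise ValueError("need >= 2 genes for an eigengene")
    if ds.n_samples < 3:
        raise ValueError("need >= 3 samples for an eigengene")
    sub = ds.subset(genes)
    spread = np.ptp(sub.values, axis=1)
    if np.any(spread == 0):
        dropped = [g for g, s in zip(sub.genes, spread) if s == 0]
        warnings.warn(f"dropping {len(dropped)} zero-variance genes from eigengene", stacklevel=2)
        keep = [g for g in sub.genes if g not in set(dropped)]
        if len(keep) == 0:
            raise ValueError("all genes have zero variance")
        sub = sub.subset(keep)
    z = sub.zscored()
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    eig = vt[0]
    total = float((s**2).sum())
    ve = float(s[0] ** 2 / total) if total > 0 else 0.0
    mean_profile = z.mean(axis=0)
    if float(eig @ mean_profile) < 0:
        eig = -eig
    return EigengeneProfile(
        module=module, samples=list(ds.samples), values=eig, variance_explained=ve
    )


def eigengene_matrix(
    ds: ExpressionDataset, assign: ModuleAssignment
) -> tuple[list[str], np.ndarray]:
    """Eigengenes of all modules as (labels, n_samples x n_modules array)."""
    mods = assign.modules()
    labels = sorted(mods)
    cols = [module_eigengene(ds, mods[m], module=m).values for m in labels]
    return labels, np.column_stack(cols) if cols else np.empty((ds.n_samples, 0))


def merge_close_modules(
    assign: ModuleAssignment, ds: ExpressionDataset, cut_height: float = 0.05
) -> ModuleAssignment:
    """Merge modules whose eigengenes are nearly collinear.

    Eigengenes are clustered by dissimilarity 1 - correlation with
    average linkage; all modules joined below ``cut_height`` (i.e.
    eigengene correlation above 1 - cut_height) merge into the label of
    the largest constituent. Repeats until no merge occurs; module count
    strictly decreases each round, so this terminates.
    """
    if assign.n_modules() == 0:
        raise ValueError("no modules to merge")
    labels = dict(assign.labels)
    while True:
        current = ModuleAssignment(labels=labels, provenance="merged")
        mods = current.modules()
        if len(mods) <= 1:
            break
        names, e = eigengene_matrix(ds, current)
        corr = np.corrcoef(e.T)
        diss = np.clip(1.0 - corr, 0.0, None)
        np.fill_diagonal(diss, 0.0)
        z = linkage(squareform(diss, checks=False), method="average")
        groups = fcluster(z, t=cut_height, criterion="distance")
        if len(set(groups)) == len(names):
            break
        for gid in set(groups):
            members = [names[i] for i in range(len(names)) if groups[i] == gid]
            if len(members) < 2:
                continue
            target = max(members, key=lambda m: (len(mods[m]), m))
            for m in members:
                if m == target:
                    continue
                for g in mods[m]:
                    labels[g] = target
    return ModuleAssignment(labels=labels, provenance="merged")


def kmeans_refine(
    assign: ModuleAssignment, ds: ExpressionDataset, max_iter: int = 30
) -> ModuleAssignment:
    """k-means style refinement with eigengene centroids.

    k equals the current module count; centroids are module eigengenes
    and the distance is 1 - correlation(gene profile, eigengene). Each
    iteration reassigns every assigned gene to its nearest centroid and
    recomputes eigengenes, stopping when no gene moves or ``max_iter``
    is reached. Unassigned genes do not participate. The summed distance
    objective is kept non-increasing: an iteration that would increase
    it is rolled back and iteration stops.
    """
    if assign.n_modules() == 0:
        raise ValueError("no modules to refine")
    labels = dict(assign.labels)
    if max_iter == 0:
        return ModuleAssignment(labels=labels, provenance="kmeans_refined")

    gene_list = [g for g, lab in labels.items() if lab != UNASSIGNED]
    z = ds.subset(gene_list).zscored()
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    zn = z / norms

    def distances(current: ModuleAssignment) -> tuple[list[str], np.ndarray]:
        names, e = eigengene_matrix(ds, current)
        en = e / np.linalg.norm(e, axis=0, keepdims=True)
        return names, 1.0 - zn @ en  # genes x modules

    def objective(dist: np.ndarray, names: list[str], cur_labels: dict[str, str]) -> float:
        col = {m: j for j, m in enumerate(names)}
        total = 0.0
        for i, g in enumerate(gene_list):
            lab = cur_labels[g]
            if lab != UNASSIGNED:
                total += float(dist[i, col[lab]])
        return total

    names, dist = distances(ModuleAssignment(labels=labels))
    prev_obj = objective(dist, names, labels)
    for _ in range(max_iter):
        col = {m: j for j, m in enumerate(names)}
        moved = False
        new_labels = dict(labels)
        for i, g in enumerate(gene_list):
            if labels[g] == UNASSIGNED:
                continue  # dropped in an earlier round; stays out
            j_best = int(np.argmin(dist[i]))
            # keep the current module on exact ties
            j_cur = col[labels[g]]
            if dist[i, j_best] < dist[i, j_cur] - 1e-12:
                new_labels[g] = names[j_best]
                moved = True
        if not moved:
            break
        counts = ModuleAssignment(labels=new_labels).sizes()
        emptied = [m for m in names if counts.get(m, 0) < 2]
        if emptied:
            warnings.warn(f"modules emptied during refinement: {emptied}", stacklevel=2)
            for g in gene_list:
                if new_labels[g] in emptied:
                    new_labels[g] = UNASSIGNED
        if ModuleAssignment(labels=new_labels).n_modules() == 0:
            break
        names, dist = distances(ModuleAssignment(labels=new_labels))
        new_obj = objective(dist, names, new_labels)
        if new_obj > prev_obj + 1e-9:
            # eigengene recomputation would increase the objective: roll back
            names, dist = distances(ModuleAssignment(labels=labels))
            break
        assert new_obj <= prev_obj + 1e-9, "refinement objective increased"
        labels = new_labels
        prev_obj = new_obj
    return ModuleAssignment(labels=labels, provenance="kmeans_refined")
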