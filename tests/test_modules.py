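import warnings

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from coexnet.core import UNASSIGNED, ExpressionDataset, ModuleAssignment, TOMMatrix
from coexnet.modules import (
    dynamic_hybrid_cut,
    hierarchical_tree,
    kmeans_refine,
    merge_close_modules,
    module_eigengene,
)


def _tom_from_blocks(block_sizes, within, between, n_total=None):
    """Block-constant TOM-like similarity matrix."""
    n = n_total or sum(block_sizes)
    t = np.full((n, n), between)
    pos = 0
    for size in block_sizes:
        t[pos : pos + size, pos : pos + size] = within
        pos += size
    np.fill_diagonal(t, 1.0)
    return TOMMatrix(genes=[f"g{i:03d}" for i in range(n)], values=t)


def _ds(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i:03d}" for i in range(values.shape[0])]
    return ExpressionDataset(
        genes=genes, samples=[f"s{j}" for j in range(values.shape[1])], values=values
    )


class TestHierarchicalTree:
    def test_identical_genes_merge_first_at_height_zero(self):
        t = np.array(
            [
                [1.0, 1.0, 0.2, 0.1],
                [1.0, 1.0, 0.2, 0.1],
                [0.2, 0.2, 1.0, 0.3],
                [0.1, 0.1, 0.3, 1.0],
            ]
        )
        dend = hierarchical_tree(TOMMatrix(genes=list("abcd"), values=t))
        a, b, h = dend.merges()[0]
        assert {a, b} == {0, 1}
        assert h == pytest.approx(0.0)

    def test_tight_pairs_merge_before_cross_merge(self):
        # two tight pairs (dissimilarity 0.1 within, 0.9 across):
        # average linkage joins both pairs at 0.1, then everything at 0.9
        t = np.full((4, 4), 0.1)
        t[0:2, 0:2] = 0.9
        t[2:4, 2:4] = 0.9
        np.fill_diagonal(t, 1.0)
        dend = hierarchical_tree(TOMMatrix(genes=list("abcd"), values=t))
        merges = dend.merges()
        assert merges[0][2] == pytest.approx(0.1)
        assert merges[1][2] == pytest.approx(0.1)
        assert merges[2][2] == pytest.approx(0.9)
        assert {merges[0][0], merges[0][1]} in ({0, 1}, {2, 3})

    def test_equidistant_triple_is_deterministic(self):
        t = np.full((3, 3), 0.5)
        np.fill_diagonal(t, 1.0)
        tom = TOMMatrix(genes=list("abc"), values=t)
        z1 = hierarchical_tree(tom).linkage_matrix
        z2 = hierarchical_tree(tom).linkage_matrix
        np.testing.assert_array_equal(z1, z2)

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_tree(TOMMatrix(genes=["a"], values=np.ones((1, 1))))


class TestDynamicHybridCut:
    def test_three_planted_blocks_recovered_exactly(self):
        tom = _tom_from_blocks([30, 30, 30], within=0.8, between=0.05)
        dend = hierarchical_tree(tom)
        assign = dynamic_hybrid_cut(dend, tom)
        truth = [i // 30 for i in range(90)]
        found = [assign.labels[g] for g in tom.genes]
        assert assign.n_modules() == 3
        assert adjusted_rand_score(truth, found) == pytest.approx(1.0)

    def test_structureless_matrix_leaves_all_unassigned(self):
        t = np.full((40, 40), 0.5)
        np.fill_diagonal(t, 1.0)
        tom = TOMMatrix(genes=[f"g{i}" for i in range(40)], values=t)
        with pytest.warns(UserWarning, match="no height structure"):
            assign = dynamic_hybrid_cut(hierarchical_tree(tom), tom)
        assert all(lab == UNASSIGNED for lab in assign.labels.values())

    def test_block_below_min_size_not_reported_as_module(self):
        tom = _tom_from_blocks([30, 5], within=0.8, between=0.05, n_total=60)
        assign = dynamic_hybrid_cut(hierarchical_tree(tom), tom, min_module_size=10)
        sizes = assign.sizes()
        assert all(s >= 10 for s in sizes.values())
        small_block = tom.genes[30:35]
        mods = assign.modules()
        assert not any(set(small_block) == set(v) for v in mods.values())

    def test_min_module_size_below_two_rejected(self):
        tom = _tom_from_blocks([20], within=0.8, between=0.05, n_total=30)
        with pytest.raises(ValueError):
            dynamic_hybrid_cut(hierarchical_tree(tom), tom, min_module_size=1)

    def test_invalid_deep_split_rejected(self):
        tom = _tom_from_blocks([20], within=0.8, between=0.05, n_total=30)
        with pytest.raises(ValueError):
            dynamic_hybrid_cut(hierarchical_tree(tom), tom, deep_split=5)


class TestModuleEigengene:
    def test_rank_one_module_fully_explained(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        # affine copies of one profile share a single z-scored direction
        eig = module_eigengene(_ds(np.vstack([2 * base + 1, 3 * base, base])), ["g000", "g001", "g002"])
        assert eig.variance_explained == pytest.approx(1.0)
        z = (base - base.mean()) / base.std()
        zn = z / np.linalg.norm(z)
        np.testing.assert_allclose(np.abs(eig.values), np.abs(zn), atol=1e-10)

    def test_orientation_follows_mean_profile(self, rng):
        vals = rng.normal(size=(10, 30))
        eig = module_eigengene(_ds(vals), [f"g{i:03d}" for i in range(10)])
        z = _ds(vals).zscored()
        assert float(np.corrcoef(eig.values, z.mean(axis=0))[0, 1]) >= 0 or np.allclose(
            z.mean(axis=0), 0
        )

    def test_negation_pair_fully_explained_with_opposite_signs(self):
        base = np.array([0.3, -1.2, 0.8, 2.0, -0.7])
        ds = _ds(np.vstack([base, -base]))
        eig = module_eigengene(ds, ["g000", "g001"])
        assert eig.variance_explained == pytest.approx(1.0)
        z = ds.zscored()
        r0 = np.corrcoef(z[0], eig.values)[0, 1]
        r1 = np.corrcoef(z[1], eig.values)[0, 1]
        assert sorted([round(r0, 6), round(r1, 6)]) == [-1.0, 1.0]

    def test_zero_variance_gene_dropped_with_warning(self, rng):
        vals = rng.normal(size=(3, 10))
        vals[1] = 4.2
        with pytest.warns(UserWarning, match="zero-variance"):
            eig = module_eigengene(_ds(vals), ["g000", "g001", "g002"])
        assert eig.values.shape == (10,)

    def test_all_zero_variance_is_error(self):
        vals = np.ones((2, 5))
        with pytest.raises(ValueError):
            module_eigengene(_ds(vals), ["g000", "g001"])


class TestMergeCloseModules:
    def _two_modules_from_factors(self, shared: bool, rng, n_samples=500):
        u1 = rng.standard_normal(n_samples)
        u2 = u1 if shared else rng.standard_normal(n_samples)
        vals = np.vstack(
            [0.8 * u1 + 0.2 * rng.standard_normal(n_samples) for _ in range(10)]
            + [0.8 * u2 + 0.2 * rng.standard_normal(n_samples) for _ in range(10)]
        )
        genes = [f"g{i:03d}" for i in range(20)]
        ds = ExpressionDataset(genes=genes, samples=[f"s{j}" for j in range(n_samples)], values=vals)
        assign = ModuleAssignment(
            labels={g: ("A" if i < 10 else "B") for i, g in enumerate(genes)}
        )
        return ds, assign

    def test_same_factor_modules_merge(self, rng):
        ds, assign = self._two_modules_from_factors(shared=True, rng=rng)
        merged = merge_close_modules(assign, ds)
        assert merged.n_modules() == 1

    def test_independent_factor_modules_stay_separate(self, rng):
        ds, assign = self._two_modules_from_factors(shared=False, rng=rng)
        merged = merge_close_modules(assign, ds)
        assert merged.n_modules() == 2

    def test_single_module_is_identity(self, rng):
        ds, assign = self._two_modules_from_factors(shared=False, rng=rng)
        one = ModuleAssignment(labels={g: "A" for g in ds.genes})
        merged = merge_close_modules(one, ds)
        assert merged.labels == one.labels

    def test_merged_label_is_largest_constituent(self, rng):
        u = rng.standard_normal(400)
        vals = np.vstack([0.9 * u + 0.1 * rng.standard_normal(400) for _ in range(15)])
        genes = [f"g{i:03d}" for i in range(15)]
        ds = ExpressionDataset(genes=genes, samples=[f"s{j}" for j in range(400)], values=vals)
        assign = ModuleAssignment(
            labels={g: ("BIG" if i < 10 else "SMALL") for i, g in enumerate(genes)}
        )
        merged = merge_close_modules(assign, ds)
        assert set(merged.labels.values()) == {"BIG"}


class TestKmeansRefine:
    def test_max_iter_zero_only_updates_provenance(self, small_pair):
        cfg, ds_a, _, truth = small_pair
        assign = ModuleAssignment(labels=dict(truth.true_assignment))
        out = kmeans_refine(assign, ds_a, max_iter=0)
        assert out.labels == assign.labels
        assert out.provenance == "kmeans_refined"

    def test_truth_assignment_is_a_fixed_point(self, small_pair):
        cfg, ds_a, _, truth = small_pair
        assign = ModuleAssignment(labels=dict(truth.true_assignment))
        out = kmeans_refine(assign, ds_a)
        moved = sum(out.labels[g] != assign.labels[g] for g in ds_a.genes)
        assert moved <= 2  # ground truth is (near-)optimal under the distance

    def test_misplaced_gene_returns_to_its_factor_module(self, small_pair):
        cfg, ds_a, _, truth = small_pair
        labels = dict(truth.true_assignment)
        mods = ModuleAssignment(labels=labels).modules()
        names = sorted(mods)
        victim = mods[names[0]][0]
        labels[victim] = names[1]  # mislabel one gene
        out = kmeans_refine(ModuleAssignment(labels=labels), ds_a)
        assert out.labels[victim] == names[0]

    def test_no_modules_rejected(self, small_pair):
        _, ds_a, _, _ = small_pair
        empty = ModuleAssignment(labels={g: UNASSIGNED for g in ds_a.genes})
        with pytest.raises(ValueError):
            kmeans_refine(empty, ds_a)


def test_end_to_end_recovery_single_seed(default_pair, default_networks):
    """Full detection chain recovers the planted partition in cohort A."""
    from coexnet.network import topological_overlap

    _, ds_a, _, truth = default_pair
    am_a, _ = default_networks
    tom = topological_overlap(am_a)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assign = dynamic_hybrid_cut(hierarchical_tree(tom), tom)
        assign = kmeans_refine(merge_close_modules(assign, ds_a), ds_a)
    truth_labels = [truth.true_assignment[g] for g in ds_a.genes]
    found = [assign.labels[g] for g in ds_a.genes]
    assert adjusted_rand_score(truth_labels, found) >= 0.9
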