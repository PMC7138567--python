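# coexnet

Weighted gene co-expression network analysis for two-cohort studies:
per-cohort network construction, module detection, cross-cohort module
preservation testing, and hub-gene significance.

## The problem

Case/control transcriptome studies often ask not just *which genes
change*, but *which regulatory programs fall apart* in disease. A
co-expression module — a cluster of genes whose expression co-varies
across samples — that exists in the disease network but whose internal
correlation structure is absent from the healthy network (or vice
versa) points at a disrupted program, and the most central genes of
such a module are natural candidate drivers or biomarkers. `coexnet`
implements that full analysis for gene-level expression matrices (one
per cohort), plus a synthetic-data generator with planted ground truth
so every stage can be validated end to end without external downloads.

## The method

1. **Network construction.** Pairwise Pearson correlations r_ij are
   soft-thresholded into an adjacency, a_ij = |r_ij|^β (unsigned,
   default) or ((1+r_ij)/2)^β (signed). β is the smallest power whose
   connectivity distribution reaches a scale-free fit of signed
   R² ≥ 0.85 (the fit regresses log10 frequency on log10 connectivity
   over binned connectivities, sign-flipped by slope). The adjacency is
   converted to a topological overlap matrix,
   TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
   with l_ij = Σ_u a_iu a_uj and k_i = Σ_j a_ij, crediting shared
   neighbours as well as direct connection strength.
2. **Module detection.** Average-linkage clustering of 1 − TOM, a
   dynamic hybrid tree cut (deepSplit 3, minimum module size 10),
   merging of modules whose eigengenes correlate above 0.95, and a
   k-means refinement step that reassigns genes to the nearest module
   eigengene (distance 1 − correlation) until convergence.
3. **Preservation testing.** Each discovery module is scored in the
   test cohort by seven statistics — mean adjacency, eigengene
   coherence, the concordances of correlation / intramodular degree /
   node contribution, and sign-aware mean correlation and contribution.
   10,000 random same-size gene sets form the permutation null;
   with the one-sided "less" alternative, a module with all seven
   p < 0.05 is called **non-preserved**. The add-one estimator
   p = (s+1)/(n+1) has floor 1/10001 ≈ 9.99E-5.
4. **Hub detection.** Genes of non-preserved modules are scored by
   module membership, betweenness, closeness, PageRank and Kleinberg's
   hub centrality on the module's weighted adjacency; significance
   comes from relabelling the adjacency's gene labels 1000 times
   (p = fraction of permuted scores exceeding the observed, strict);
   a gene with any score p < 0.01 is a significant hub.
5. **Annotation statistics.** Hypergeometric over-representation of
   module genes in GMT gene-set libraries, a two-sided Fisher exact
   test for GWAS-gene enrichment in non-preserved modules, and the
   eQTL-filtered (p < 1e-4, frequency > 0.10, both strict)
   gene→SNP→miRNA join with cross-disease SNP overlap.

## Worked example

```python
from coexnet.simulate import SyntheticConfig, generate_cohort_pair
from coexnet.network import correlation_matrix, adjacency, topological_overlap
from coexnet.modules import hierarchical_tree, dynamic_hybrid_cut, \
    merge_close_modules, kmeans_refine
from coexnet.preservation import preservation_permutation_test, classify_nonpreserved

cfg = SyntheticConfig(seed=0)           # 600 genes, 4 planted modules,
ds_a, ds_b, truth = generate_cohort_pair(cfg)  # last module destroyed in B

am_a = adjacency(correlation_matrix(ds_a), power=6)
am_b = adjacency(correlation_matrix(ds_b), power=6)
tom = topological_overlap(am_a)
assign = dynamic_hybrid_cut(hierarchical_tree(tom), tom)
assign = kmeans_refine(merge_close_modules(assign, ds_a), ds_a).relabeled_by_size()
print(assign.sizes())

res = preservation_permutation_test((ds_a, am_a), (ds_b, am_b), assign,
                                    n_perm=1000, seed=0)
for r in res:
    print(r.module, r.module_size, round(r.max_p, 4), r.nonpreserved)
print("non-preserved:", classify_nonpreserved(res))
```

Output:

```
{'M1': 220, 'M3': 60, 'M4': 50, 'M2': 131}
M1 220 1.0 False
M3 60 1.0 False
M4 50 1.0 False
M2 131 0.004 True
non-preserved: {'M2'}
```

The detector recovers the four planted modules at (almost exactly)
their true sizes of 220/60/50/130; the module whose correlation
structure was destroyed in cohort B (detected as M2, 131 genes) is the
only one with all seven preservation p-values below 0.05
(max p = 0.004), while the three genuinely preserved modules sit at
the opposite end of the null (max p = 1.0).

The same analysis runs from the shell:

```sh
coexnet simulate --out-dir sim --seed 0
coexnet run-all --config config.yaml --seed 0 --output-dir results/
```

with a `config.yaml` such as

```yaml
cohort_a_tsv: sim/cohort_a.tsv
cohort_b_tsv: sim/cohort_b.tsv
preservation_n_perm: 1000   # protocol default is 10000
direction: both
gmt_path: sim/gene_sets.gmt
gwas_path: sim/gwas_genes.txt
```

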