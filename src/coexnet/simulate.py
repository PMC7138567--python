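"""Synthetic two-cohort expression data with planted network ground truth.

The generator emulates the structure the network pipeline assumes: two
cohorts sharing a gene universe, block-structured co-expression modules
driven by latent eigengene factors with per-gene loadings (designated
hubs carry the highest loading), and a subset of modules whose
correlation structure is destroyed in the second cohort (non-preserved).
Gene i of module m is generated as

    x_i = w_i * u_m + eps,   eps ~ Normal(0, noise_sd^2),

with u_m a standard-normal latent factor drawn independently per cohort
(preservation is a property of correlation structure, not of sample
values) and w_i drawn uniformly from ``loading_range`` (``hub_loading``
for hubs). Background genes are pure noise. For non-preserved modules,
cohort B expression is regenerated as independent noise (loadings set
to 0); a partial-perturbation mode that shuffles a fraction of loadings
is available for power studies. The induced population correlation
between module genes i, j is w_i w_j / sqrt((w_i^2 + s^2)(w_j^2 + s^2)).

Matched annotation fixtures (gene sets enriched in planted modules,
"GWAS" genes concentrated in non-preserved modules, gene->SNP and
SNP->miRNA join tables with boundary decoys) make every downstream
stage testable without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import GeneSetLibrary
from .core import UNASSIGNED, ExpressionDataset

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort_pair",
    "generate_gene_set_library",
    "generate_variant_tables",
    "population_correlation",
]


@dataclass
class SyntheticConfig:
    """Study-design parameters for the two-cohort generator."""

    n_genes: int = 600
    n_samples_a: int = 150
    n_samples_b: int = 150
    # skewed sizes with a dominant module, mirroring the heavy-tailed
    # module size distributions of real co-expression networks: the
    # largest module acts like the global co-expression component that
    # any random gene subset of real data samples from. The last module
    # (the non-preserved one by default) is kept above 100 genes so that
    # sub-1% hub ranks are attainable at the conventional alpha of 0.01.
    module_sizes: tuple[int, ...] = (220, 60, 50, 130)
    n_nonpreserved: int = 1
    loading_range: tuple[float, float] = (0.5, 0.8)
    hub_loading: float = 1.0
    noise_sd: float = 0.5
    n_hubs_per_module: int = 1
    seed: int = 0
    # fraction of a non-preserved module's loadings shuffled instead of
    # zeroed; 1.0 (default) destroys the module completely in cohort B
    destroy_fraction: float = 1.0

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"sum(module_sizes)={sum(self.module_sizes)} exceeds n_genes={self.n_genes}"
            )
        if self.n_nonpreserved > len(self.module_sizes):
            raise ValueError(
                f"n_nonpreserved={self.n_nonpreserved} exceeds number of modules "
                f"{len(self.module_sizes)}"
            )
        lo, hi = self.loading_range
        if not (0 < lo <= hi <= 1):
            raise ValueError(f"loading_range must satisfy 0 < lo <= hi <= 1, got {self.loading_range}")
        if not (0 < self.hub_loading <= 1):
            raise ValueError(f"hub_loading must be in (0, 1], got {self.hub_loading}")
        if self.hub_loading < hi:
            raise ValueError(
                f"hub_loading={self.hub_loading} below upper end of loading_range {hi}"
            )
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if self.n_hubs_per_module > min(self.module_sizes):
            raise ValueError("n_hubs_per_module exceeds smallest module")
        if not 0.0 <= self.destroy_fraction <= 1.0:
            raise ValueError("destroy_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort pair."""

    true_assignment: dict[str, str]  # gene -> module label or "unassigned"
    nonpreserved_labels: set[str]
    hub_genes: dict[str, list[str]]
    gwas_genes: list[str] = field(default_factory=list)
    disease_mirnas: list[str] = field(default_factory=list)

    def module_genes(self, label: str) -> list[str]:
        return [g for g, m in self.true_assignment.items() if m == label]

    def module_labels(self) -> list[str]:
        seen: list[str] = []
        for m in self.true_assignment.values():
            if m != UNASSIGNED and m not in seen:
                seen.append(m)
        return seen

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "true_assignment": self.true_assignment,
                    "nonpreserved_labels": sorted(self.nonpreserved_labels),
                    "hub_genes": self.hub_genes,
                    "gwas_genes": self.gwas_genes,
                    "disease_mirnas": self.disease_mirnas,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            true_assignment=d["true_assignment"],
            nonpreserved_labels=set(d["nonpreserved_labels"]),
            hub_genes=d["hub_genes"],
            gwas_genes=d.get("gwas_genes", []),
            disease_mirnas=d.get("disease_mirnas", []),
        )


def population_correlation(w_i: float, w_j: float, noise_sd: float) -> float:
    """Model-implied correlation of two same-module genes in one cohort."""
    s2 = noise_sd**2
    return w_i * w_j / np.sqrt((w_i**2 + s2) * (w_j**2 + s2))


def _cohort_matrix(
    rng: np.random.Generator,
    loadings: np.ndarray,
    module_of: np.ndarray,
    n_modules: int,
    n_samples: int,
    noise_sd: float,
) -> np.ndarray:
    u = rng.standard_normal((n_modules, n_samples))
    x = rng.standard_normal((loadings.size, n_samples)) * noise_sd
    in_module = module_of >= 0
    x[in_module] += loadings[in_module, None] * u[module_of[in_module]]
    return x


def generate_cohort_pair(
    config: SyntheticConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, GroundTruth]:
    """Generate the two cohorts and their planted ground truth.

    Deterministic given ``config.seed``. The last ``n_nonpreserved``
    modules are the non-preserved ones; their cohort-B loadings are
    zeroed (``destroy_fraction=1``) or partially shuffled. GWAS fixture
    genes are concentrated in non-preserved modules and disease-miRNA
    identifiers are emitted for the variant-table fixtures.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"G{i + 1:05d}" for i in range(n)]

    module_of = np.full(n, -1, dtype=int)
    pos = 0
    labels = []
    for m, size in enumerate(config.module_sizes):
        labels.append(f"T{m + 1}")
        module_of[pos : pos + size] = m
        pos += size
    nonpreserved = set(labels[len(labels) - config.n_nonpreserved :]) if config.n_nonpreserved else set()

    lo, hi = config.loading_range
    loadings = np.zeros(n)
    in_mod = module_of >= 0
    loadings[in_mod] = rng.uniform(lo, hi, size=in_mod.sum())
    hub_genes: dict[str, list[str]] = {}
    for m, lab in enumerate(labels):
        members = np.where(module_of == m)[0]
        hubs = rng.choice(members, size=config.n_hubs_per_module, replace=False)
        loadings[hubs] = config.hub_loading
        hub_genes[lab] = sorted(genes[i] for i in hubs)

    loadings_b = loadings.copy()
    for lab in nonpreserved:
        m = labels.index(lab)
        members = np.where(module_of == m)[0]
        n_destroy = int(round(config.destroy_fraction * members.size))
        destroyed = rng.choice(members, size=n_destroy, replace=False)
        loadings_b[destroyed] = 0.0
    module_of_b = module_of.copy()
    module_of_b[loadings_b == 0] = -1

    xa = _cohort_matrix(rng, loadings, module_of, len(labels), config.n_samples_a, config.noise_sd)
    xb = _cohort_matrix(rng, loadings_b, module_of_b, len(labels), config.n_samples_b, config.noise_sd)

    ds_a = ExpressionDataset(
        genes=genes,
        samples=[f"A{j + 1:04d}" for j in range(config.n_samples_a)],
        values=xa,
        cohort="A",
    )
    ds_b = ExpressionDataset(
        genes=genes,
        samples=[f"B{j + 1:04d}" for j in range(config.n_samples_b)],
        values=xb,
        cohort="B",
    )

    true_assignment = {
        g: (labels[module_of[i]] if module_of[i] >= 0 else UNASSIGNED)
        for i, g in enumerate(genes)
    }

    # GWAS fixture: concentrated in non-preserved modules (70%), the rest
    # spread over the remaining universe
    n_gwas = min(10, n)
    np_pool = [g for g in genes if true_assignment[g] in nonpreserved]
    other_pool = [g for g in genes if true_assignment[g] not in nonpreserved]
    gwas: list[str] = []
    if np_pool:
        k_np = min(int(round(0.7 * n_gwas)), len(np_pool))
        gwas.extend(rng.choice(np_pool, size=k_np, replace=False))
    k_other = min(n_gwas - len(gwas), len(other_pool))
    if k_other > 0:
        gwas.extend(rng.choice(other_pool, size=k_other, replace=False))

    mirnas = [f"hsa-miR-{100 + i}" for i in range(8)]

    truth = GroundTruth(
        true_assignment=true_assignment,
        nonpreserved_labels=nonpreserved,
        hub_genes=hub_genes,
        gwas_genes=sorted(gwas),
        disease_mirnas=mirnas,
    )
    return ds_a, ds_b, truth


def generate_gene_set_library(
    truth: GroundTruth,
    n_sets: int = 20,
    enriched_fraction: float = 0.8,
    set_size: int = 20,
    seed: int = 0,
) -> GeneSetLibrary:
    """Gene-set library with a known module-enriched subset.

    Every other set (by index) is "enriched": ``enriched_fraction`` of
    its genes come from one planted module (cycled), the rest drawn from
    the whole universe; remaining sets are uniform draws. Set names
    record the source module so tests can verify enrichment calls.
    """
    if not 0.0 <= enriched_fraction <= 1.0:
        raise ValueError("enriched_fraction must be in [0, 1]")
    universe = sorted(truth.true_assignment)
    if not universe:
        raise ValueError("empty gene universe")
    rng = np.random.default_rng(seed)
    modules = truth.module_labels()
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        enriched = bool(modules) and i % 2 == 0
        if enriched:
            lab = modules[(i // 2) % len(modules)]
            pool = truth.module_genes(lab)
            k_mod = min(int(round(enriched_fraction * set_size)), len(pool))
            members = list(rng.choice(pool, size=k_mod, replace=False))
            rest = [g for g in universe if g not in set(members)]
            k_rest = min(set_size - k_mod, len(rest))
            members += list(rng.choice(rest, size=k_rest, replace=False))
            name = f"SET{i + 1:03d}_enriched_{lab}"
        else:
            members = list(rng.choice(universe, size=min(set_size, len(universe)), replace=False))
            name = f"SET{i + 1:03d}_random"
        sets[name] = sorted(members)
    return GeneSetLibrary(sets=sets, source="synthetic")


def generate_variant_tables(
    truth: GroundTruth, seed: int = 0, n_planted: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene->SNP and SNP->miRNA fixture tables with boundary decoys.

    Planted rows pass the downstream filters (eQTL p < 1e-4, allele
    frequency > 0.10) and join to disease miRNAs. Each decoy row fails
    exactly one filter, sitting exactly on the open boundary (p = 1e-4
    or frequency = 0.10) so strict-inequality handling is observable.
    """
    genes = sorted(g for g, m in truth.true_assignment.items() if m != UNASSIGNED) or sorted(
        truth.true_assignment
    )
    if not genes:
        raise ValueError("ground truth contains no genes")
    rng = np.random.default_rng(seed)
    mirnas = truth.disease_mirnas or ["hsa-miR-100"]
    rows = []
    mir_rows = []
    n_planted = min(n_planted, len(genes))
    for i in range(n_planted):
        gene = genes[i]
        snp = f"rs{1000 + i}"
        rows.append((gene, snp, 10.0 ** rng.uniform(-8, -5), rng.uniform(0.15, 0.45)))
        mir_rows.append((snp, mirnas[i % len(mirnas)]))
    # decoys: one fails the p filter exactly, one fails the frequency filter
    g0 = genes[0]
    rows.append((g0, "rs9001", 1.0e-4, 0.3))  # p not strictly below threshold
    rows.append((g0, "rs9002", 1.0e-6, 0.10))  # frequency not strictly above
    mir_rows.append(("rs9001", mirnas[0]))
    mir_rows.append(("rs9002", mirnas[0]))
    # a passing SNP whose miRNA is NOT disease-associated
    rows.append((g0, "rs9003", 1.0e-6, 0.3))
    mir_rows.append(("rs9003", "hsa-miR-9999"))
    gene_snp = pd.DataFrame(rows, columns=["gene", "snp_id", "p_value", "frequency"])
    snp_mirna = pd.DataFrame(mir_rows, columns=["snp_id", "mirna_id"])
    return gene_snp, snp_mirna
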