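"""Local annotation statistics for detected modules.

Covers gene-set over-representation against GMT libraries (one-sided
hypergeometric), generic 2x2 Fisher exact tests with conditional-MLE
odds ratios and exact confidence intervals, GWAS-gene enrichment in
non-preserved modules, and the filtered gene->SNP->miRNA join with
cross-disease SNP overlap. Everything runs on local tables; no remote
service is queried.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

from .core import UNASSIGNED, ModuleAssignment

__all__ = [
    "GeneSetLibrary",
    "EnrichmentRecord",
    "Fisher2x2Result",
    "overrepresentation_test",
    "fisher_2x2",
    "gwas_module_enrichment",
    "snp_mirna_filter_join",
    "cross_disease_overlap",
]


@dataclass
class GeneSetLibrary:
    """Named gene sets (GMT-compatible)."""

    sets: dict[str, list[str]]
    source: str = "synthetic"  # GO | KEGG | TF | synthetic

    def __post_init__(self) -> None:
        empty = [name for name, genes in self.sets.items() if not genes]
        if empty:
            raise ValueError(f"empty gene sets: {empty[:5]}")

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.sets.items():
                fh.write("\t".join([name, self.source, *genes]) + "\n")

    @classmethod
    def from_gmt(cls, path, source: str = "synthetic") -> "GeneSetLibrary":
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                sets[parts[0]] = [g for g in parts[2:] if g]
        return cls(sets=sets, source=source)


@dataclass
class EnrichmentRecord:
    set_name: str
    overlap_count: int
    set_size: int  # in-background set size
    p_value: float
    overlap_string: str  # "k/K", e.g. "7/108"
    fdr: float | None = None


def overrepresentation_test(
    query: list[str],
    lib: GeneSetLibrary,
    background: list[str],
    with_fdr: bool = True,
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric over-representation of ``query`` in each set.

    The universe is ``background``; query genes outside it are dropped
    with a warning, and each set is intersected with the background
    before testing (the reported K in "k/K" is the in-background set
    size). Records are sorted by ascending p-value.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background")
    stray = [g for g in query if g not in bg]
    if stray:
        warnings.warn(f"{len(stray)} query genes outside background dropped", stacklevel=2)
    q = set(query) & bg
    n_bg, n_q = len(bg), len(q)
    records = []
    for name, genes in lib.sets.items():
        in_bg = set(genes) & bg
        k = len(q & in_bg)
        big_k = len(in_bg)
        # upper-tail: P(X >= k) for X ~ Hypergeom(n_bg, big_k, n_q)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_q)) if big_k else 1.0
        records.append(
            EnrichmentRecord(
                set_name=name,
                overlap_count=k,
                set_size=big_k,
                p_value=min(p, 1.0),
                overlap_string=f"{k}/{big_k}",
            )
        )
    records.sort(key=lambda r: (r.p_value, r.set_name))
    if with_fdr and records:
        fdr = multipletests([r.p_value for r in records], method="fdr_bh")[1]
        for r, f in zip(records, fdr):
            r.fdr = float(f)
    return records


def enrichment_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in records],
            "overlap": [r.overlap_string for r in records],
            "p": [r.p_value for r in records],
            "fdr": [r.fdr for r in records],
        }
    )


@dataclass
class Fisher2x2Result:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float  # conditional MLE
    ci_low: float
    ci_high: float
    p_value: float
    alternative: str


def fisher_2x2(a: int, b: int, c: int, d: int, alternative: str = "two_sided") -> Fisher2x2Result:
    """Fisher exact test on the table [[a, b], [c, d]].

    The two-sided p-value uses the probability-mass definition (sum of
    hypergeometric probabilities of tables at most as probable as the
    observed one); the odds ratio is the conditional MLE of the
    noncentral hypergeometric and the 95% CI inverts the exact test.
    """
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"cell counts must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    if a + b + c + d == 0:
        raise ValueError("all cells are zero")
    alt_map = {"two_sided": "two-sided", "greater": "greater", "less": "less"}
    if alternative not in alt_map:
        raise ValueError(f"unknown alternative {alternative!r}")
    table = np.array([[a, b], [c, d]])
    p = float(stats.fisher_exact(table, alternative=alt_map[alternative]).pvalue)
    res = _odds_ratio(table, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return Fisher2x2Result(
        table=((a, b), (c, d)),
        odds_ratio=float(res.statistic),
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        p_value=min(p, 1.0),
        alternative=alternative,
    )


def gwas_module_enrichment(
    assign: ModuleAssignment,
    nonpreserved: set[str],
    gwas: list[str],
    include_unassigned: bool = True,
) -> Fisher2x2Result:
    """Two-sided Fisher test: are GWAS genes over-represented in
    non-preserved modules?

    The 2x2 table strata are (gene in a non-preserved module) x (gene in
    the GWAS list) over all genes in the assignment. Unassigned genes
    count in the preserved stratum by default, since the contrast is
    non-preserved modules against everything else.
    """
    if not gwas:
        raise ValueError("empty GWAS gene list")
    if not nonpreserved:
        raise ValueError("no non-preserved modules: nothing to test, skip this analysis")
    gwas_set = set(gwas)
    a = b = c = d = 0
    for gene, lab in assign.labels.items():
        if lab == UNASSIGNED and not include_unassigned:
            continue
        in_np = lab in nonpreserved
        in_gwas = gene in gwas_set
        if in_np and in_gwas:
            a += 1
        elif in_np:
            b += 1
        elif in_gwas:
            c += 1
        else:
            d += 1
    return fisher_2x2(a, b, c, d, alternative="two_sided")


_GENE_SNP_COLS = ("gene", "snp_id", "p_value", "frequency")
_SNP_MIRNA_COLS = ("snp_id", "mirna_id")


def _check_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} table is missing column(s): {missing}")


def snp_mirna_filter_join(
    module_genes: list[str],
    gene_snp: pd.DataFrame,
    snp_mirna: pd.DataFrame,
    disease_mirnas: list[str],
    p_thresh: float = 1e-4,
    freq_thresh: float = 0.10,
) -> pd.DataFrame:
    """eQTL-filtered gene->SNP->miRNA join for one module.

    Keeps gene_snp rows with gene in the module, eQTL p strictly below
    ``p_thresh`` and allele frequency strictly above ``freq_thresh``,
    joins them to snp_mirna, and keeps rows whose miRNA is in the
    disease list. Returns unique (gene, snp_id, mirna_id) rows sorted
    deterministically.
    """
    _check_columns(gene_snp, _GENE_SNP_COLS, "gene_snp")
    _check_columns(snp_mirna, _SNP_MIRNA_COLS, "snp_mirna")
    module_set = set(module_genes)
    kept = gene_snp[
        gene_snp["gene"].isin(module_set)
        & (gene_snp["p_value"] < p_thresh)
        & (gene_snp["frequency"] > freq_thresh)
    ]
    joined = kept.merge(snp_mirna, on="snp_id", how="inner")
    joined = joined[joined["mirna_id"].isin(set(disease_mirnas))]
    out = (
        joined[["gene", "snp_id", "mirna_id"]]
        .drop_duplicates()
        .sort_values(["gene", "snp_id", "mirna_id"])
        .reset_index(drop=True)
    )
    return out


def cross_disease_overlap(
    hits_a: pd.DataFrame, hits_b: pd.DataFrame
) -> tuple[list[str], dict]:
    """Shared SNPs between two diseases' filtered hit tables.

    Returns the sorted shared snp_id list and summary counts, including
    the genes the shared SNPs map to in each table.
    """
    snps_a = set(hits_a["snp_id"]) if len(hits_a) else set()
    snps_b = set(hits_b["snp_id"]) if len(hits_b) else set()
    shared = sorted(snps_a & snps_b)
    genes_a = sorted(set(hits_a[hits_a["snp_id"].isin(shared)]["gene"])) if shared else []
    genes_b = sorted(set(hits_b[hits_b["snp_id"].isin(shared)]["gene"])) if shared else []
    counts = {
        "n_a": len(snps_a),
        "n_b": len(snps_b),
        "n_shared": len(shared),
        "shared_genes_a": genes_a,
        "shared_genes_b": genes_b,
    }
    return shared, counts
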