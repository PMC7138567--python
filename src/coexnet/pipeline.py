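"""Config-driven orchestration of the full two-cohort analysis.

Stages: (optional) preprocessing -> per-cohort network construction with
per-cohort soft power -> module detection with eigengene merging and
k-means refinement -> bidirectional preservation permutation testing ->
hub detection in non-preserved modules -> annotation statistics.
Everything is seeded from a single master seed fanned out to per-stage
child seeds, so re-running with the same config reproduces outputs
bit-for-bit and any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    GeneSetLibrary,
    enrichment_to_frame,
    gwas_module_enrichment,
    overrepresentation_test,
    snp_mirna_filter_join,
)
from .core import ExpressionDataset, ModuleAssignment, UNASSIGNED
from .hubs import (
    HubScoreTable,
    ModuleGraph,
    export_threshold_graph,
    hub_permutation_test,
    hub_scores,
    significant_hubs,
)
from .modules import (
    dynamic_hybrid_cut,
    hierarchical_tree,
    kmeans_refine,
    merge_close_modules,
    module_eigengene,
)
from .network import (
    AdjacencyMatrix,
    SoftThresholdReport,
    adjacency,
    correlation_matrix,
    soft_threshold_scan,
    topological_overlap,
)
from .preprocess import filter_low_expression
from .preservation import (
    classify_nonpreserved,
    preservation_permutation_test,
    results_to_frame,
    results_to_json,
)
from .simulate import SyntheticConfig, generate_cohort_pair

logger = logging.getLogger("coexnet")

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "stage_seed"]

_KNOWN_KEYS = {
    "cohort_a_tsv", "cohort_b_tsv", "synthetic", "low_expression_fraction",
    "powers", "r2_target", "network_type", "fallback_power", "n_bins",
    "deep_split", "min_module_size", "merge_cut_height", "kmeans_max_iter",
    "preservation_n_perm", "preservation_alpha", "direction",
    "hub_n_perm", "hub_alpha", "edge_interpretation",
    "gmt_path", "gwas_path", "gene_snp_path", "snp_mirna_path", "mirna_path",
    "enrichment_alpha", "seed", "output_dir",
}


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the standard protocol.

    Either both cohort TSV paths or a ``synthetic`` spec (kwargs for
    :class:`coexnet.simulate.SyntheticConfig`) must be provided.
    """

    cohort_a_tsv: str | None = None
    cohort_b_tsv: str | None = None
    synthetic: dict | None = None
    low_expression_fraction: float = 0.0  # 0.05 for raw microarray input
    powers: tuple[int, ...] = tuple(range(1, 21))
    r2_target: float = 0.85
    network_type: str = "unsigned"
    fallback_power: int | None = None  # best-fit power when no power hits r2_target
    n_bins: int = 10
    deep_split: int = 3
    min_module_size: int = 10
    merge_cut_height: float = 0.05
    kmeans_max_iter: int = 30
    preservation_n_perm: int = 10000
    preservation_alpha: float = 0.05
    direction: str = "both"  # "a_to_b" | "b_to_a" | "both"
    hub_n_perm: int = 1000
    hub_alpha: float = 0.01
    edge_interpretation: str = "weight_as_cost"
    gmt_path: str | None = None
    gwas_path: str | None = None
    gene_snp_path: str | None = None
    snp_mirna_path: str | None = None
    mirna_path: str | None = None
    enrichment_alpha: float = 0.05
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if self.synthetic is None and (self.cohort_a_tsv is None or self.cohort_b_tsv is None):
            raise ValueError("provide cohort TSV paths or a synthetic spec")
        if not 0 <= self.low_expression_fraction < 1:
            raise ValueError("low_expression_fraction must be in [0, 1)")
        if self.direction not in ("a_to_b", "b_to_a", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not 0 < self.preservation_alpha < 1 or not 0 < self.hub_alpha < 1:
            raise ValueError("alpha thresholds must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "powers" in raw:
            raw["powers"] = tuple(int(p) for p in raw["powers"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["powers"] = list(self.powers)
        return d


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2^31)."""
    return (int(master_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class CohortNetwork:
    """Everything the pipeline derives for one cohort."""

    dataset: ExpressionDataset
    soft_threshold: SoftThresholdReport
    power: int
    adjacency: AdjacencyMatrix
    assignment: ModuleAssignment

    def module_table(self) -> pd.DataFrame:
        sizes = self.assignment.sizes()
        return pd.DataFrame(
            {"module": list(sizes), "n_genes": list(sizes.values())}
        ).sort_values("module").reset_index(drop=True)


@dataclass
class ReportBundle:
    config: PipelineConfig
    cohorts: dict[str, CohortNetwork]
    preservation: dict[str, pd.DataFrame]  # direction -> table
    nonpreserved: dict[str, set[str]]  # direction -> labels
    hub_tables: dict[str, HubScoreTable]  # "direction:module" -> table
    enrichment: dict[str, pd.DataFrame] = field(default_factory=dict)
    gwas_tests: dict[str, dict] = field(default_factory=dict)
    snp_hits: dict[str, pd.DataFrame] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "metadata": self.metadata,
            "modules": {
                c: net.assignment.sizes() for c, net in self.cohorts.items()
            },
            "chosen_powers": {c: net.power for c, net in self.cohorts.items()},
            "nonpreserved": {d: sorted(v) for d, v in self.nonpreserved.items()},
            "significant_hubs": {
                key: significant_hubs(tab, tab.alpha)
                for key, tab in self.hub_tables.items()
            },
            "gwas_tests": self.gwas_tests,
        }


def _build_cohort(
    ds: ExpressionDataset, config: PipelineConfig, name: str
) -> CohortNetwork:
    logger.info("[%s] building network (%d genes x %d samples)", name, ds.n_genes, ds.n_samples)
    if config.low_expression_fraction > 0:
        ds = filter_low_expression(ds, config.low_expression_fraction)
    cm = correlation_matrix(ds)
    report = soft_threshold_scan(
        cm,
        powers=config.powers,
        n_bins=config.n_bins,
        network_type=config.network_type,
        r2_target=config.r2_target,
    )
    power = report.chosen_power
    if power is None:
        if config.fallback_power is not None:
            power = config.fallback_power
        else:
            power = report.powers[int(np.argmax(report.signed_r2))]
        warnings.warn(
            f"[{name}] no power reached signed R^2 >= {config.r2_target}; using {power}",
            stacklevel=2,
        )
    am = adjacency(cm, power, config.network_type)
    tom = topological_overlap(am)
    dend = hierarchical_tree(tom)
    assign = dynamic_hybrid_cut(
        dend, tom, deep_split=config.deep_split, min_module_size=config.min_module_size
    )
    if assign.n_modules() > 0:
        assign = merge_close_modules(assign, ds, cut_height=config.merge_cut_height)
        assign = kmeans_refine(assign, ds, max_iter=config.kmeans_max_iter)
    assign = assign.relabeled_by_size()
    logger.info("[%s] power=%d, %d modules", name, power, assign.n_modules())
    return CohortNetwork(
        dataset=ds, soft_threshold=report, power=power, adjacency=am, assignment=assign
    )


def _directions(config: PipelineConfig) -> list[tuple[str, str, str]]:
    pairs = {"a_to_b": ("A", "B"), "b_to_a": ("B", "A")}
    if config.direction == "both":
        return [("a_to_b", *pairs["a_to_b"]), ("b_to_a", *pairs["b_to_a"])]
    return [(config.direction, *pairs[config.direction])]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and (optionally) write all artifacts."""
    config.validate()
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    stage = "load"
    try:
        if config.synthetic is not None:
            syn = dict(config.synthetic)
            syn.setdefault("seed", stage_seed(config.seed, "simulate"))
            ds_a, ds_b, truth = generate_cohort_pair(SyntheticConfig(**syn))
        else:
            ds_a = ExpressionDataset.from_tsv(config.cohort_a_tsv, cohort="A")
            ds_b = ExpressionDataset.from_tsv(config.cohort_b_tsv, cohort="B")
            truth = None

        stage = "network_and_modules"
        cohorts = {
            "A": _build_cohort(ds_a, config, "A"),
            "B": _build_cohort(ds_b, config, "B"),
        }

        stage = "preservation"
        preservation: dict[str, pd.DataFrame] = {}
        raw_results: dict[str, list] = {}
        nonpreserved: dict[str, set[str]] = {}
        for dname, disc, test in _directions(config):
            res = preservation_permutation_test(
                discovery=(cohorts[disc].dataset, cohorts[disc].adjacency),
                test=(cohorts[test].dataset, cohorts[test].adjacency),
                assignment=cohorts[disc].assignment,
                n_perm=config.preservation_n_perm,
                alpha=config.preservation_alpha,
                seed=stage_seed(config.seed, f"preserve:{dname}"),
            )
            raw_results[dname] = res
            preservation[dname] = results_to_frame(res)
            nonpreserved[dname] = classify_nonpreserved(res, config.preservation_alpha)

        stage = "hubs"
        hub_tables: dict[str, HubScoreTable] = {}
        for dname, disc, _ in _directions(config):
            net = cohorts[disc]
            mods = net.assignment.modules()
            idx = net.adjacency.gene_index()
            for module in sorted(nonpreserved[dname]):
                genes = mods[module]
                rows = [idx[g] for g in genes]
                graph = ModuleGraph(
                    genes=genes,
                    weights=net.adjacency.values[np.ix_(rows, rows)],
                    edge_interpretation=config.edge_interpretation,
                )
                eig = module_eigengene(net.dataset, genes, module=module)
                tab = hub_scores(graph, net.dataset, eig)
                tab = hub_permutation_test(
                    graph,
                    tab,
                    n_perm=config.hub_n_perm,
                    seed=stage_seed(config.seed, f"hubs:{dname}:{module}"),
                    alpha=config.hub_alpha,
                )
                hub_tables[f"{dname}:{module}"] = tab

        stage = "annotation"
        enrichment: dict[str, pd.DataFrame] = {}
        gwas_tests: dict[str, dict] = {}
        snp_hits: dict[str, pd.DataFrame] = {}
        lib = GeneSetLibrary.from_gmt(config.gmt_path) if config.gmt_path else None
        gwas = (
            [l.strip() for l in open(config.gwas_path) if l.strip()]
            if config.gwas_path
            else None
        )
        gene_snp = (
            pd.read_csv(config.gene_snp_path, sep="\t") if config.gene_snp_path else None
        )
        snp_mirna = (
            pd.read_csv(config.snp_mirna_path, sep="\t") if config.snp_mirna_path else None
        )
        mirnas = (
            [l.strip() for l in open(config.mirna_path) if l.strip()]
            if config.mirna_path
            else None
        )
        for dname, disc, _ in _directions(config):
            net = cohorts[disc]
            mods = net.assignment.modules()
            background = list(net.dataset.genes)
            for module in sorted(nonpreserved[dname]):
                key = f"{dname}:{module}"
                if lib is not None:
                    enrichment[key] = enrichment_to_frame(
                        overrepresentation_test(mods[module], lib, background)
                    )
                if gene_snp is not None and snp_mirna is not None and mirnas is not None:
                    snp_hits[key] = snp_mirna_filter_join(
                        mods[module], gene_snp, snp_mirna, mirnas
                    )
            if gwas is not None and nonpreserved[dname]:
                r = gwas_module_enrichment(net.assignment, nonpreserved[dname], gwas)
                gwas_tests[dname] = {
                    "table": r.table,
                    "odds_ratio": r.odds_ratio,
                    "ci": [r.ci_low, r.ci_high],
                    "p_value": r.p_value,
                }
    except Exception as err:  # annotate the failing stage, keep partial outputs
        raise RuntimeError(f"pipeline failed during stage {stage!r}: {err}") from err

    bundle = ReportBundle(
        config=config,
        cohorts=cohorts,
        preservation=preservation,
        nonpreserved=nonpreserved,
        hub_tables=hub_tables,
        enrichment=enrichment,
        gwas_tests=gwas_tests,
        snp_hits=snp_hits,
        metadata={
            "seed": config.seed,
            "coexnet_version": __version__,
            "network_type": config.network_type,
            "edge_interpretation": config.edge_interpretation,
            "background": "all genes surviving preprocessing",
            "direction": config.direction,
        },
    )
    if out:
        _write_bundle(bundle, raw_results, out)
    return bundle


def _write_bundle(bundle: ReportBundle, raw_results: dict, out: Path) -> None:
    for name, net in bundle.cohorts.items():
        net.soft_threshold.to_json(out / f"soft_threshold_{name}.json")
        net.assignment.to_tsv(out / f"modules_{name}.tsv")
        net.module_table().to_csv(out / f"module_sizes_{name}.tsv", sep="\t", index=False)
    for dname, frame in bundle.preservation.items():
        frame.to_csv(out / f"preservation_{dname}.tsv", sep="\t", index=False)
        results_to_json(raw_results[dname], out / f"preservation_{dname}.json")
    for key, tab in bundle.hub_tables.items():
        tab.to_tsv(out / f"hubs_{key.replace(':', '_')}.tsv")
    for key, frame in bundle.enrichment.items():
        frame.to_csv(out / f"enrichment_{key.replace(':', '_')}.tsv", sep="\t", index=False)
    for key, frame in bundle.snp_hits.items():
        frame.to_csv(out / f"snp_hits_{key.replace(':', '_')}.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(bundle.summary(), fh, indent=2, sort_keys=True, default=str)
    with open(out / "config.json", "w") as fh:
        json.dump(bundle.config.to_dict(), fh, indent=2)
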