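"""Pre-network data reduction filters.

Two filters are applied to microarray-style matrices before network
construction: probe-to-gene collapse keeping the probe with the highest
median absolute deviation (MAD), and removal of the bottom fraction of
genes by mean expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionDataset

__all__ = ["ProbeMatrix", "collapse_probes_by_mad", "filter_low_expression", "mad"]


@dataclass
class ProbeMatrix:
    """Probes x samples matrix plus a probe -> gene map.

    Probes without a mapping entry are dropped on load.
    """

    probe_ids: list[str]
    probe_gene_map: dict[str, str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.samples)):
            raise ValueError("values shape does not match probes x samples")
        missing = [p for p in self.probe_ids if p not in self.probe_gene_map]
        if missing:
            raise ValueError(f"probes without gene mapping: {missing[:5]}")

    @classmethod
    def from_tsv(cls, matrix_path, map_path) -> "ProbeMatrix":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        mp = pd.read_csv(map_path, sep="\t", dtype=str)
        probe_col, gene_col = mp.columns[:2]
        mapping = dict(zip(mp[probe_col], mp[gene_col]))
        keep = [p for p in df.index.astype(str) if p in mapping]
        df = df.loc[keep]
        return cls(
            probe_ids=[str(p) for p in df.index],
            probe_gene_map=mapping,
            samples=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
        )


def mad(x: np.ndarray) -> float:
    """Unscaled median absolute deviation: median(|x - median(x)|).

    No 1.4826 consistency constant -- it would not change which probe
    attains the maximum.
    """
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


def collapse_probes_by_mad(pm: ProbeMatrix) -> ExpressionDataset:
    """Collapse multi-probe genes to the probe with maximal MAD.

    Ties are broken by the lexicographically smallest probe ID, so the
    collapse is deterministic and idempotent.
    """
    if len(pm.probe_ids) == 0:
        raise ValueError("empty probe matrix")
    best: dict[str, tuple[float, str, int]] = {}
    for i, probe in enumerate(pm.probe_ids):
        gene = pm.probe_gene_map[probe]
        m = mad(pm.values[i])
        key = (-m, probe)  # max MAD, then smallest probe ID
        if gene not in best or key < (best[gene][0], best[gene][1]):
            best[gene] = (-m, probe, i)
    genes = sorted(best)
    rows = [best[g][2] for g in genes]
    return ExpressionDataset(
        genes=genes, samples=list(pm.samples), values=pm.values[rows]
    )


def filter_low_expression(ds: ExpressionDataset, fraction: float = 0.05) -> ExpressionDataset:
    """Remove the ``floor(fraction * n_genes)`` genes with lowest mean expression.

    Ties at the cut are resolved by removing the lexicographically smaller
    gene ID first; surviving genes keep their input order.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    n_remove = int(np.floor(fraction * ds.n_genes))
    if n_remove == 0:
        return ExpressionDataset(
            genes=list(ds.genes), samples=list(ds.samples),
            values=ds.values.copy(), cohort=ds.cohort,
        )
    means = ds.values.mean(axis=1)
    order = sorted(range(ds.n_genes), key=lambda i: (means[i], ds.genes[i]))
    removed = set(order[:n_remove])
    keep = [i for i in range(ds.n_genes) if i not in removed]
    return ExpressionDataset(
        genes=[ds.genes[i] for i in keep],
        samples=list(ds.samples),
        values=ds.values[keep],
        cohort=ds.cohort,
    )
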