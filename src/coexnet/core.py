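"""Core data containers shared across the pipeline.

The pipeline operates on gene-level expression matrices (genes x samples)
and on symmetric gene-gene similarity matrices derived from them:
Pearson correlation, soft-thresholded adjacency, and topological overlap.
Module structure is carried as a gene -> label mapping with an explicit
``"unassigned"`` sentinel, plus per-module eigengene profiles.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"

__all__ = [
    "UNASSIGNED",
    "ExpressionDataset",
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "TOMMatrix",
    "ModuleAssignment",
    "EigengeneProfile",
]


@dataclass
class ExpressionDataset:
    """Expression matrix with genes as rows and samples as columns.

    Values are stored as given (normalized intensities); standardization
    is performed inside consumers that require it.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), float
    cohort: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene identifiers")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def subset(self, genes: list[str]) -> "ExpressionDataset":
        idx = self.gene_index()
        rows = [idx[g] for g in genes]
        return ExpressionDataset(
            genes=list(genes),
            samples=list(self.samples),
            values=self.values[rows],
            cohort=self.cohort,
        )

    def zscored(self, ddof: int = 0) -> np.ndarray:
        """Gene-wise z-scored copy of the value matrix.

        Zero-variance genes come out as all-zero rows rather than NaN.
        """
        mu = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, ddof=ddof, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (self.values - mu) / sd
        z[~np.isfinite(z)] = 0.0
        return z

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.genes, columns=self.samples)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, cohort: str = "") -> "ExpressionDataset":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genes=[str(g) for g in df.index],
            samples=[str(s) for s in df.columns],
            values=df.to_numpy(dtype=float),
            cohort=cohort,
        )


def _check_square_symmetric(values: np.ndarray, genes: list[str], tol: float = 1e-8) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n = len(genes)
    if values.shape != (n, n):
        raise ValueError(f"matrix shape {values.shape} does not match {n} genes")
    if not np.allclose(values, values.T, atol=tol):
        raise ValueError("matrix is not symmetric")
    return values


@dataclass
class _GeneGeneMatrix:
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_square_symmetric(self.values, self.genes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def submatrix(self, genes: list[str]) -> np.ndarray:
        idx = self.gene_index()
        rows = np.array([idx[g] for g in genes])
        return self.values[np.ix_(rows, rows)]

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.genes, columns=self.genes)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")


@dataclass
class CorrelationMatrix(_GeneGeneMatrix):
    """Pearson correlations, unit diagonal; zero-variance genes correlate 0."""

    zero_variance_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(np.abs(self.values) > 1 + 1e-8):
            raise ValueError("correlations outside [-1, 1]")


@dataclass
class AdjacencyMatrix(_GeneGeneMatrix):
    """Soft-thresholded adjacency in [0, 1] with unit diagonal."""

    power: int = 1
    network_type: str = "unsigned"  # or "signed"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError(f"unknown network_type {self.network_type!r}")
        if np.any(self.values < -1e-10) or np.any(self.values > 1 + 1e-10):
            raise ValueError("adjacency outside [0, 1]")


@dataclass
class TOMMatrix(_GeneGeneMatrix):
    """Topological overlap similarity in [0, 1] with unit diagonal."""

    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, None)


@dataclass
class ModuleAssignment:
    """Map gene -> module label, with an ``unassigned`` sentinel.

    ``provenance`` tags the detection stage that produced the assignment
    (``initial`` | ``merged`` | ``kmeans_refined``).
    """

    labels: dict[str, str]
    provenance: str = "initial"

    def modules(self) -> dict[str, list[str]]:
        """Module label -> member genes (unassigned excluded), insertion order."""
        out: dict[str, list[str]] = {}
        for g, lab in self.labels.items():
            if lab == UNASSIGNED:
                continue
            out.setdefault(lab, []).append(g)
        return out

    def sizes(self) -> dict[str, int]:
        return {m: len(gs) for m, gs in self.modules().items()}

    def n_modules(self) -> int:
        return len(self.modules())

    def relabeled_by_size(self, prefix: str = "M") -> "ModuleAssignment":
        """Stable labels M1, M2, ... by decreasing module size (ties by old label)."""
        mods = self.modules()
        order = sorted(mods, key=lambda m: (-len(mods[m]), m))
        rename = {old: f"{prefix}{i + 1}" for i, old in enumerate(order)}
        labels = {
            g: (rename[lab] if lab != UNASSIGNED else UNASSIGNED)
            for g, lab in self.labels.items()
        }
        return ModuleAssignment(labels=labels, provenance=self.provenance)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {"gene_id": list(self.labels), "module": list(self.labels.values())}
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, provenance: str = "initial") -> "ModuleAssignment":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(labels=dict(zip(df["gene_id"], df["module"])), provenance=provenance)


@dataclass
class EigengeneProfile:
    """First principal component of a module's standardized expression.

    The profile has unit norm and is oriented so that its correlation with
    the module's mean z-scored expression is non-negative.
    """

    module: str
    samples: list[str]
    values: np.ndarray  # one value per sample, unit norm
    variance_explained: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples),):
            raise ValueError("eigengene length does not match sample count")
        if not 0.0 <= self.variance_explained <= 1.0 + 1e-9:
            raise ValueError("variance_explained outside [0, 1]")


# WGCNA-style color names, for presentation parity with published module tables.
MODULE_COLOR_NAMES = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue", "darkred",
    "darkgreen", "darkturquoise", "darkgrey", "orange", "darkorange", "white",
    "skyblue", "saddlebrown", "steelblue", "paleturquoise", "violet",
    "darkolivegreen", "darkmagenta",
]


def color_name_mapping(assignment: ModuleAssignment) -> dict[str, str]:
    """Map size-ordered module labels to conventional color names.

    Purely cosmetic; once the name list is exhausted the stable label
    itself is used.
    """
    mods = assignment.modules()
    order = sorted(mods, key=lambda m: (-len(mods[m]), m))
    mapping = {}
    for i, lab in enumerate(order):
        mapping[lab] = MODULE_COLOR_NAMES[i] if i < len(MODULE_COLOR_NAMES) else lab
    return mapping
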