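"""Weighted co-expression network construction.

Pipeline: Pearson correlation matrix -> soft-thresholded adjacency
(power chosen so the connectivity distribution approximates scale-free
topology, signed R^2 >= 0.85) -> topological overlap matrix (TOM).

The scale-free fit follows the standard convention: connectivities are
binned into equal-width bins, and log10(frequency) is regressed on
log10(mean connectivity) over non-empty bins; the R^2 is sign-flipped by
the slope so that only decreasing (power-law-like) fits score highly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import AdjacencyMatrix, CorrelationMatrix, ExpressionDataset, TOMMatrix

__all__ = [
    "correlation_matrix",
    "adjacency",
    "scale_free_fit",
    "soft_threshold_scan",
    "topological_overlap",
    "SoftThresholdReport",
]

DEFAULT_POWERS = tuple(range(1, 21))
DEFAULT_R2_TARGET = 0.85


def correlation_matrix(ds: ExpressionDataset) -> CorrelationMatrix:
    """All-pairs Pearson correlation of gene expression profiles.

    Genes with zero variance get correlation 0 to every other gene and
    are reported in ``zero_variance_genes`` (with a warning); the
    diagonal is forced to 1. Missing values are a hard error.
    """
    if ds.n_samples < 3:
        raise ValueError(f"need >= 3 samples, got {ds.n_samples}")
    if not np.all(np.isfinite(ds.values)):
        bad = [ds.genes[i] for i in np.where(~np.isfinite(ds.values).all(axis=1))[0]]
        raise ValueError(f"non-finite expression values for genes: {bad[:5]}")
    spread = np.ptp(ds.values, axis=1)
    zero_var = [ds.genes[i] for i in np.where(spread == 0)[0]]
    if zero_var:
        warnings.warn(
            f"{len(zero_var)} zero-variance genes set to correlation 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ds.values)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(genes=list(ds.genes), values=r, zero_variance_genes=zero_var)


def adjacency(cm: CorrelationMatrix, power: int, network_type: str = "unsigned") -> AdjacencyMatrix:
    """Soft-threshold the correlation matrix.

    unsigned: a_ij = |r_ij|^beta; signed: a_ij = ((1 + r_ij)/2)^beta.
    Diagonal is set to 1.
    """
    if power < 1:
        raise ValueError(f"power must be >= 1, got {power}")
    if network_type == "unsigned":
        a = np.abs(cm.values) ** power
    elif network_type == "signed":
        a = ((1.0 + cm.values) / 2.0) ** power
    else:
        raise ValueError(f"unknown network_type {network_type!r}")
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(
        genes=list(cm.genes), values=a, power=int(power), network_type=network_type
    )


def connectivity(am: AdjacencyMatrix) -> np.ndarray:
    """Whole-network connectivity k_i = sum_{j != i} a_ij."""
    return am.values.sum(axis=1) - np.diag(am.values)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity vector.

    Bins ``k`` into ``n_bins`` equal-width bins, drops empty bins, and
    regresses log10(fraction of genes) on log10(mean k) across bins.
    Returns ``(signed_r2, slope)`` where signed_r2 = -sign(slope) * R^2.
    Degenerate inputs (constant k, fewer than 2 usable bins) score 0.
    """
    k = np.asarray(k, dtype=float)
    if k.size == 0 or np.ptp(k) == 0:
        warnings.warn("constant connectivity: scale-free fit undefined, set to 0", stacklevel=2)
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    mean_k, freq = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            mk = k[mask].mean()
            if mk > 0:
                mean_k.append(mk)
                freq.append(mask.sum() / k.size)
    if len(mean_k) < 2:
        warnings.warn("fewer than 2 usable connectivity bins, fit set to 0", stacklevel=2)
        return 0.0, 0.0
    res = stats.linregress(np.log10(mean_k), np.log10(freq))
    slope = float(res.slope)
    r2 = float(res.rvalue**2)
    return -np.sign(slope) * r2, slope


@dataclass
class SoftThresholdReport:
    powers: list[int]
    signed_r2: list[float]
    slopes: list[float]
    mean_connectivity: list[float]
    chosen_power: int | None
    r2_target: float
    network_type: str
    # Assumptions recorded for reproducibility: signedness of the network
    # and the correlation estimator are configuration choices, not givens.
    assumptions: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(
                {
                    "powers": self.powers,
                    "signed_r2": self.signed_r2,
                    "slopes": self.slopes,
                    "mean_connectivity": self.mean_connectivity,
                    "chosen_power": self.chosen_power,
                    "r2_target": self.r2_target,
                    "network_type": self.network_type,
                    "assumptions": self.assumptions,
                },
                fh,
                indent=2,
            )


def soft_threshold_scan(
    cm: CorrelationMatrix,
    powers=DEFAULT_POWERS,
    n_bins: int = 10,
    network_type: str = "unsigned",
    r2_target: float = DEFAULT_R2_TARGET,
) -> SoftThresholdReport:
    """Scan candidate soft-thresholding powers for scale-free fit.

    ``chosen_power`` is the smallest power whose signed R^2 reaches
    ``r2_target`` (0.85 by default), or None if none does.
    """
    powers = [int(p) for p in powers]
    if not powers:
        raise ValueError("powers must be non-empty")
    if cm.n_genes < n_bins:
        raise ValueError(f"need >= {n_bins} genes for {n_bins} connectivity bins")
    r2s, slopes, mean_ks = [], [], []
    for p in powers:
        am = adjacency(cm, p, network_type)
        k = connectivity(am)
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        r2s.append(r2)
        slopes.append(slope)
        mean_ks.append(float(k.mean()))
    chosen = None
    for p, r2 in zip(powers, r2s):
        if r2 >= r2_target:
            chosen = p
            break
    return SoftThresholdReport(
        powers=powers,
        signed_r2=r2s,
        slopes=slopes,
        mean_connectivity=mean_ks,
        chosen_power=chosen,
        r2_target=r2_target,
        network_type=network_type,
        assumptions={
            "correlation": "pearson",
            "network_type": network_type,
            "binning": f"{n_bins} equal-width bins, empty bins dropped",
        },
    )


def topological_overlap(am: AdjacencyMatrix) -> TOMMatrix:
    """Unsigned topological overlap of a weighted adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, where
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{j != i} a_ij; TOM_ii = 1.
    The adjacency diagonal participates in neither k nor l.
    """
    a = am.values.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    assert np.all(denom > 0), "TOM denominator <= 0: adjacency outside [0, 1]?"
    tom = (l + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMMatrix(genes=list(am.genes), values=tom)
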