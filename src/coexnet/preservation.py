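"""Seven-statistic module preservation testing between two networks.

A module detected in a discovery cohort is scored in a test cohort by
seven statistics of its correlation/connectivity structure (average
edge weight, eigengene coherence, correlation of correlations, of
intramodular degree and of node contributions, and sign-aware average
correlation and contribution). Significance comes from a permutation
null in which the discovery module is paired with random same-size gene
sets from the shared universe of the test network; with the "less"
alternative, a module whose observed statistics all fall in the lower
tail of the null (all seven p < alpha) is called non-preserved.

The permutation p-value uses the add-one estimator
p = (#{null <= observed} + 1) / (n_perm + 1), whose smallest attainable
value is 1 / (n_perm + 1) -- with the conventional 10,000 permutations,
9.999e-5, printed as 9.99E-5 when truncated to three significant
figures.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AdjacencyMatrix, ExpressionDataset, ModuleAssignment

__all__ = [
    "STAT_NAMES",
    "PreservationStats",
    "PreservationResult",
    "preservation_statistics",
    "preservation_permutation_test",
    "classify_nonpreserved",
    "min_permutation_pvalue",
    "format_pvalue_truncated",
]

STAT_NAMES = (
    "avg_weight",
    "coherence",
    "cor_cor",
    "cor_degree",
    "cor_contrib",
    "avg_cor",
    "avg_contrib",
)


@dataclass
class PreservationStats:
    avg_weight: float
    coherence: float
    cor_cor: float
    cor_degree: float
    cor_contrib: float
    avg_cor: float
    avg_contrib: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in STAT_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "PreservationStats":
        return cls(**{s: float(v) for s, v in zip(STAT_NAMES, arr)})


@dataclass
class PreservationResult:
    module: str
    observed: PreservationStats
    p_values: dict[str, float]
    nonpreserved: bool
    n_permutations: int
    module_size: int

    @property
    def max_p(self) -> float:
        return max(self.p_values.values())


class _CohortView:
    """Correlation / adjacency / z-scored data aligned to a gene order."""

    def __init__(self, ds: ExpressionDataset, am: AdjacencyMatrix, genes: list[str]):
        ds_idx = ds.gene_index()
        am_idx = am.gene_index()
        rows_ds = np.array([ds_idx[g] for g in genes])
        rows_am = np.array([am_idx[g] for g in genes])
        z = ds.zscored()[rows_ds]
        n = z.shape[1]
        self.corr = (z @ z.T) / n
        np.fill_diagonal(self.corr, 1.0)
        self.adj = am.values[np.ix_(rows_am, rows_am)]
        self.genes = list(genes)


def _node_contributions(corr_sub: np.ndarray) -> np.ndarray:
    """Correlation of each module gene with the module eigengene.

    Derived from the leading eigenpair of the module correlation matrix:
    with z-scored data X (rows unit variance) and C = X X^T / n, the
    eigengene is X^T v for the leading eigenvector v with eigenvalue
    lambda, and cor(x_i, eigengene) = sqrt(lambda) v_i. The eigenvector
    is oriented so the mean contribution is non-negative (eigengene
    positively correlated with the mean module profile).
    """
    vals, vecs = np.linalg.eigh(corr_sub)
    lam = max(float(vals[-1]), 0.0)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    return np.clip(np.sqrt(lam) * v, -1.0, 1.0)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _discovery_side(view: _CohortView, idx: np.ndarray) -> dict:
    c = view.corr[np.ix_(idx, idx)]
    a = view.adj[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    cor_vec = c[iu]
    k = a.sum(axis=1) - np.diag(a)
    contrib = _node_contributions(c)
    return {
        "cor_vec": cor_vec,
        "k": k,
        "contrib": contrib,
        "sign_cor": np.sign(cor_vec),
        "sign_contrib": np.sign(contrib),
    }


def _module_stats(view_d: _CohortView, view_t: _CohortView, idx: np.ndarray) -> np.ndarray:
    """Seven statistics of one gene set, discovery and test sides aligned."""
    return _seven_stats(_discovery_side(view_d, idx), view_t, idx)


def _seven_stats(disc: dict, view_t: _CohortView, idx_t: np.ndarray) -> np.ndarray:
    c = view_t.corr[np.ix_(idx_t, idx_t)]
    a = view_t.adj[np.ix_(idx_t, idx_t)]
    iu = np.triu_indices(len(idx_t), k=1)
    cor_t = c[iu]
    k_t = a.sum(axis=1) - np.diag(a)
    contrib_t = _node_contributions(c)
    return np.array(
        [
            float(a[iu].mean()),  # avg_weight
            float(np.mean(contrib_t**2)),  # coherence
            _pearson(disc["cor_vec"], cor_t),  # cor_cor
            _pearson(disc["k"], k_t),  # cor_degree
            _pearson(disc["contrib"], contrib_t),  # cor_contrib
            float(np.mean(cor_t * disc["sign_cor"])),  # avg_cor
            float(np.mean(contrib_t * disc["sign_contrib"])),  # avg_contrib
        ]
    )


def preservation_statistics(
    discovery: tuple[ExpressionDataset, AdjacencyMatrix],
    test: tuple[ExpressionDataset, AdjacencyMatrix],
    genes: list[str],
) -> PreservationStats:
    """Observed preservation statistics of one module in the test cohort."""
    if len(genes) < 3:
        raise ValueError("need >= 3 module genes")
    ds_d, am_d = discovery
    ds_t, am_t = test
    for ds, am in ((ds_d, am_d), (ds_t, am_t)):
        have = set(ds.genes) & set(am.genes)
        missing = [g for g in genes if g not in have]
        if missing:
            raise ValueError(f"module genes absent from a cohort: {missing[:5]}")
    view_d = _CohortView(ds_d, am_d, genes)
    view_t = _CohortView(ds_t, am_t, genes)
    idx = np.arange(len(genes))
    disc = _discovery_side(view_d, idx)
    arr = _seven_stats(disc, view_t, idx)
    if np.isnan(arr).any():
        bad = [STAT_NAMES[i] for i in np.where(np.isnan(arr))[0]]
        warnings.warn(f"zero-variance input: statistic(s) {bad} are NaN", stacklevel=2)
    return PreservationStats.from_array(arr)


def preservation_permutation_test(
    discovery: tuple[ExpressionDataset, AdjacencyMatrix],
    test: tuple[ExpressionDataset, AdjacencyMatrix],
    assignment: ModuleAssignment | dict[str, list[str]],
    n_perm: int = 10000,
    alternative: str = "less",
    alpha: float = 0.05,
    seed: int | None = None,
) -> list[PreservationResult]:
    """Permutation test of all modules of ``assignment`` in the test cohort.

    Null draws are random module-sized subsets of the shared gene
    universe (the module's own genes included), sampled without
    replacement independently per permutation; each draw is scored with
    the same seven formulas as the observed module, its discovery-side
    structure recomputed from the draw itself. Under ``alternative="less"``,
    p_s = (#{null_s <= observed_s} + 1) / (n_perm + 1) for each of the
    seven statistics; a module is non-preserved iff all seven p < alpha.
    Deterministic given ``seed``.

    ``assignment`` may also be a plain mapping of module label to gene
    list (modules are then allowed to overlap), which is convenient for
    scoring externally defined gene sets.
    """
    if alternative not in ("less", "greater"):
        raise ValueError(f"unsupported alternative {alternative!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ds_d, am_d = discovery
    ds_t, am_t = test
    common = set(ds_t.genes) & set(am_t.genes) & set(am_d.genes)
    shared = [g for g in ds_d.genes if g in common]
    if not shared:
        raise ValueError("no shared gene universe between cohorts")
    view_d = _CohortView(ds_d, am_d, shared)
    view_t = _CohortView(ds_t, am_t, shared)
    pos = {g: i for i, g in enumerate(shared)}
    rng = np.random.default_rng(seed)
    n_universe = len(shared)

    modules = (
        assignment.modules() if isinstance(assignment, ModuleAssignment) else dict(assignment)
    )
    results = []
    for module, genes in modules.items():
        if len(genes) > n_universe:
            raise ValueError(f"module {module} larger than shared universe")
        genes_in = [g for g in genes if g in pos]
        if len(genes_in) < len(genes):
            warnings.warn(
                f"module {module}: {len(genes) - len(genes_in)} genes outside shared universe",
                stacklevel=2,
            )
        m = len(genes_in)
        if m < 3:
            warnings.warn(f"module {module} has < 3 shared genes; skipped", stacklevel=2)
            continue
        idx = np.array([pos[g] for g in genes_in])
        observed = _module_stats(view_d, view_t, idx)
        # null: a random module of the same size, scored discovery -> test
        # with the same formulas (its own discovery-side structure included)
        null = np.empty((n_perm, len(STAT_NAMES)))
        for p in range(n_perm):
            draw = rng.choice(n_universe, size=m, replace=False)
            null[p] = _module_stats(view_d, view_t, draw)
        nan_obs = np.isnan(observed)
        if nan_obs.any():
            warnings.warn(
                f"module {module}: NaN statistic(s) "
                f"{[STAT_NAMES[i] for i in np.where(nan_obs)[0]]}; p set to 1",
                stacklevel=2,
            )
        with np.errstate(invalid="ignore"):
            if alternative == "less":
                counts = np.sum(null <= observed, axis=0)
            else:
                counts = np.sum(null >= observed, axis=0)
        p_values = (counts + 1) / (n_perm + 1)
        p_values = np.where(nan_obs, 1.0, p_values)
        pv = {s: float(v) for s, v in zip(STAT_NAMES, p_values)}
        results.append(
            PreservationResult(
                module=module,
                observed=PreservationStats.from_array(observed),
                p_values=pv,
                nonpreserved=bool(all(v < alpha for v in pv.values())),
                n_permutations=n_perm,
                module_size=m,
            )
        )
    return results


def classify_nonpreserved(results: list[PreservationResult], alpha: float = 0.05) -> set[str]:
    """Modules whose seven permutation p-values are all below ``alpha``."""
    return {
        r.module
        for r in results
        if all(p < alpha for p in r.p_values.values())
    }


def min_permutation_pvalue(n_perm: int) -> float:
    """Smallest attainable p under the add-one estimator: 1 / (n_perm + 1)."""
    return 1.0 / (n_perm + 1)


def format_pvalue_truncated(p: float, sig: int = 3) -> str:
    """Scientific notation truncated (not rounded) to ``sig`` significant figures.

    1/10001 -> "9.99E-5": the convention used when reporting permutation
    p-values at their estimator floor.
    """
    if not 0 < p <= 1:
        raise ValueError(f"p must be in (0, 1], got {p}")
    exponent = math.floor(math.log10(p))
    mantissa = p / 10.0**exponent
    factor = 10.0 ** (sig - 1)
    mantissa = math.floor(mantissa * factor + 1e-12) / factor
    if mantissa >= 10.0:  # e.g. p exactly a power of ten boundary
        mantissa /= 10.0
        exponent += 1
    return f"{mantissa:.{sig - 1}f}E{exponent}"


def results_to_frame(results: list[PreservationResult]) -> pd.DataFrame:
    """Table-style export: module, seven p-values, max p, size."""
    rows = []
    for r in results:
        row = {"module": r.module}
        row.update({f"p_{s}": r.p_values[s] for s in STAT_NAMES})
        row["max_p"] = r.max_p
        row["max_p_printed"] = format_pvalue_truncated(r.max_p)
        row["nonpreserved"] = r.nonpreserved
        row["n_genes"] = r.module_size
        rows.append(row)
    return pd.DataFrame(rows)


def results_to_json(results: list[PreservationResult], path) -> None:
    payload = [
        {
            "module": r.module,
            "observed": {s: getattr(r.observed, s) for s in STAT_NAMES},
            "p_values": r.p_values,
            "max_p": r.max_p,
            "nonpreserved": r.nonpreserved,
            "n_permutations": r.n_permutations,
            "n_genes": r.module_size,
        }
        for r in results
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
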