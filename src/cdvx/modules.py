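"""Weighted co-expression module detection.

Pipeline: soft-threshold selection by scale-free fit, topological overlap
from the soft-thresholded |Pearson| adjacency, average-linkage clustering
of 1 - TOM with a static cut, eigengene computation (first principal
component of the gene-standardized module submatrix), and iterative
merging of modules whose eigengenes correlate above 1 - merge_height.

Module labels are letters assigned in decreasing module size ("A" is the
largest); "unassigned" is reserved for genes in branches smaller than the
minimum module size.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .preprocess import ExpressionMatrix

__all__ = [
    "NetworkConfig",
    "ModulePartition",
    "EigengeneMatrix",
    "pick_soft_threshold",
    "compute_tom",
    "detect_modules",
    "compute_eigengenes",
    "merge_modules",
    "build_modules",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class NetworkConfig:
    power_grid: tuple[int, ...] = tuple(range(1, 21))
    rsq_target: float = 0.8
    min_module_size: int = 30
    cut_height: float = 0.99
    merge_height: float = 0.25
    n_connectivity_bins: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.merge_height < 1):
            raise ValueError("merge_height must lie in (0, 1)")
        if any(p < 1 for p in self.power_grid):
            raise ValueError("powers must be >= 1")


@dataclass(frozen=True)
class ModulePartition:
    """Gene -> module-label map for one sample set."""

    labels: dict[str, str]
    sample_set_id: str = "global"

    @property
    def genes(self) -> list[str]:
        return list(self.labels)

    @property
    def modules(self) -> list[str]:
        out = sorted({m for m in self.labels.values() if m != UNASSIGNED})
        return out

    def members(self, module: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]

    def assigned(self) -> dict[str, str]:
        return {g: m for g, m in self.labels.items() if m != UNASSIGNED}

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.labels.values():
            if m != UNASSIGNED:
                out[m] = out.get(m, 0) + 1
        return out

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"gene": list(self.labels), "module": list(self.labels.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, sample_set_id: str = "global") -> "ModulePartition":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df["gene"], df["module"])), sample_set_id)


@dataclass(frozen=True)
class EigengeneMatrix:
    """Module x sample eigengene values (unit variance, positively
    oriented towards member genes)."""

    data: pd.DataFrame  # modules x samples
    sample_set_id: str = "global"

    @property
    def modules(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def profile(self, module: str) -> np.ndarray:
        return self.data.loc[module].to_numpy()

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="module")


def _module_labels(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... — stable alphabet for module names."""
    out = []
    letters = string.ascii_uppercase
    for i in range(n):
        label = ""
        j = i
        while True:
            label = letters[j % 26] + label
            j = j // 26 - 1
            if j < 0:
                break
        out.append(label)
    return out


def _adjacency(expr: ExpressionMatrix, beta: int) -> np.ndarray:
    values = expr.values
    sd = values.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [expr.genes[i] for i in zero[:10]]
        raise ValueError(f"zero-variance genes: {names}")
    corr = np.corrcoef(values)
    np.fill_diagonal(corr, 1.0)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def pick_soft_threshold(expr: ExpressionMatrix, cfg: NetworkConfig = NetworkConfig()) -> int:
    """Smallest power whose signed scale-free fit R^2 reaches the target.

    The fit regresses log10 p(k) on log10 k over binned connectivities;
    R^2 is sign-adjusted (negated for a positive slope) so only a
    decreasing degree distribution can satisfy the target. If no power
    reaches the target, the power maximizing R^2 is returned.
    """
    if len(cfg.power_grid) == 1:
        return cfg.power_grid[0]
    corr = np.corrcoef(expr.values)
    np.fill_diagonal(corr, 0.0)
    acorr = np.abs(corr)
    best_power, best_rsq = None, -np.inf
    for beta in cfg.power_grid:
        k = (acorr**beta).sum(axis=1)
        rsq = _scale_free_rsq(k, cfg.n_connectivity_bins)
        if rsq is None:
            logger.warning("degenerate connectivity at power %d", beta)
            continue
        if rsq >= cfg.rsq_target:
            return beta
        if rsq > best_rsq:
            best_power, best_rsq = beta, rsq
    if best_power is None:
        fallback = sorted(cfg.power_grid)[len(cfg.power_grid) // 2]
        logger.warning("all powers degenerate; falling back to power %d", fallback)
        return fallback
    return best_power


def _scale_free_rsq(k: np.ndarray, n_bins: int) -> float | None:
    if np.allclose(k, k[0]):
        return None
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        mean_k = k[mask].mean()
        freq = mask.mean()
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3:
        return None
    slope, _ = np.polyfit(xs, ys, 1)
    r = np.corrcoef(xs, ys)[0, 1]
    return -np.sign(slope) * r**2


def compute_tom(expr: ExpressionMatrix, beta: int) -> pd.DataFrame:
    """Unsigned topological overlap matrix of the soft-thresholded network.

    a_ij = |PCC(i,j)|^beta with unit diagonal;
    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the connectivity excluding the diagonal.
    """
    adj = _adjacency(expr, beta)
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    shared = a @ a  # (i,j) entry sums over u != i and u != j automatically
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    tom = (tom + tom.T) / 2.0
    return pd.DataFrame(tom, index=expr.genes, columns=expr.genes)


def detect_modules(
    tom: pd.DataFrame,
    cfg: NetworkConfig = NetworkConfig(),
    sample_set_id: str = "global",
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Branches below ``cfg.min_module_size`` become "unassigned". Modules are
    labeled provisionally by size; run :func:`merge_modules` to obtain the
    final labels.
    """
    values = tom.to_numpy()
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("TOM must be symmetric")
    if not np.allclose(np.diag(values), 1.0):
        raise ValueError("TOM diagonal must be 1")
    genes = list(tom.index)
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=cfg.cut_height, criterion="distance")
    counts: dict[int, int] = {}
    for c in raw:
        counts[c] = counts.get(c, 0) + 1
    big = [c for c, n in counts.items() if n >= cfg.min_module_size]
    if not big:
        raise ValueError(
            "all genes unassigned: no branch reaches min_module_size="
            f"{cfg.min_module_size}; lower it or raise cut_height"
        )
    # stable relabeling: decreasing size, ties by first gene index
    first_index = {c: int(np.flatnonzero(raw == c)[0]) for c in big}
    order = sorted(big, key=lambda c: (-counts[c], first_index[c]))
    names = _module_labels(len(order))
    relabel = {c: names[i] for i, c in enumerate(order)}
    labels = {
        g: relabel.get(int(c), UNASSIGNED) for g, c in zip(genes, raw)
    }
    return ModulePartition(labels, sample_set_id)


def compute_eigengenes(
    expr: ExpressionMatrix, partition: ModulePartition
) -> EigengeneMatrix:
    """First-PC eigengene per module, unit variance, positively oriented.

    Each module's submatrix is gene-standardized before the SVD; the
    eigengene is the sample-score vector of the first component, rescaled
    to unit (population) variance and sign-flipped so its mean Pearson
    correlation with member genes is non-negative. A single-gene module's
    eigengene is that gene standardized.
    """
    missing = [g for g in partition.labels if g not in set(expr.genes)]
    if missing:
        raise KeyError(f"partition genes absent from matrix: {missing[:5]}")
    rows = []
    modules = []
    for module in partition.modules:
        members = partition.members(module)
        sub = expr.data.loc[members].to_numpy().astype(float)
        mean = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=0, keepdims=True)
        ok = sd.ravel() > 0
        if not ok.any():
            logger.warning("module %s has only constant genes; skipped", module)
            continue
        z = (sub[ok] - mean[ok]) / sd[ok]
        if z.shape[0] == 1:
            eig = z[0].copy()
        else:
            # first right singular vector = PC1 sample scores direction
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            eig = vt[0]
        eig_sd = eig.std(ddof=0)
        if eig_sd == 0:
            logger.warning("module %s eigengene degenerate; skipped", module)
            continue
        eig = eig / eig_sd
        mean_corr = float(np.mean([np.corrcoef(eig, g)[0, 1] for g in z]))
        if mean_corr < 0:
            eig = -eig
        rows.append(eig)
        modules.append(module)
    data = pd.DataFrame(np.array(rows), index=modules, columns=expr.samples)
    return EigengeneMatrix(data, partition.sample_set_id)


def merge_modules(
    expr: ExpressionMatrix,
    partition: ModulePartition,
    eigengenes: EigengeneMatrix | None = None,
    merge_height: float = 0.25,
    max_rounds: int = 20,
) -> tuple[ModulePartition, EigengeneMatrix]:
    """Merge modules whose eigengenes correlate at >= 1 - merge_height.

    Iterates: average-linkage clustering of eigengenes on 1 - PCC, merging
    every group joined at or below ``merge_height``, recomputing
    eigengenes, until no pair of eigengenes correlates at or above the
    threshold. Final labels are alphabetical in decreasing module size.
    """
    if not partition.modules:
        raise ValueError("no modules to merge")
    if eigengenes is None:
        eigengenes = compute_eigengenes(expr, partition)
    labels = dict(partition.labels)
    for _ in range(max_rounds):
        modules = eigengenes.modules
        if len(modules) < 2:
            break
        em = eigengenes.data.to_numpy()
        corr = np.corrcoef(em)
        dist = 1.0 - corr
        np.fill_diagonal(dist, 0.0)
        dist = np.clip(dist, 0.0, None)
        Z = linkage(squareform(dist, checks=False), method="average")
        groups = fcluster(Z, t=merge_height, criterion="distance")
        if len(set(groups)) == len(modules):
            break
        group_of = dict(zip(modules, groups))
        merged = {
            g: (f"merged{group_of[m]}" if m != UNASSIGNED else UNASSIGNED)
            for g, m in labels.items()
        }
        labels = merged
        part = ModulePartition(labels, partition.sample_set_id)
        eigengenes = compute_eigengenes(expr, part)
    final = _relabel_by_size(ModulePartition(labels, partition.sample_set_id))
    return final, compute_eigengenes(expr, final)


def _relabel_by_size(partition: ModulePartition) -> ModulePartition:
    sizes = partition.sizes()
    first = {}
    for i, (g, m) in enumerate(partition.labels.items()):
        if m != UNASSIGNED and m not in first:
            first[m] = i
    order = sorted(sizes, key=lambda m: (-sizes[m], first[m]))
    names = _module_labels(len(order))
    mapping = {m: names[i] for i, m in enumerate(order)}
    mapping[UNASSIGNED] = UNASSIGNED
    return ModulePartition(
        {g: mapping[m] for g, m in partition.labels.items()}, partition.sample_set_id
    )


def build_modules(
    expr: ExpressionMatrix,
    cfg: NetworkConfig = NetworkConfig(),
    sample_set_id: str = "global",
) -> tuple[ModulePartition, EigengeneMatrix, int]:
    """Full module pipeline: soft threshold, TOM, detect, merge.

    Returns the merged partition, its eigengenes and the chosen power.
    """
    beta = pick_soft_threshold(expr, cfg)
    tom = compute_tom(expr, beta)
    partition = detect_modules(tom, cfg, sample_set_id)
    merged, eigengenes = merge_modules(
        expr, partition, merge_height=cfg.merge_height
    )
    return merged, eigengenes, beta
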