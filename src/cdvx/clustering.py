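"""K-means sample clustering with silhouette-based selection of k.

Samples are clustered as points in gene space (the expression matrix is
transposed internally). Cluster ids are integers 1..k, renumbered in
decreasing cluster size so that id 1 is always the largest cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .preprocess import ExpressionMatrix

__all__ = [
    "ClusterAssignment",
    "SilhouetteReport",
    "kmeans_cluster",
    "silhouette_sweep",
    "select_k",
]


@dataclass(frozen=True)
class ClusterAssignment:
    """Sample -> cluster-id map (ids 1..k, all clusters non-empty)."""

    assignment: dict[str, int]
    k: int

    def __post_init__(self) -> None:
        ids = set(self.assignment.values())
        if ids != set(range(1, self.k + 1)):
            raise ValueError(f"cluster ids must be exactly 1..{self.k}, got {sorted(ids)}")

    @property
    def sizes(self) -> dict[int, int]:
        out = {c: 0 for c in range(1, self.k + 1)}
        for c in self.assignment.values():
            out[c] += 1
        return out

    def samples_in(self, cluster: int) -> list[str]:
        return [s for s, c in self.assignment.items() if c == cluster]

    def labels_for(self, samples: Sequence[str]) -> np.ndarray:
        return np.array([self.assignment[s] for s in samples])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"sample": list(self.assignment), "cluster": list(self.assignment.values())}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "cluster": int})
        assignment = dict(zip(df["sample"], df["cluster"]))
        return cls(assignment=assignment, k=int(df["cluster"].max()))


@dataclass
class SilhouetteEntry:
    k: int
    mean_silhouette: float
    cluster_silhouettes: dict[int, list[float]]
    sizes: dict[int, int]
    criterion_a_pass: bool
    criterion_b_pass: bool
    error: str | None = None

    @property
    def admissible(self) -> bool:
        return self.error is None and self.criterion_a_pass and self.criterion_b_pass


@dataclass
class SilhouetteReport:
    entries: list[SilhouetteEntry] = field(default_factory=list)

    def entry(self, k: int) -> SilhouetteEntry:
        for e in self.entries:
            if e.k == k:
                return e
        raise KeyError(f"no entry for k={k}")

    def to_dict(self) -> dict:
        return {
            str(e.k): {
                "mean_silhouette": e.mean_silhouette,
                "sizes": {str(c): n for c, n in e.sizes.items()},
                "criterion_a_pass": e.criterion_a_pass,
                "criterion_b_pass": e.criterion_b_pass,
                "error": e.error,
            }
            for e in self.entries
        }


def kmeans_cluster(expr: ExpressionMatrix, k: int, seed: int = 1024) -> ClusterAssignment:
    """Euclidean k-means over samples; deterministic under ``seed``.

    Uses k-means++ with 10 restarts, keeping the best inertia. Labels are
    renumbered 1..k in decreasing cluster size (ties broken by the
    original label for stability).
    """
    if expr.scale_tag != "zscore":
        raise ValueError("kmeans_cluster expects a z-scored matrix (run standardize)")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > expr.n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({expr.n_samples})")
    points = expr.values.T  # samples x genes
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    raw = km.fit_predict(points)
    counts = np.bincount(raw, minlength=k)
    order = sorted(range(k), key=lambda c: (-counts[c], c))
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignment = {s: relabel[int(c)] for s, c in zip(expr.samples, raw)}
    return ClusterAssignment(assignment=assignment, k=k)


def silhouette_sweep(
    expr: ExpressionMatrix,
    k_grid: Sequence[int],
    seed: int = 1024,
    size_ratio_cap: float = 10.0,
) -> SilhouetteReport:
    """Run k-means for each k and evaluate the two admission criteria.

    Criterion (a): every cluster's maximum per-sample silhouette strictly
    exceeds the overall mean silhouette. Criterion (b): the max/min
    cluster-size ratio is at most ``size_ratio_cap``.
    """
    report = SilhouetteReport()
    points = expr.values.T
    for k in k_grid:
        try:
            ca = kmeans_cluster(expr, k, seed=seed)
            labels = ca.labels_for(expr.samples)
            sil = silhouette_samples(points, labels, metric="euclidean")
            overall = float(sil.mean())
            per_cluster = {
                c: [float(v) for v in sil[labels == c]] for c in range(1, k + 1)
            }
            crit_a = all(max(vals) > overall for vals in per_cluster.values())
            sizes = ca.sizes
            crit_b = (max(sizes.values()) / min(sizes.values())) <= size_ratio_cap
            report.entries.append(
                SilhouetteEntry(k, overall, per_cluster, sizes, crit_a, crit_b)
            )
        except ValueError as exc:
            report.entries.append(
                SilhouetteEntry(k, float("nan"), {}, {}, False, False, error=str(exc))
            )
    return report


def select_k(report: SilhouetteReport) -> int:
    """Pick the admissible k with the highest mean silhouette; tie -> larger k."""
    if not report.entries:
        raise ValueError("empty silhouette report")
    admissible = [e for e in report.entries if e.admissible]
    if not admissible:
        diag = {e.k: (e.criterion_a_pass, e.criterion_b_pass, e.error) for e in report.entries}
        raise ValueError(f"no admissible k; per-k (crit_a, crit_b, error): {diag}")
    best = max(admissible, key=lambda e: (e.mean_silhouette, e.k))
    return best.k
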