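"""Tree-ensemble regulatory network inference within a module.

Each target gene's standardized profile is regressed on the candidate
regulator profiles with a random forest; the importance of each regulator
(total variance reduction, normalized to sum to 1 per target) becomes the
edge weight. Edges are filtered at an inclusive minimum weight and the
network is exported as GraphML plus a Cytoscape-friendly SIF/attribute
pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .preprocess import ExpressionMatrix, FunctionAnnotation

__all__ = ["GRNEdgeList", "infer_grn", "filter_edges", "annotate_and_export"]

logger = logging.getLogger(__name__)


@dataclass
class GRNEdgeList:
    """Directed regulator -> target edges with importance weights."""

    edges: pd.DataFrame  # columns: regulator, target, weight
    regulators: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.edges["regulator"] == self.edges["target"]).any():
            raise ValueError("self-edges are not allowed")
        if (self.edges["weight"] < 0).any():
            raise ValueError("weights must be >= 0")

    @property
    def nodes(self) -> list[str]:
        return sorted(set(self.edges["regulator"]) | set(self.edges["target"]))

    def to_tsv(self, path: str | Path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def infer_grn(
    expr_module: ExpressionMatrix,
    regulators: Sequence[str],
    n_trees: int = 1000,
    seed: int = 1024,
) -> GRNEdgeList:
    """Random-forest importance scores for every regulator -> target pair.

    Targets are all genes in ``expr_module``; for a target that is itself
    a regulator, the target is excluded from its own candidate set.
    Incoming weights per target sum to 1. Samples are put in a canonical
    order internally so the result is invariant to column permutations.
    """
    if expr_module.n_samples < 10:
        raise ValueError("need at least 10 samples for network inference")
    regulators = [r for r in regulators if r in set(expr_module.genes)]
    if not regulators:
        raise ValueError("no candidate regulators present in the module")
    data = expr_module.data[sorted(expr_module.samples)]
    values = data.to_numpy().astype(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    z = (values - mean) / sd
    zrow = {g: z[i] for i, g in enumerate(data.index)}

    rows = []
    for t_idx, target in enumerate(data.index):
        candidates = [r for r in regulators if r != target]
        if not candidates:
            raise ValueError(f"no regulators left for target {target}")
        X = np.stack([zrow[r] for r in candidates], axis=1)
        y = zrow[target]
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=seed + t_idx,
            n_jobs=1,
        )
        rf.fit(X, y)
        importances = rf.feature_importances_
        total = importances.sum()
        if total > 0:
            importances = importances / total
        for r, w in zip(candidates, importances):
            rows.append({"regulator": r, "target": target, "weight": float(w)})
    edges = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    return GRNEdgeList(edges, regulators=list(regulators))


def filter_edges(
    edges: GRNEdgeList, min_weight: float = 0.06, drop_isolated: bool = True
) -> GRNEdgeList:
    """Keep edges with weight >= min_weight (inclusive bound)."""
    kept = edges.edges[edges.edges["weight"] >= min_weight].reset_index(drop=True)
    if kept.empty:
        logger.warning("no edges survive the %.3f weight filter", min_weight)
    return GRNEdgeList(kept, regulators=edges.regulators)


def annotate_and_export(
    edges: GRNEdgeList,
    cdv: pd.DataFrame | None,
    annot: FunctionAnnotation | None,
    out_prefix: str | Path,
) -> nx.DiGraph:
    """Write GraphML plus SIF + node-attribute TSV for Cytoscape.

    Node attributes: ``cdv`` (omitted, not zero-filled, when the gene has
    no eligible CDV row), ``is_regulator`` and ``bin``. Edge attribute:
    ``weight``. Returns the annotated graph.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    graph = nx.DiGraph()
    cdv_of: dict[str, float] = {}
    if cdv is not None and not cdv.empty:
        eligible = cdv[cdv["eligible"]]
        cdv_of = dict(zip(eligible["gene"], eligible["cdv"]))
    regulator_set = set(edges.regulators)
    for node in edges.nodes:
        attrs: dict = {"is_regulator": node in regulator_set}
        if node in cdv_of:
            attrs["cdv"] = float(cdv_of[node])
        if annot is not None:
            bins = sorted(annot.bins_of(node))
            if bins:
                attrs["bin"] = ";".join(bins)
        graph.add_node(node, **attrs)
    for r in edges.edges.itertuples(index=False):
        graph.add_edge(r.regulator, r.target, weight=float(r.weight))
    try:
        nx.write_graphml(graph, f"{out_prefix}.graphml")
        with open(f"{out_prefix}.sif", "w") as fh:
            for r in edges.edges.itertuples(index=False):
                fh.write(f"{r.regulator}\tregulates\t{r.target}\n")
        node_rows = []
        for node, attrs in graph.nodes(data=True):
            node_rows.append(
                {
                    "gene": node,
                    "cdv": attrs.get("cdv", ""),
                    "is_regulator": attrs["is_regulator"],
                    "bin": attrs.get("bin", ""),
                }
            )
        pd.DataFrame(node_rows, columns=["gene", "cdv", "is_regulator", "bin"]).to_csv(
            f"{out_prefix}.nodes.tsv", sep="\t", index=False
        )
    except OSError as exc:
        raise OSError(f"failed writing network files at {out_prefix}: {exc}") from exc
    return graph
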