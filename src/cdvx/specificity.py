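"""Condition-specificity statistics.

GMC (gene-module consistency) is the Pearson correlation between a
gene's expression profile and the eigengene of the module it belongs to.
CDV (correlation difference value) contrasts, over the samples of one
cluster, a gene's correlation with its cluster-specific-module eigengene
against its correlation with its global-module eigengene restricted to
those same samples:

    CDV = PCC_m(g, ceg) - PCC_m(g, geg|cluster samples)

so CDV ranges over [-2, 2] and is large for genes whose co-expression
partners change inside the cluster. Only genes passing the double GMC
eligibility gate (cluster GMC and full-compendium global GMC both at or
above the floor) receive a CDV.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_mutual_info_score, fowlkes_mallows_score

from .clustering import ClusterAssignment
from .enrichment import annotation_to_term_sets, enrich_groups
from .modules import EigengeneMatrix, ModulePartition
from .preprocess import ExpressionMatrix, FunctionAnnotation

__all__ = [
    "gmc",
    "compute_gmc_table",
    "compute_cdv_table",
    "fms",
    "amis",
    "cdv_threshold_sweep",
    "function_cdv_matrix",
]

logger = logging.getLogger(__name__)


class ConstantProfileError(ValueError):
    """A correlation was requested against a constant vector."""


def gmc(gene_profile: Sequence[float], eigengene_profile: Sequence[float]) -> float:
    """Pearson correlation between a gene profile and an eigengene profile."""
    g = np.asarray(gene_profile, dtype=float)
    e = np.asarray(eigengene_profile, dtype=float)
    if g.shape != e.shape or g.ndim != 1:
        raise ValueError("profiles must be 1-D vectors of equal length")
    if g.size < 3:
        raise ValueError("need at least 3 samples")
    gd = g - g.mean()
    ed = e - e.mean()
    gss = float(gd @ gd)
    ess = float(ed @ ed)
    if gss == 0 or ess == 0:
        raise ConstantProfileError("constant profile has no defined correlation")
    return float(gd @ ed / np.sqrt(gss * ess))


def compute_gmc_table(
    expr: ExpressionMatrix,
    partition: ModulePartition,
    eigengenes: EigengeneMatrix,
) -> pd.DataFrame:
    """One GMC row per assigned gene against its own module's eigengene.

    ``expr`` must cover the partition's sample set; genes whose module has
    no eigengene are skipped with a warning.
    """
    if partition.sample_set_id != eigengenes.sample_set_id:
        raise ValueError("partition and eigengenes come from different sample sets")
    samples = eigengenes.samples
    sub = expr.subset_samples(samples)
    have = set(eigengenes.modules)
    rows = []
    for gene, module in partition.assigned().items():
        if module not in have:
            logger.warning("gene %s: module %s lacks an eigengene; skipped", gene, module)
            continue
        profile = sub.data.loc[gene].to_numpy()
        try:
            value = gmc(profile, eigengenes.profile(module))
        except ConstantProfileError:
            logger.warning("gene %s constant over %s; skipped", gene, partition.sample_set_id)
            continue
        rows.append(
            {
                "gene": gene,
                "sample_set_id": partition.sample_set_id,
                "module": module,
                "gmc": value,
                "n_samples": len(samples),
            }
        )
    return pd.DataFrame(rows, columns=["gene", "sample_set_id", "module", "gmc", "n_samples"])


def compute_cdv_table(
    expr: ExpressionMatrix,
    cluster: ClusterAssignment,
    cluster_id: int,
    global_partition: ModulePartition,
    global_eigengenes: EigengeneMatrix,
    cluster_partition: ModulePartition,
    cluster_eigengenes: EigengeneMatrix,
    gmc_floor: float = 0.6,
    require_both: bool = True,
) -> pd.DataFrame:
    """Per-gene CDV for one sample cluster.

    For each gene assigned in both partitions, three correlations are
    computed: ``gmc_cluster`` (cluster samples vs the cluster-module
    eigengene), ``gmc_global_full`` (all samples vs the global-module
    eigengene) and ``gmc_global_restricted`` (cluster samples vs the
    global-module eigengene restricted to them). Eligibility requires
    ``gmc_cluster >= gmc_floor`` and ``gmc_global_full >= gmc_floor``
    (or either one when ``require_both=False``); eligible genes get
    ``cdv = gmc_cluster - gmc_global_restricted``.
    """
    cluster_samples = [s for s in cluster_eigengenes.samples]
    member_samples = set(cluster.samples_in(cluster_id))
    if member_samples != set(cluster_samples):
        raise ValueError(
            "cluster eigengenes were not computed on cluster "
            f"{cluster_id}'s samples"
        )
    global_samples = global_eigengenes.samples
    if not member_samples <= set(global_samples):
        raise ValueError("cluster samples are not a subset of the global sample set")

    expr_global = expr.subset_samples(global_samples)
    expr_cluster = expr.subset_samples(cluster_samples)
    g_assigned = global_partition.assigned()
    c_assigned = cluster_partition.assigned()
    common = [g for g in c_assigned if g in g_assigned]
    g_have = set(global_eigengenes.modules)
    c_have = set(cluster_eigengenes.modules)

    restricted_global = global_eigengenes.data[cluster_samples]

    rows = []
    for gene in common:
        gmod, cmod = g_assigned[gene], c_assigned[gene]
        if gmod not in g_have or cmod not in c_have:
            continue
        g_full = expr_global.data.loc[gene].to_numpy()
        g_clu = expr_cluster.data.loc[gene].to_numpy()
        record = {
            "gene": gene,
            "cluster": cluster_id,
            "global_module": gmod,
            "cluster_module": cmod,
            "gmc_cluster": np.nan,
            "gmc_global_full": np.nan,
            "gmc_global_restricted": np.nan,
            "cdv": np.nan,
            "eligible": False,
            "reason": "",
        }
        try:
            record["gmc_cluster"] = gmc(g_clu, cluster_eigengenes.profile(cmod))
            record["gmc_global_full"] = gmc(g_full, global_eigengenes.profile(gmod))
        except ConstantProfileError:
            record["reason"] = "constant profile"
            rows.append(record)
            continue
        try:
            restricted = gmc(g_clu, restricted_global.loc[gmod].to_numpy())
            record["gmc_global_restricted"] = restricted
        except ConstantProfileError:
            record["reason"] = "global eigengene constant over cluster samples"
            rows.append(record)
            continue
        gc, gf = record["gmc_cluster"], record["gmc_global_full"]
        if require_both:
            eligible = gc >= gmc_floor and gf >= gmc_floor
        else:
            eligible = gc >= gmc_floor or gf >= gmc_floor
        record["eligible"] = bool(eligible)
        if eligible:
            record["cdv"] = gc - restricted
        else:
            record["reason"] = "gmc below floor"
        rows.append(record)
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "cluster",
            "global_module",
            "cluster_module",
            "gmc_cluster",
            "gmc_global_full",
            "gmc_global_restricted",
            "cdv",
            "eligible",
            "reason",
        ],
    )


def _common_assigned(p: ModulePartition, q: ModulePartition) -> list[str]:
    pa, qa = p.assigned(), q.assigned()
    return [g for g in pa if g in qa]


def fms(p: ModulePartition, q: ModulePartition, genes: Sequence[str] | None = None) -> float:
    """Fowlkes-Mallows score between two partitions of the same genes.

    Genes unassigned in either partition are dropped; ``genes`` optionally
    restricts the comparison further.
    """
    labels_p, labels_q = _paired_labels(p, q, genes)
    return float(fowlkes_mallows_score(labels_p, labels_q))


def amis(p: ModulePartition, q: ModulePartition, genes: Sequence[str] | None = None) -> float:
    """Adjusted mutual information between two partitions (1.0 when
    identical, including the degenerate both-single-cluster case)."""
    labels_p, labels_q = _paired_labels(p, q, genes)
    return float(adjusted_mutual_info_score(labels_p, labels_q, average_method="arithmetic"))


def _paired_labels(
    p: ModulePartition, q: ModulePartition, genes: Sequence[str] | None
) -> tuple[list[str], list[str]]:
    common = _common_assigned(p, q)
    if genes is not None:
        keep = set(genes)
        common = [g for g in common if g in keep]
    if len(common) < 2:
        raise ValueError("fewer than 2 genes assigned in both partitions")
    pa, qa = p.assigned(), q.assigned()
    return [pa[g] for g in common], [qa[g] for g in common]


def cdv_threshold_sweep(
    cdv: pd.DataFrame,
    global_partition: ModulePartition,
    cluster_partition: ModulePartition,
    thresholds: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Partition similarity among eligible genes with cdv <= t, per t.

    Rows where too few genes remain carry NaN similarities. Retained
    gene sets are nested, so counts are monotone non-decreasing in t.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.0, 1.0001, 0.05), 10)
    thresholds = sorted(float(t) for t in thresholds)
    eligible = cdv[cdv["eligible"]]
    if eligible.empty:
        raise ValueError("no eligible genes in CDV table")
    rows = []
    for t in thresholds:
        genes = eligible.loc[eligible["cdv"] <= t, "gene"].tolist()
        record = {"threshold": t, "n_genes": len(genes), "fms": np.nan, "amis": np.nan}
        try:
            record["fms"] = fms(global_partition, cluster_partition, genes)
            record["amis"] = amis(global_partition, cluster_partition, genes)
        except ValueError:
            logger.warning("threshold %.3f retains too few genes", t)
        rows.append(record)
    return pd.DataFrame(rows, columns=["threshold", "n_genes", "fms", "amis"])


def function_cdv_matrix(
    cdv: pd.DataFrame,
    annot: FunctionAnnotation,
    groups: Mapping[str, Sequence[str]],
    population: Sequence[str],
    min_bin_size: int = 100,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mean CDV and enrichment per (group, function bin).

    Bins must contain strictly more than ``min_bin_size`` genes (within
    the population) to be reported. ``groups`` maps a group id (module
    label or cluster id) to its member genes; ``population`` is the
    filtered gene universe. Cells with members but no CDV-bearing gene
    get ``empty=True`` and no mean.
    """
    population = list(population)
    pop_set = set(population)
    term_sets = annotation_to_term_sets(annot)["function"]
    kept_bins = {
        b: set(members) & pop_set
        for b, members in term_sets.items()
        if len(set(members) & pop_set) > min_bin_size
    }
    if not kept_bins:
        return pd.DataFrame(
            columns=["group", "bin", "mean_cdv", "n_cdv_genes", "fdr", "significant", "empty"]
        )
    enr = enrich_groups(
        groups, {"function": kept_bins}, population, alpha=alpha
    )
    enr_key = {
        (r.group, r.term): (r.fdr, r.significant) for r in enr.itertuples(index=False)
    }
    cdv_of = dict(
        zip(cdv.loc[cdv["eligible"], "gene"], cdv.loc[cdv["eligible"], "cdv"])
    )
    rows = []
    for group_id, members in groups.items():
        member_set = set(members)
        for bin_id, bin_genes in sorted(kept_bins.items()):
            cell = member_set & bin_genes
            values = [cdv_of[g] for g in cell if g in cdv_of]
            fdr, signif = enr_key.get((group_id, bin_id), (np.nan, False))
            rows.append(
                {
                    "group": group_id,
                    "bin": bin_id,
                    "mean_cdv": float(np.mean(values)) if values else np.nan,
                    "n_cdv_genes": len(values),
                    "fdr": fdr,
                    "significant": bool(signif),
                    "empty": len(values) == 0,
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "bin", "mean_cdv", "n_cdv_genes", "fdr", "significant", "empty"]
    )
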