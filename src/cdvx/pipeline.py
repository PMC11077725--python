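"""End-to-end orchestration of the condition-specific co-expression study.

Stages: preprocess -> sample clustering -> metadata annotation -> global
and per-cluster module detection -> GMC/CDV -> threshold sweep ->
function-level CDV maps -> regulatory network. Every stage writes its
outputs before the next starts and the run manifest records parameters,
counts and output checksums, so a rerun with the same config is
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import clustering, enrichment, grn, modules, specificity
from .preprocess import (
    ExpressionMatrix,
    FunctionAnnotation,
    filter_genes,
    load_annotation,
    load_expression,
    log_transform,
    standardize,
)

logger = logging.getLogger(__name__)

STAGES = [
    "preprocess",
    "cluster",
    "metadata_annotation",
    "modules",
    "specificity",
    "threshold_sweep",
    "function_maps",
    "grn",
]


@dataclass
class RunConfig:
    expression: str
    metadata: str
    annotation: str
    outdir: str
    regulators: str | None = None
    k: int = 4
    seed: int = 1024
    min_mean_tpm: float = 2.0
    gmc_floor: float = 0.6
    merge_height: float = 0.25
    min_module_size: int = 30
    cut_height: float = 0.99
    min_bin_size: int = 100
    min_weight: float = 0.06
    alpha: float = 0.05
    n_trees: int = 1000
    grn_module: str | None = None  # default: auto-pick per cluster below
    grn_cluster: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)

    def validate(self) -> None:
        for name in ("expression", "metadata", "annotation"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.regulators and not Path(self.regulators).exists():
            raise FileNotFoundError(f"regulators file not found: {self.regulators}")
        if not (0 < self.merge_height < 1):
            raise ValueError("merge_height must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": config.__dict__.copy(), "stages": {}, "outputs": {}}

    def record(stage: str, files: Sequence[Path], **counts) -> None:
        manifest["stages"][stage] = {"counts": counts, "outputs": [f.name for f in files]}
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)
        logger.info("stage %s done: %s", stage, counts)

    try:
        # 1. preprocess
        expr = load_expression(config.expression)
        annot = load_annotation(config.annotation)
        filtered = filter_genes(expr, annot, config.min_mean_tpm)
        logexpr = log_transform(filtered)
        zexpr = standardize(filtered)
        f_path = outdir / "filtered.tsv"
        filtered.to_tsv(f_path)
        record(
            "preprocess",
            [f_path],
            genes_in=expr.n_genes,
            genes_kept=filtered.n_genes,
            samples=filtered.n_samples,
        )

        # 2. k-means clustering
        assignment = clustering.kmeans_cluster(zexpr, config.k, seed=config.seed)
        c_path = outdir / "clusters.tsv"
        assignment.to_tsv(c_path)
        record("cluster", [c_path], k=config.k, sizes=assignment.sizes)

        # 3. metadata annotation of clusters
        metadata = pd.read_csv(config.metadata, sep="\t", dtype=str)
        term_sets, missing = enrichment.metadata_to_term_sets(metadata)
        groups = {
            str(c): assignment.samples_in(c) for c in range(1, config.k + 1)
        }
        meta_enr = enrichment.enrich_groups(
            groups,
            term_sets,
            list(assignment.assignment),
            alpha=config.alpha,
            excluded=missing,
        )
        me_path = outdir / "cluster_metadata_enrichment.tsv"
        meta_enr.to_csv(me_path, sep="\t", index=False)
        record(
            "metadata_annotation",
            [me_path],
            significant=int(meta_enr["significant"].sum()),
        )

        # 4. global modules
        net_cfg = modules.NetworkConfig(
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            merge_height=config.merge_height,
        )
        g_part, g_eig, g_beta = modules.build_modules(logexpr, net_cfg, "global")
        gp_path = outdir / "modules_global.tsv"
        ge_path = outdir / "eigengenes_global.tsv"
        g_part.to_tsv(gp_path)
        g_eig.to_tsv(ge_path)
        files = [gp_path, ge_path]
        counts = {"global_modules": len(g_part.modules), "power": g_beta}
        cluster_parts: dict[int, modules.ModulePartition] = {}
        cluster_eigs: dict[int, modules.EigengeneMatrix] = {}
        for c in range(1, config.k + 1):
            sub = logexpr.subset_samples(assignment.samples_in(c))
            part, eig, _ = modules.build_modules(sub, net_cfg, f"cluster-{c}")
            cluster_parts[c], cluster_eigs[c] = part, eig
            pp = outdir / f"modules_cluster{c}.tsv"
            ep = outdir / f"eigengenes_cluster{c}.tsv"
            part.to_tsv(pp)
            eig.to_tsv(ep)
            files += [pp, ep]
            counts[f"cluster{c}_modules"] = len(part.modules)
        record("modules", files, **counts)

        # 6. GMC + CDV
        files = []
        gmc_global = specificity.compute_gmc_table(logexpr, g_part, g_eig)
        gg_path = outdir / "gmc_global.tsv"
        gmc_global.to_csv(gg_path, sep="\t", index=False)
        files.append(gg_path)
        cdv_tables: dict[int, pd.DataFrame] = {}
        for c in range(1, config.k + 1):
            cdv = specificity.compute_cdv_table(
                logexpr,
                assignment,
                c,
                g_part,
                g_eig,
                cluster_parts[c],
                cluster_eigs[c],
                gmc_floor=config.gmc_floor,
            )
            cdv_tables[c] = cdv
            cp = outdir / f"cdv_cluster{c}.tsv"
            cdv.to_csv(cp, sep="\t", index=False)
            files.append(cp)
        record(
            "specificity",
            files,
            eligible={c: int(t["eligible"].sum()) for c, t in cdv_tables.items()},
        )

        # 7. CDV threshold sweep
        files = []
        for c in range(1, config.k + 1):
            try:
                curve = specificity.cdv_threshold_sweep(
                    cdv_tables[c], g_part, cluster_parts[c]
                )
            except ValueError as exc:
                logger.warning("sweep skipped for cluster %d: %s", c, exc)
                continue
            sp = outdir / f"sweep_cluster{c}.tsv"
            curve.to_csv(sp, sep="\t", index=False)
            files.append(sp)
        record("threshold_sweep", files, clusters=len(files))

        # 8. function-level CDV maps (clusters on one axis, and the focus
        # cluster's modules on the other)
        files = []
        population = filtered.genes
        cluster_groups = {
            f"cluster-{c}": list(cdv_tables[c]["gene"]) for c in range(1, config.k + 1)
        }
        fc = specificity.function_cdv_matrix(
            pd.concat(cdv_tables.values(), ignore_index=True),
            annot,
            cluster_groups,
            population,
            min_bin_size=config.min_bin_size,
            alpha=config.alpha,
        )
        fc_path = outdir / "function_cdv_by_cluster.tsv"
        fc.to_csv(fc_path, sep="\t", index=False)
        files.append(fc_path)
        focus = config.grn_cluster or _most_specific_cluster(cdv_tables)
        module_groups = {
            m: cluster_parts[focus].members(m) for m in cluster_parts[focus].modules
        }
        fm = specificity.function_cdv_matrix(
            cdv_tables[focus],
            annot,
            module_groups,
            population,
            min_bin_size=config.min_bin_size,
            alpha=config.alpha,
        )
        fm_path = outdir / f"function_cdv_modules_cluster{focus}.tsv"
        fm.to_csv(fm_path, sep="\t", index=False)
        files.append(fm_path)
        record("function_maps", files, focus_cluster=focus)

        # 9. regulatory network in the chosen module of the focus cluster
        regulators = _load_regulators(config, annot)
        module_label = config.grn_module or _highest_cdv_module(cdv_tables[focus])
        module_genes = cluster_parts[focus].members(module_label)
        sub = logexpr.subset_genes(module_genes).subset_samples(
            assignment.samples_in(focus)
        )
        cand = [r for r in regulators if r in set(module_genes)]
        if not cand:
            logger.warning("no regulators in module %s; GRN stage skipped", module_label)
            record("grn", [], skipped=1)
        else:
            net = grn.infer_grn(sub, cand, n_trees=config.n_trees, seed=config.seed)
            kept = grn.filter_edges(net, min_weight=config.min_weight)
            prefix = outdir / f"grn_cluster{focus}_{module_label}"
            grn.annotate_and_export(kept, cdv_tables[focus], annot, prefix)
            kept.to_tsv(outdir / f"grn_cluster{focus}_{module_label}.edges.tsv")
            record(
                "grn",
                [
                    Path(f"{prefix}.graphml"),
                    Path(f"{prefix}.sif"),
                    Path(f"{prefix}.nodes.tsv"),
                    Path(f"{prefix}.edges.tsv"),
                ],
                module=module_label,
                edges_kept=len(kept.edges),
            )
    except Exception as exc:
        stage = STAGES[min(len(manifest["stages"]), len(STAGES) - 1)]
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest


def _load_regulators(config: RunConfig, annot: FunctionAnnotation) -> list[str]:
    if config.regulators:
        text = Path(config.regulators).read_text().split()
        return [g for g in text if g]
    # default: genes annotated to transcription-factor-like bins
    tf_bins = {b for b in annot.bins if "transcription" in b.lower() or "tf" in b.lower()}
    return sorted(g for g, bins in annot.gene_bins.items() if bins & tf_bins)


def _most_specific_cluster(cdv_tables: dict[int, pd.DataFrame]) -> int:
    """Cluster whose eligible genes have the highest mean CDV."""
    best, best_val = None, -np.inf
    for c, table in cdv_tables.items():
        eligible = table[table["eligible"]]
        if eligible.empty:
            continue
        val = float(eligible["cdv"].mean())
        if val > best_val:
            best, best_val = c, val
    if best is None:
        raise ValueError("no cluster has eligible CDV genes")
    return best


def _highest_cdv_module(cdv: pd.DataFrame) -> str:
    eligible = cdv[cdv["eligible"]]
    if eligible.empty:
        raise ValueError("no eligible genes to choose a module from")
    means = eligible.groupby("cluster_module")["cdv"].mean()
    return str(means.idxmax())


def condition_expression_summary(
    expr: ExpressionMatrix, samples: Sequence[str], genes: Sequence[str]
) -> pd.DataFrame:
    """Long-format z-scores of selected genes over selected samples.

    The z-score is computed over the selected samples only. Constant
    genes are flagged (``constant=True``) with no z value.
    """
    missing = [s for s in samples if s not in set(expr.samples)]
    missing += [g for g in genes if g not in set(expr.genes)]
    if missing:
        raise KeyError(f"unknown ids: {missing[:10]}")
    sub = expr.data.loc[list(genes), list(samples)]
    rows = []
    for gene, profile in sub.iterrows():
        values = profile.to_numpy().astype(float)
        sd = values.std(ddof=0)
        constant = sd == 0
        z = (values - values.mean()) / sd if not constant else None
        for i, sample in enumerate(samples):
            rows.append(
                {
                    "gene": gene,
                    "sample": sample,
                    "z": float(z[i]) if z is not None else np.nan,
                    "constant": bool(constant),
                }
            )
    return pd.DataFrame(rows, columns=["gene", "sample", "z", "constant"])
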