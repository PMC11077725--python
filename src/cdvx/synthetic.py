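"""Synthetic expression compendia with planted ground truth.

The generative model works on the log2 scale: each co-expression module is
driven by a latent factor, gene log-expression is ``loading * factor +
cluster offset + noise`` plus a per-gene baseline, and TPM values are
obtained by exponentiation. Conserved modules share one factor across all
sample clusters. Condition-specific modules follow their own latent factor
inside their home cluster but track a designated conserved ("partner")
module's factor elsewhere, so their correlation structure — not their
abundance — is what distinguishes the home cluster.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix, FunctionAnnotation

__all__ = [
    "ModuleSpec",
    "GRNSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate",
    "default_config",
]

ROOT_BIN = "BIN.root"


class SyntheticConfigError(ValueError):
    """Configuration invariant violation; the message names the field."""


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    ``kind`` is ``"conserved"`` (one latent factor over all samples) or
    ``"specific"`` (own factor in ``home_cluster``, partner module's factor
    elsewhere). ``home_mix`` blends a fraction of the partner factor into
    the home-cluster profile so that specific genes stay attached to the
    partner's global module.
    """

    name: str
    size: int
    kind: str = "conserved"
    home_cluster: Optional[int] = None
    partner: Optional[str] = None
    loading_mean: float = 1.0
    loading_sd: float = 0.1
    home_mix: float = 0.2


@dataclass
class GRNSpec:
    """A small linear regulator->target network planted inside one
    specific module (targets are linear combinations of regulator
    profiles plus noise)."""

    n_regulators: int = 5
    n_targets: int = 20
    coef_range: tuple[float, float] = (0.8, 1.2)
    max_regulators_per_target: int = 2
    regulator_noise_sd: float = 0.6
    target_noise_sd: float = 0.25


@dataclass
class SyntheticConfig:
    n_clusters: int = 4
    samples_per_cluster: list[int] = field(default_factory=lambda: [40, 40, 40, 40])
    modules: list[ModuleSpec] = field(default_factory=list)
    n_background_genes: int = 1540
    noise_sd: float = 0.4
    background_noise_sd: float = 0.8
    cluster_shift_sd: float = 5.0
    background_shift_sd: float = 0.8
    background_dropout: float = 0.3
    baseline_range: tuple[float, float] = (3.0, 8.0)
    dropout_baseline_range: tuple[float, float] = (-3.0, -1.0)
    metadata_categories: tuple[str, ...] = ("cultivar", "tissue", "treatment")
    metadata_affinity: float = 0.85
    metadata_missing_rate: float = 0.05
    bin_padding: int = 60
    n_decoy_bins: int = 3
    decoy_bin_size: int = 120
    grn: Optional[GRNSpec] = field(default_factory=GRNSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.n_clusters < 1:
            raise SyntheticConfigError("n_clusters must be >= 1")
        if len(self.samples_per_cluster) != self.n_clusters:
            raise SyntheticConfigError(
                "samples_per_cluster length must equal n_clusters"
            )
        if any(m < 3 for m in self.samples_per_cluster):
            raise SyntheticConfigError("samples_per_cluster entries must all be >= 3")
        if self.noise_sd <= 0:
            raise SyntheticConfigError("noise_sd must be > 0")
        if not 0 <= self.background_dropout <= 1:
            raise SyntheticConfigError("background_dropout must be in [0, 1]")
        names = [m.name for m in self.modules]
        if len(set(names)) != len(names):
            raise SyntheticConfigError("modules must have unique names")
        conserved = {m.name for m in self.modules if m.kind == "conserved"}
        for m in self.modules:
            if m.kind not in ("conserved", "specific"):
                raise SyntheticConfigError(f"modules[{m.name}].kind must be conserved|specific")
            if m.size < 1:
                raise SyntheticConfigError(f"modules[{m.name}].size must be >= 1")
            if m.kind == "specific":
                if m.home_cluster is None or not (1 <= m.home_cluster <= self.n_clusters):
                    raise SyntheticConfigError(
                        f"modules[{m.name}].home_cluster must name a cluster in 1..{self.n_clusters}"
                    )
                if m.partner is not None and m.partner not in conserved:
                    raise SyntheticConfigError(
                        f"modules[{m.name}].partner must name a conserved module"
                    )
        if self.grn is not None and self.modules:
            specific = [m for m in self.modules if m.kind == "specific"]
            if specific:
                host = specific[0]
                if self.grn.n_regulators + self.grn.n_targets > host.size:
                    raise SyntheticConfigError(
                        "grn regulators+targets exceed the host module size"
                    )


@dataclass
class SyntheticTruth:
    """Planted ground truth for every downstream stage."""

    true_cluster: dict[str, int]
    true_module: dict[str, str]
    specificity_label: dict[str, str]
    true_edges: list[tuple[str, str, float]]
    module_home: dict[str, int]
    planted_terms: dict[str, dict[int, str]]
    module_bins: dict[str, str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_cluster": self.true_cluster,
            "true_module": self.true_module,
            "specificity_label": self.specificity_label,
            "true_edges": [[r, t, c] for r, t, c in self.true_edges],
            "module_home": self.module_home,
            "planted_terms": {
                cat: {str(c): t for c, t in terms.items()}
                for cat, terms in self.planted_terms.items()
            },
            "module_bins": self.module_bins,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    metadata: pd.DataFrame  # columns: sample, category, term
    annotation: FunctionAnnotation
    regulators: list[str]
    truth: SyntheticTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.expression.to_tsv(outdir / "expression.tsv")
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        self.annotation.to_tsv(outdir / "function_bins.tsv")
        (outdir / "regulators.txt").write_text("\n".join(self.regulators) + "\n")
        self.truth.to_json(outdir / "truth.json")


def default_config(seed: int = 0) -> SyntheticConfig:
    """The reference desk-scale scenario: 4 clusters x 40 samples,
    three conserved and three specific modules, ~2000 genes."""
    modules = [
        ModuleSpec("CONS1", 150, "conserved"),
        ModuleSpec("CONS2", 90, "conserved"),
        ModuleSpec("CONS3", 80, "conserved"),
        ModuleSpec("SPEC1", 50, "specific", home_cluster=1, partner="CONS1"),
        ModuleSpec("SPEC2", 50, "specific", home_cluster=2, partner="CONS2"),
        ModuleSpec("SPEC3", 40, "specific", home_cluster=3, partner="CONS3"),
    ]
    return SyntheticConfig(modules=modules, seed=seed)


def _assign_partners(config: SyntheticConfig) -> dict[str, str]:
    conserved = [m.name for m in config.modules if m.kind == "conserved"]
    partners: dict[str, str] = {}
    i = 0
    for m in config.modules:
        if m.kind != "specific":
            continue
        if m.partner is not None:
            partners[m.name] = m.partner
        else:
            if not conserved:
                raise SyntheticConfigError(
                    f"modules[{m.name}].partner: no conserved module available"
                )
            partners[m.name] = conserved[i % len(conserved)]
            i += 1
    return partners


def _simplex_mean_patterns(
    K: int, conserved: list[ModuleSpec], amplitude: float
) -> dict[str, np.ndarray]:
    """Per-module cluster mean patterns placing the K cluster centroids
    on a regular simplex.

    Rows of the Helmert sub-matrix are orthonormal contrasts, so summing
    over modules (amplitudes equalized by module size) keeps every
    cluster pair equidistant — no k smaller than K offers a natural
    coarser split.
    """
    if not conserved:
        return {}
    helmert = np.zeros((K - 1, K)) if K > 1 else np.zeros((1, 1))
    for r in range(1, K):
        helmert[r - 1, :r] = 1.0
        helmert[r - 1, r] = -r
        helmert[r - 1] /= np.linalg.norm(helmert[r - 1])
    mean_size = float(np.mean([m.size for m in conserved]))
    out: dict[str, np.ndarray] = {}
    for j, m in enumerate(conserved):
        row = helmert[j % max(1, K - 1)]
        weight = np.sqrt(mean_size / m.size)
        out[m.name] = amplitude * np.sqrt(K) * weight * row
    return out


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one synthetic compendium; byte-identical under a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    partners = _assign_partners(config)

    n_samples = int(sum(config.samples_per_cluster))
    sample_ids: list[str] = []
    sample_cluster = np.empty(n_samples, dtype=int)
    pos = 0
    for c, m in enumerate(config.samples_per_cluster, start=1):
        for j in range(m):
            sample_ids.append(f"C{c}S{j + 1:03d}")
        sample_cluster[pos : pos + m] = c
        pos += m

    # latent factors: conserved modules get one global vector; specific
    # modules get an own home factor blended per home_mix, partner factor
    # elsewhere. Cluster separation (what k-means recovers) enters as a
    # per-(module, cluster) mean shift on the factor, so it travels
    # coherently with the module instead of adding incoherent per-gene
    # variance.
    factors: dict[str, np.ndarray] = {}
    K = config.n_clusters
    conserved_specs = [m for m in config.modules if m.kind == "conserved"]
    patterns = _simplex_mean_patterns(K, conserved_specs, config.cluster_shift_sd)
    for m in conserved_specs:
        factors[m.name] = rng.standard_normal(n_samples) + patterns[m.name][
            sample_cluster - 1
        ]
    for m in config.modules:
        if m.kind != "specific":
            continue
        cf = factors[partners[m.name]]
        home = sample_cluster == m.home_cluster
        hf = rng.standard_normal(int(home.sum())) + config.cluster_shift_sd
        f = cf.copy()
        rho = m.home_mix
        f[home] = rho * cf[home] + np.sqrt(max(0.0, 1.0 - rho**2)) * hf
        factors[m.name] = f

    # gene bookkeeping
    gene_ids: list[str] = []
    true_module: dict[str, str] = {}
    specificity_label: dict[str, str] = {}
    module_genes: dict[str, list[str]] = {}
    gi = 0
    for m in config.modules:
        ids = [f"G{gi + j:05d}" for j in range(m.size)]
        gi += m.size
        gene_ids.extend(ids)
        module_genes[m.name] = ids
        for g in ids:
            true_module[g] = m.name
            specificity_label[g] = "specific" if m.kind == "specific" else "conserved"
    background_ids = [f"G{gi + j:05d}" for j in range(config.n_background_genes)]
    gene_ids.extend(background_ids)
    for g in background_ids:
        true_module[g] = "background"
        specificity_label[g] = "background"

    n_genes = len(gene_ids)
    log_dev = np.empty((n_genes, n_samples))
    row = {g: i for i, g in enumerate(gene_ids)}

    grn_spec = config.grn
    specific_modules = [m for m in config.modules if m.kind == "specific"]
    grn_host = specific_modules[0].name if (grn_spec and specific_modules) else None

    regulators: list[str] = []
    true_edges: list[tuple[str, str, float]] = []

    for m in config.modules:
        f = factors[m.name]
        ids = module_genes[m.name]
        loadings = rng.normal(m.loading_mean, m.loading_sd, size=len(ids))
        base = np.outer(loadings, f)
        if grn_host == m.name:
            nr, nt = grn_spec.n_regulators, grn_spec.n_targets
            regulators = ids[:nr]
            targets = ids[nr : nr + nt]
            reg_profiles = base[:nr] + rng.normal(
                0.0, grn_spec.regulator_noise_sd, size=(nr, n_samples)
            )
            base[:nr] = reg_profiles
            lo, hi = grn_spec.coef_range
            for t_idx, t in enumerate(targets):
                n_parents = int(rng.integers(1, grn_spec.max_regulators_per_target + 1))
                parents = rng.choice(nr, size=n_parents, replace=False)
                coefs = rng.uniform(lo, hi, size=n_parents)
                profile = coefs @ reg_profiles[parents] / np.sqrt((coefs**2).sum())
                profile = profile + rng.normal(
                    0.0, grn_spec.target_noise_sd, size=n_samples
                )
                base[nr + t_idx] = profile
                for p, cf_ in zip(parents, coefs):
                    true_edges.append((ids[int(p)], t, float(cf_)))
            noise_rows = np.ones(len(ids), dtype=bool)
            noise_rows[: nr + nt] = False
            base[noise_rows] += rng.normal(
                0.0, config.noise_sd, size=(int(noise_rows.sum()), n_samples)
            )
        else:
            base = base + rng.normal(0.0, config.noise_sd, size=base.shape)
        for g, prof in zip(ids, base):
            log_dev[row[g]] = prof

    # background genes: iid noise plus small independent per-(gene,
    # cluster) offsets — they add cluster separation across many
    # incoherent dimensions without creating co-expression structure
    bg_block = rng.normal(
        0.0, config.background_noise_sd, size=(len(background_ids), n_samples)
    )
    bg_offsets = rng.normal(
        0.0, config.background_shift_sd, size=(len(background_ids), config.n_clusters)
    )
    bg_block = bg_block + bg_offsets[:, sample_cluster - 1]
    for g, prof in zip(background_ids, bg_block):
        log_dev[row[g]] = prof

    # baselines: module genes always expressed; a configured fraction of
    # background genes sits below the mean-TPM filter
    lo, hi = config.baseline_range
    dlo, dhi = config.dropout_baseline_range
    baselines = rng.uniform(lo, hi, size=n_genes)
    dropout_mask = rng.random(len(background_ids)) < config.background_dropout
    for g, drop in zip(background_ids, dropout_mask):
        if drop:
            baselines[row[g]] = rng.uniform(dlo, dhi)

    log_expr = log_dev + baselines[:, None]
    tpm = np.exp2(log_expr)
    expr = ExpressionMatrix(
        pd.DataFrame(tpm, index=gene_ids, columns=sample_ids), scale_tag="tpm"
    )

    # metadata: one planted term per (category, cluster); samples carry
    # their cluster's term with probability metadata_affinity
    planted_terms: dict[str, dict[int, str]] = {}
    meta_rows: list[dict[str, str]] = []
    for cat in config.metadata_categories:
        terms = {c: f"{cat}_c{c}" for c in range(1, config.n_clusters + 1)}
        planted_terms[cat] = terms
        for s, c in zip(sample_ids, sample_cluster):
            u = rng.random()
            if u < config.metadata_missing_rate:
                term = "missing"
            elif u < config.metadata_missing_rate + config.metadata_affinity:
                term = terms[c]
            else:
                others = [t for cc, t in terms.items() if cc != c]
                term = others[int(rng.integers(len(others)))] if others else terms[c]
            meta_rows.append({"sample": s, "category": cat, "term": term})
    metadata = pd.DataFrame(meta_rows, columns=["sample", "category", "term"])

    # function bins: one bin per module (padded past the >100-gene cutoff
    # with background genes), decoy bins, and a catch-all root bin
    annot = FunctionAnnotation()
    for g in gene_ids:
        annot.gene_bins[g] = {ROOT_BIN}
    expressed_bg = [g for g, drop in zip(background_ids, dropout_mask) if not drop]
    module_bins: dict[str, str] = {}
    for m in config.modules:
        bin_id = f"BIN.{m.name}"
        module_bins[m.name] = bin_id
        pad_n = min(config.bin_padding, len(expressed_bg))
        pad = rng.choice(len(expressed_bg), size=pad_n, replace=False) if pad_n else []
        members = module_genes[m.name] + [expressed_bg[int(i)] for i in pad]
        for g in members:
            annot.gene_bins[g].add(bin_id)
        annot.bin_names[bin_id] = f"planted bin for module {m.name}"
    for d in range(config.n_decoy_bins):
        bin_id = f"BIN.decoy{d + 1}"
        size = min(config.decoy_bin_size, len(expressed_bg))
        if size == 0:
            break
        picks = rng.choice(len(expressed_bg), size=size, replace=False)
        for i in picks:
            annot.gene_bins[expressed_bg[int(i)]].add(bin_id)
        annot.bin_names[bin_id] = "decoy bin"
    annot.bin_names[ROOT_BIN] = "all genes"

    truth = SyntheticTruth(
        true_cluster={s: int(c) for s, c in zip(sample_ids, sample_cluster)},
        true_module=true_module,
        specificity_label=specificity_label,
        true_edges=true_edges,
        module_home={m.name: m.home_cluster for m in specific_modules},
        planted_terms=planted_terms,
        module_bins=module_bins,
    )
    return SyntheticDataset(expr, metadata, annot, regulators, truth)
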