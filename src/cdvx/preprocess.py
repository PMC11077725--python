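"""Expression matrix container, loading, filtering and scaling.

The matrix is oriented genes x samples throughout. Downstream sample
clustering transposes internally so that samples are the points being
clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "FunctionAnnotation",
    "load_expression",
    "load_annotation",
    "filter_genes",
    "standardize",
    "log_transform",
]


class ExpressionParseError(ValueError):
    """Raised when an expression TSV cannot be parsed into a valid matrix."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample expression values with an explicit scale tag.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by gene id, columns by sample id.
    scale_tag : str
        One of ``"tpm"``, ``"log2"``, ``"zscore"``.
    """

    data: pd.DataFrame
    scale_tag: str = "tpm"

    def __post_init__(self) -> None:
        if self.scale_tag not in ("tpm", "log2", "zscore"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ExpressionParseError(f"duplicate gene ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ExpressionParseError(f"duplicate sample ids: {dups}")
        if self.data.isna().any().any():
            raise ExpressionParseError("matrix contains missing values")
        if self.scale_tag == "tpm" and (self.data.to_numpy() < 0).any():
            raise ExpressionParseError("negative TPM values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = set(genes) - set(self.data.index)
        if missing:
            raise KeyError(f"unknown gene ids: {sorted(missing)[:5]}")
        return replace(self, data=self.data.loc[genes])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        missing = set(samples) - set(self.data.columns)
        if missing:
            raise KeyError(f"unknown sample ids: {sorted(missing)[:5]}")
        return replace(self, data=self.data[samples])

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene")


@dataclass
class FunctionAnnotation:
    """Gene -> functional bin mapping (bins may overlap).

    ``gene_bins`` maps each gene id to the set of bin ids it carries;
    ``bin_names`` optionally maps bin ids to descriptive names.
    """

    gene_bins: dict[str, set[str]] = field(default_factory=dict)
    bin_names: dict[str, str] = field(default_factory=dict)

    def bins_of(self, gene: str) -> set[str]:
        return self.gene_bins.get(gene, set())

    def genes_in(self, bin_id: str) -> set[str]:
        return {g for g, bins in self.gene_bins.items() if bin_id in bins}

    @property
    def bins(self) -> set[str]:
        out: set[str] = set()
        for bins in self.gene_bins.values():
            out |= bins
        return out

    def is_annotated(self, gene: str) -> bool:
        return bool(self.gene_bins.get(gene))

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"gene": g, "bin": b}
            for g, bins in self.gene_bins.items()
            for b in sorted(bins)
        ]
        pd.DataFrame(rows, columns=["gene", "bin"]).to_csv(path, sep="\t", index=False)


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Load a gene x sample TPM matrix from TSV.

    The first row is the sample-id header, the first column holds gene ids.
    Raises :class:`ExpressionParseError` on duplicate ids, non-numeric
    cells or ragged rows, naming the offending line where possible.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ExpressionParseError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        line = list(df.index).index(gene) + 2  # header + 1-based
        raise ExpressionParseError(f"{path}: non-numeric cell at line {line} (gene {gene!r})")
    if numeric.isna().any().any():
        gene = numeric.isna().any(axis=1).idxmax()
        line = list(df.index).index(gene) + 2
        raise ExpressionParseError(f"{path}: missing value at line {line} (gene {gene!r})")
    return ExpressionMatrix(numeric.astype(float), scale_tag="tpm")


def load_annotation(path: str | Path) -> FunctionAnnotation:
    """Load a 2-column (gene, bin) TSV into a :class:`FunctionAnnotation`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 columns (gene, bin)")
    gene_col, bin_col = df.columns[0], df.columns[1]
    annot = FunctionAnnotation()
    for gene, bin_id in zip(df[gene_col], df[bin_col]):
        annot.gene_bins.setdefault(str(gene), set()).add(str(bin_id))
    return annot


def filter_genes(
    expr: ExpressionMatrix,
    annot: FunctionAnnotation,
    min_mean_tpm: float = 2.0,
) -> ExpressionMatrix:
    """Keep genes with mean TPM strictly above ``min_mean_tpm`` and >= 1 bin.

    The inequality is strict: a gene whose mean is exactly ``min_mean_tpm``
    is removed. The sample axis is unchanged.
    """
    if expr.scale_tag != "tpm":
        raise ValueError("filter_genes expects a TPM-scale matrix")
    means = expr.data.mean(axis=1)
    keep = [
        g for g in expr.genes if means[g] > min_mean_tpm and annot.is_annotated(g)
    ]
    if not keep:
        raise ValueError("no genes pass filter")
    return expr.subset_genes(keep)


def standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene row (population sd, ddof=0).

    Zero-variance rows are rejected: the caller must drop them first.
    """
    if expr.n_samples < 2:
        raise ValueError("standardize requires >= 2 samples")
    values = expr.values.astype(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat = np.flatnonzero(sd.ravel() == 0)
    if flat.size:
        names = [expr.genes[i] for i in flat[:10]]
        raise ValueError(f"zero-variance genes cannot be standardized: {names}")
    z = (values - mean) / sd
    return ExpressionMatrix(
        pd.DataFrame(z, index=expr.data.index, columns=expr.data.columns),
        scale_tag="zscore",
    )


def log_transform(expr: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform."""
    if expr.scale_tag != "tpm":
        raise ValueError("log_transform expects a TPM-scale matrix")
    return ExpressionMatrix(np.log2(expr.data + 1.0), scale_tag="log2")
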