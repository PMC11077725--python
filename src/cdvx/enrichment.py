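"""Hypergeometric term enrichment with Benjamini-Hochberg correction.

One upper-tail hypergeometric test per (group, term); BH is applied
within each (group, category) family. Works both for annotating sample
clusters with metadata terms and for annotating gene modules with
function bins.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .preprocess import FunctionAnnotation

__all__ = ["hypergeom_sf", "bh_fdr", "enrich_groups", "metadata_to_term_sets"]

logger = logging.getLogger(__name__)

MISSING_TERM = "missing"


def _log_comb(n: np.ndarray | int, k: np.ndarray | int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), via log-factorials.

    ``N`` population size, ``K`` marked items, ``n`` draws, ``k`` observed
    overlap. The sum runs over the support [max(k, k_min), min(K, n)].
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds: N={N}, K={K}, n={n}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    hi = min(K, n)
    if k > hi:
        return 0.0
    lo = max(k, K + n - N)
    xs = np.arange(lo, hi + 1)
    log_pmf = _log_comb(K, xs) + _log_comb(N - K, n - xs) - _log_comb(N, n)
    total = float(np.exp(log_pmf).sum())
    return min(1.0, total)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def metadata_to_term_sets(
    metadata: pd.DataFrame,
) -> tuple[dict[str, dict[str, set[str]]], dict[str, set[str]]]:
    """Reshape a (sample, category, term) table to category -> term -> samples.

    Returns ``(term_sets, missing)``: the reserved term ``"missing"`` is
    not a testable term; samples carrying only it in a category are
    reported in ``missing`` so they can be excluded from that category's
    population (both K and N).
    """
    out: dict[str, dict[str, set[str]]] = {}
    flagged: dict[str, set[str]] = {}
    for sample, category, term in metadata[["sample", "category", "term"]].itertuples(index=False):
        if term == MISSING_TERM:
            flagged.setdefault(category, set()).add(sample)
            continue
        out.setdefault(category, {}).setdefault(term, set()).add(sample)
    missing: dict[str, set[str]] = {}
    for category, samples in flagged.items():
        labeled: set[str] = set()
        for members in out.get(category, {}).values():
            labeled |= members
        missing[category] = samples - labeled
    return out, missing


def annotation_to_term_sets(annot: FunctionAnnotation) -> dict[str, dict[str, set[str]]]:
    """FunctionAnnotation as a single-category term-set mapping."""
    bins: dict[str, set[str]] = {}
    for gene, gene_bins in annot.gene_bins.items():
        for b in gene_bins:
            bins.setdefault(b, set()).add(gene)
    return {"function": bins}


def enrich_groups(
    groups: Mapping[str, Iterable[str]],
    term_sets: Mapping[str, Mapping[str, Iterable[str]]],
    population: Iterable[str],
    alpha: float = 0.05,
    excluded: Mapping[str, Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of terms in item groups.

    Parameters
    ----------
    groups : mapping group-id -> member items (samples or genes)
    term_sets : mapping category -> term -> items carrying that term
    population : the full item universe being tested
    alpha : significance level on the BH-adjusted values
    excluded : optional category -> items to drop from that category's
        population (e.g. samples whose metadata is missing)

    Returns a table with one row per (group, category, term); ``fdr`` is
    adjusted within each (group, category) family and ``significant`` is
    ``fdr <= alpha``.
    """
    population = set(population)
    excluded = {k: set(v) for k, v in (excluded or {}).items()}
    rows: list[dict] = []
    for group_id, all_members in groups.items():
        if not set(all_members) & population:
            logger.warning("group %s empty within population; skipped", group_id)
            continue
        for category, terms in term_sets.items():
            cat_population = population - excluded.get(category, set())
            members = set(all_members) & cat_population
            N = len(cat_population)
            n = len(members & cat_population)
            family: list[dict] = []
            for term, t_members in terms.items():
                t_members = set(t_members) & cat_population
                K = len(t_members)
                if K == 0:
                    logger.warning(
                        "term %s/%s empty within population; skipped", category, term
                    )
                    continue
                k = len(members & t_members)
                p = hypergeom_sf(k, N, K, n)
                family.append(
                    {
                        "group": group_id,
                        "category": category,
                        "term": term,
                        "overlap": k,
                        "group_size": n,
                        "term_total": K,
                        "population": N,
                        "p_value": p,
                    }
                )
            if not family:
                continue
            fdrs = bh_fdr([r["p_value"] for r in family])
            for r, fdr in zip(family, fdrs):
                r["fdr"] = fdr
                r["significant"] = fdr <= alpha
            rows.extend(family)
    columns = [
        "group",
        "category",
        "term",
        "overlap",
        "group_size",
        "term_total",
        "population",
        "p_value",
        "fdr",
        "significant",
    ]
    return pd.DataFrame(rows, columns=columns)
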