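"""Shared fixtures.

The heavyweight session fixture runs the full analysis chain once on the
default synthetic scenario; acceptance and several module tests share it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from cdvx import clustering, modules, preprocess, specificity, synthetic

SEED = 11


def make_expr(values, genes=None, samples=None, scale_tag="tpm"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return preprocess.ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale_tag=scale_tag
    )


@pytest.fixture(scope="session")
def dataset():
    return synthetic.generate(synthetic.default_config(seed=SEED))


@dataclass
class AnalysisProducts:
    dataset: synthetic.SyntheticDataset
    filtered: preprocess.ExpressionMatrix
    zscored: preprocess.ExpressionMatrix
    logexpr: preprocess.ExpressionMatrix
    assignment: clustering.ClusterAssignment
    cluster_map: dict  # true cluster id -> detected cluster id
    global_partition: modules.ModulePartition
    global_eigengenes: modules.EigengeneMatrix
    cluster_partitions: dict
    cluster_eigengenes: dict
    cdv_tables: dict  # detected cluster id -> CDV table


@pytest.fixture(scope="session")
def products(dataset) -> AnalysisProducts:
    """One full run of the pipeline stages on the default scenario."""
    filt = preprocess.filter_genes(dataset.expression, dataset.annotation)
    z = preprocess.standardize(filt)
    logx = preprocess.log_transform(filt)
    ca = clustering.kmeans_cluster(z, 4, seed=1024)
    cluster_map = {}
    for c in range(1, 5):
        members = [s for s in z.samples if dataset.truth.true_cluster[s] == c]
        cluster_map[c] = Counter(ca.assignment[s] for s in members).most_common(1)[0][0]
    cfg = modules.NetworkConfig()
    g_part, g_eig, _ = modules.build_modules(logx, cfg, "global")
    c_parts, c_eigs, cdvs = {}, {}, {}
    for c in range(1, 5):
        sub = logx.subset_samples(ca.samples_in(c))
        c_parts[c], c_eigs[c], _ = modules.build_modules(sub, cfg, f"cluster-{c}")
        cdvs[c] = specificity.compute_cdv_table(
            logx, ca, c, g_part, g_eig, c_parts[c], c_eigs[c]
        )
    return AnalysisProducts(
        dataset=dataset,
        filtered=filt,
        zscored=z,
        logexpr=logx,
        assignment=ca,
        cluster_map=cluster_map,
        global_partition=g_part,
        global_eigengenes=g_eig,
        cluster_partitions=c_parts,
        cluster_eigengenes=c_eigs,
        cdv_tables=cdvs,
    )
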