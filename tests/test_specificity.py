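"""GMC, CDV, partition similarity and downstream maps.

FMS and AMIS are validated against exhaustive pair-counting and
contingency-table oracles; CDV against its defining identity and the
planted synthetic truth.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from cdvx import specificity as sp
from cdvx.modules import EigengeneMatrix, ModulePartition
from conftest import make_expr


# ---------------------------------------------------------------- gmc


class TestGMC:
    def test_identity(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        assert sp.gmc(v, v) == pytest.approx(1.0)

    def test_negation(self):
        v = np.array([1.0, 3.0, 2.0, 5.0])
        assert sp.gmc(v, -v) == pytest.approx(-1.0)

    def test_hand_computed(self):
        # PCC((1,2,3), (1,2,4)) = 3 / sqrt(2 * 14/3)
        expected = 3 / math.sqrt(2 * 14 / 3)
        assert sp.gmc([1, 2, 3], [1, 2, 4]) == pytest.approx(expected, abs=1e-9)
        assert sp.gmc([1, 2, 3], [1, 2, 4]) == pytest.approx(0.981981, abs=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(sp.ConstantProfileError):
            sp.gmc([1, 1, 1], [1, 2, 3])

    def test_too_short(self):
        with pytest.raises(ValueError):
            sp.gmc([1, 2], [3, 4])


class TestGMCTable:
    def test_eigengene_duplicate_gene(self):
        rng = np.random.default_rng(0)
        e = rng.standard_normal(8)
        expr = make_expr([e], scale_tag="log2")
        part = ModulePartition({"g0": "A"}, "global")
        eig = EigengeneMatrix(
            pd.DataFrame([e / e.std()], index=["A"], columns=expr.samples), "global"
        )
        table = sp.compute_gmc_table(expr, part, eig)
        assert table.iloc[0]["gmc"] == pytest.approx(1.0)

    def test_range_invariant(self, products):
        table = sp.compute_gmc_table(
            products.logexpr, products.global_partition, products.global_eigengenes
        )
        assert table["gmc"].between(-1, 1).all()
        assert (table["n_samples"] >= 3).all()

    def test_mismatched_sample_sets_rejected(self, products):
        with pytest.raises(ValueError):
            sp.compute_gmc_table(
                products.logexpr,
                products.global_partition,
                products.cluster_eigengenes[1],
            )

    def test_cluster_median_gmc_at_least_global(self, products):
        # direction check: co-expression fits cluster samples better
        # when modules are built from those samples alone
        for c, table in products.cdv_tables.items():
            assert (
                table["gmc_cluster"].median()
                >= table["gmc_global_restricted"].median()
            )


# ---------------------------------------------------------------- cdv


class TestCDV:
    def test_constructed_maximum(self):
        rng = np.random.default_rng(1)
        e = rng.standard_normal(50)
        cdv = sp.gmc(e, e) - sp.gmc(e, -e)
        assert cdv == pytest.approx(2.0)

    def test_gene_matching_both_eigengenes_zero(self):
        rng = np.random.default_rng(2)
        e = rng.standard_normal(30)
        assert sp.gmc(e, e) - sp.gmc(e, e.copy()) == pytest.approx(0.0)

    def test_identity_and_range(self, products):
        for table in products.cdv_tables.values():
            eligible = table[table["eligible"]]
            np.testing.assert_allclose(
                eligible["cdv"],
                eligible["gmc_cluster"] - eligible["gmc_global_restricted"],
                atol=1e-12,
            )
            assert eligible["cdv"].between(-2, 2).all()
            assert table.loc[~table["eligible"], "cdv"].isna().all()

    def test_eligibility_gate(self, products):
        for table in products.cdv_tables.values():
            el = table[table["eligible"]]
            assert (el["gmc_cluster"] >= 0.6).all()
            assert (el["gmc_global_full"] >= 0.6).all()

    def test_specific_genes_score_higher(self, products):
        truth = products.dataset.truth
        spec_rows, cons_rows = [], []
        cons_genes = {
            g for g, l in truth.specificity_label.items() if l == "conserved"
        }
        for module, home in truth.module_home.items():
            detected = products.cluster_map[home]
            table = products.cdv_tables[detected]
            genes = {g for g, m in truth.true_module.items() if m == module}
            el = table[table["eligible"] & table["gene"].isin(genes)]
            spec_rows += list(el["cdv"])
        for table in products.cdv_tables.values():
            el = table[table["eligible"] & table["gene"].isin(cons_genes)]
            cons_rows += list(el["cdv"])
        labels = [1] * len(spec_rows) + [0] * len(cons_rows)
        values = spec_rows + cons_rows
        assert roc_auc_score(labels, values) >= 0.9
        assert np.mean(spec_rows) - np.mean(cons_rows) >= 0.3


# ------------------------------------------------- fms / amis oracles


def set_partitions(items, max_blocks=None):
    """All set partitions via restricted-growth strings."""
    n = len(items)
    if n == 0:
        return
    codes = [0] * n

    def rec(i, m):
        if i == n:
            if max_blocks is None or m + 1 <= max_blocks:
                yield list(codes)
            return
        for c in range(min(m + 1, (max_blocks or n) - 1) + 1):
            codes[i] = c
            yield from rec(i + 1, max(m, c))

    yield from rec(1, 0)


def fms_oracle(a, b):
    n = len(a)
    tp = fp = fn = 0
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        tp += sa and sb
        fp += sa and not sb
        fn += sb and not sa
    if tp + fp == 0 or tp + fn == 0:
        return 0.0
    return tp / math.sqrt((tp + fp) * (tp + fn))


def ami_oracle(a, b):
    """Adjusted MI with the exact hypergeometric-model E[MI]."""
    n = len(a)
    la, lb = sorted(set(a)), sorted(set(b))
    cont = np.zeros((len(la), len(lb)))
    for x, y in zip(a, b):
        cont[la.index(x), lb.index(y)] += 1
    ai, bj = cont.sum(1), cont.sum(0)
    mi = 0.0
    for i in range(len(la)):
        for j in range(len(lb)):
            nij = cont[i, j]
            if nij > 0:
                mi += (nij / n) * math.log(n * nij / (ai[i] * bj[j]))
    emi = 0.0
    for i in range(len(la)):
        for j in range(len(lb)):
            lo = int(max(ai[i] + bj[j] - n, 1))
            hi = int(min(ai[i], bj[j]))
            for nij in range(lo, hi + 1):
                term = (nij / n) * math.log(n * nij / (ai[i] * bj[j]))
                prob = (
                    math.comb(int(bj[j]), nij)
                    * math.comb(n - int(bj[j]), int(ai[i]) - nij)
                    / math.comb(n, int(ai[i]))
                )
                emi += prob * term
    ha = -sum((x / n) * math.log(x / n) for x in ai if x > 0)
    hb = -sum((x / n) * math.log(x / n) for x in bj if x > 0)
    denom = (ha + hb) / 2 - emi
    if denom == 0:
        return 1.0
    return (mi - emi) / denom


def as_partition(labels, prefix="p"):
    return ModulePartition(
        {f"g{i}": str(l) for i, l in enumerate(labels)}, prefix
    )


class TestFMS:
    def test_identical(self):
        p = as_partition([1, 1, 2, 2])
        assert sp.fms(p, as_partition([1, 1, 2, 2], "q")) == pytest.approx(1.0)

    def test_orthogonal(self):
        p = as_partition([1, 1, 2, 2])
        q = as_partition([1, 2, 1, 2], "q")
        assert sp.fms(p, q) == pytest.approx(0.0)

    def test_hand_computed(self):
        # TP=1, pairs(p)=3, pairs(q)=2 -> 1/sqrt(6)
        p = as_partition([1, 1, 1, 2])
        q = as_partition([1, 1, 2, 2], "q")
        assert sp.fms(p, q) == pytest.approx(1 / math.sqrt(6), abs=1e-12)

    def test_unassigned_dropped(self):
        p = ModulePartition({"g0": "A", "g1": "A", "g2": "unassigned", "g3": "B"})
        q = ModulePartition({"g0": "X", "g1": "X", "g2": "X", "g3": "Y"}, "q")
        assert sp.fms(p, q) == pytest.approx(1.0)

    def test_too_few_genes(self):
        p = ModulePartition({"g0": "A"})
        with pytest.raises(ValueError):
            sp.fms(p, ModulePartition({"g0": "B"}, "q"))


class TestAMIS:
    def test_identical(self):
        p = as_partition([1, 2, 2, 3])
        assert sp.amis(p, as_partition([1, 2, 2, 3], "q")) == pytest.approx(1.0)

    def test_label_permutation_invariance(self):
        p = as_partition([1, 1, 2, 2, 3])
        q = as_partition([3, 3, 1, 1, 2], "q")
        assert sp.amis(p, q) == pytest.approx(1.0)

    def test_both_single_cluster(self):
        p = as_partition([1, 1, 1])
        assert sp.amis(p, as_partition([2, 2, 2], "q")) == pytest.approx(1.0)

    def test_2x2_contingency_matches_exact_oracle(self):
        a, b = [1, 1, 1, 2], [1, 1, 2, 2]
        got = sp.amis(as_partition(a), as_partition(b, "q"))
        assert got == pytest.approx(ami_oracle(a, b), abs=1e-10)


class TestOracleEquivalence:
    def test_exhaustive_small_partitions(self):
        # all pairs of partitions of 5 items into <= 3 blocks
        parts = list(set_partitions(range(5), max_blocks=3))
        for a in parts:
            for b in parts:
                pa, pb = as_partition(a), as_partition(b, "q")
                assert sp.fms(pa, pb) == pytest.approx(fms_oracle(a, b), abs=1e-10)
                assert sp.amis(pa, pb) == pytest.approx(ami_oracle(a, b), abs=1e-8)

    def test_sampled_partitions_of_eight(self):
        rng = np.random.default_rng(3)
        parts = list(set_partitions(range(8), max_blocks=3))
        idx = rng.choice(len(parts), size=(150, 2))
        for i, j in idx:
            a, b = parts[i], parts[j]
            pa, pb = as_partition(a), as_partition(b, "q")
            assert sp.fms(pa, pb) == pytest.approx(fms_oracle(a, b), abs=1e-10)
            assert sp.amis(pa, pb) == pytest.approx(ami_oracle(a, b), abs=1e-8)


# ---------------------------------------------------------------- sweep


class TestThresholdSweep:
    @pytest.fixture
    def focus(self, products):
        truth = products.dataset.truth
        c = products.cluster_map[truth.module_home["SPEC1"]]
        return c, products.cdv_tables[c]

    def test_counts_monotone(self, products, focus):
        c, table = focus
        curve = sp.cdv_threshold_sweep(
            table, products.global_partition, products.cluster_partitions[c]
        )
        counts = curve["n_genes"].to_numpy()
        assert (np.diff(counts) >= 0).all()

    def test_saturation_equals_unrestricted(self, products, focus):
        c, table = focus
        curve = sp.cdv_threshold_sweep(
            table,
            products.global_partition,
            products.cluster_partitions[c],
            thresholds=[2.5],
        )
        eligible = table.loc[table["eligible"], "gene"].tolist()
        expected = sp.fms(
            products.global_partition, products.cluster_partitions[c], eligible
        )
        assert curve.iloc[0]["fms"] == pytest.approx(expected, abs=1e-12)

    def test_similarity_decreases_with_threshold(self, products, focus):
        c, table = focus
        curve = sp.cdv_threshold_sweep(
            table, products.global_partition, products.cluster_partitions[c]
        )
        by_t = curve.set_index("threshold")
        assert by_t.loc[0.10, "fms"] >= by_t.loc[0.90, "fms"]


# ------------------------------------------------------ function maps


class TestFunctionCDVMatrix:
    def test_bin_at_exact_cutoff_excluded(self, products):
        table = products.cdv_tables[1]
        population = products.filtered.genes
        from cdvx.preprocess import FunctionAnnotation

        annot = FunctionAnnotation(
            gene_bins={g: {"exact100"} for g in population[:100]}
        )
        out = sp.function_cdv_matrix(
            table, annot, {"grp": population[:50]}, population, min_bin_size=100
        )
        assert out.empty

    def test_empty_flag_when_no_cdv_members(self):
        from cdvx.preprocess import FunctionAnnotation

        genes = [f"g{i}" for i in range(30)]
        cdv = pd.DataFrame(
            {
                "gene": genes,
                "cluster": 1,
                "cdv": [np.nan] * 30,
                "eligible": [False] * 30,
            }
        )
        annot = FunctionAnnotation(gene_bins={g: {"bin1"} for g in genes})
        out = sp.function_cdv_matrix(
            cdv, annot, {"grp": genes[:10]}, genes, min_bin_size=5
        )
        row = out.iloc[0]
        assert row["empty"]
        assert np.isnan(row["mean_cdv"])

    def test_planted_bin_significant_and_highest(self, products):
        truth = products.dataset.truth
        c = products.cluster_map[truth.module_home["SPEC1"]]
        table = products.cdv_tables[c]
        parts = products.cluster_partitions[c]
        groups = {m: parts.members(m) for m in parts.modules}
        out = sp.function_cdv_matrix(
            table, products.dataset.annotation, groups, products.filtered.genes
        )
        spec_genes = {g for g, m in truth.true_module.items() if m == "SPEC1"}
        host = pd.Series(
            [parts.labels[g] for g in spec_genes]
        ).mode()[0]
        bin_id = truth.module_bins["SPEC1"]
        cell = out[(out["group"] == host) & (out["bin"] == bin_id)].iloc[0]
        assert cell["significant"]
        host_rows = out[(out["group"] == host) & ~out["empty"]]
        assert cell["mean_cdv"] == host_rows["mean_cdv"].max()
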