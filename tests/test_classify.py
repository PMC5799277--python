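"""Profile comparison, cluster assignment, enrichment bookkeeping and BH."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import swingrna as sw
from swingrna.errors import InputError
from swingrna.structures import StructureProfile


def profile(label, vec, cluster="none", n=100):
    return StructureProfile(label, n, *vec, cluster=cluster)


def step_up_bh(pvalues):
    """Hand-written BH step-up closed form (independent oracle)."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestCompareProfiles:
    def test_identity_gives_r_one(self, table1_profiles):
        c1 = table1_profiles[0]
        res = sw.compare_profiles(c1, c1)
        assert res.r == pytest.approx(1.0)
        assert res.significant

    def test_circ1_vs_circ2(self, table1_profiles):
        c1, c2 = table1_profiles[0], table1_profiles[1]
        assert (c1.label, c2.label) == ("Circ1", "Circ2")
        res = sw.compare_profiles(c1, c2)
        assert res.r == pytest.approx(0.959, abs=5e-4)
        assert res.significant  # 0.959 >= 0.95 decision threshold

    def test_p_matches_df2_t_oracle(self, table1_profiles):
        # the reported p must equal the upper-tail t-transform at df=2,
        # recomputed here directly from the t distribution
        res = sw.compare_profiles(table1_profiles[0], table1_profiles[1])
        t = res.r * math.sqrt(2 / (1 - res.r ** 2))
        assert res.p_one_tailed == pytest.approx(float(sps.t.sf(t, 2)))

    def test_r_095_corresponds_to_p_0025(self):
        # the r=0.95 decision threshold sits at one-tailed p=0.025 for df=2
        t = 0.95 * math.sqrt(2 / (1 - 0.95 ** 2))
        assert float(sps.t.sf(t, 2)) == pytest.approx(0.025, abs=1e-6)

    def test_zero_variance_flagged_not_zero(self):
        res = sw.compare_profiles(profile("q", (50, 50, 50, 50)),
                                  profile("r", (1, 2, 3, 4), "B1"))
        assert not res.comparable
        assert math.isnan(res.r)
        assert "variance" in res.reason

    def test_affine_invariance(self, rng):
        for _ in range(20):
            v = rng.uniform(0, 100, 4)
            w = rng.uniform(0, 100, 4)
            a, b = rng.uniform(0.1, 2), rng.uniform(0, 10)
            r1 = sw.compare_profiles(profile("q", v), profile("r", w, "B1")).r
            r2 = sw.compare_profiles(
                profile("q", a * v / 3 + b), profile("r", w, "B1")
            ).r
            assert r1 == pytest.approx(r2, abs=1e-9)


class TestClassifyStructure:
    def test_self_reference_wins(self, table1_profiles):
        q = table1_profiles[0]
        a = sw.classify_structure(q, table1_profiles)
        assert a.best_reference_label == "Circ1"
        assert a.best_r == pytest.approx(1.0)
        assert a.assigned_cluster == "B1"

    def test_circ1_between_b1_and_d1(self, table1_profiles):
        c1, c2, c8 = (table1_profiles[i] for i in (0, 1, 7))
        assert c8.label == "Circ8" and c8.cluster == "D1"
        a = sw.classify_structure(c1, [c2, c8])
        assert a.assigned_cluster == "B1"

    def test_reference_order_invariance(self, table1_profiles):
        q = table1_profiles[5]
        refs = table1_profiles[1:20]
        a1 = sw.classify_structure(q, refs)
        a2 = sw.classify_structure(q, refs[::-1])
        assert a1.assigned_cluster == a2.assigned_cluster
        assert a1.best_r == a2.best_r

    def test_counts_sum_to_references(self, table1_profiles):
        a = sw.classify_structure(table1_profiles[0], table1_profiles)
        total = sum(d["comparisons"] for d in a.per_cluster.values())
        assert total == len(table1_profiles)

    def test_unlabeled_reference_rejected(self, table1_profiles):
        bad = profile("r", (1, 2, 3, 4))  # cluster "none"
        with pytest.raises(InputError):
            sw.classify_structure(table1_profiles[0], [bad])

    def test_all_non_comparable_unassigned(self):
        q = profile("q", (7, 7, 7, 7))
        a = sw.classify_structure(q, [profile("r", (1, 2, 3, 4), "B1")])
        assert not a.assigned
        assert a.reason


class TestClusterEnrichment:
    def test_comparison_bookkeeping(self, rng):
        queries = [profile(f"q{i}", rng.uniform(0, 100, 4))
                   for i in range(24)]
        refs = (
            [profile(f"b{i}", rng.uniform(0, 100, 4), "B1") for i in range(6)]
            + [profile(f"d2_{i}", rng.uniform(0, 100, 4), "D2")
               for i in range(17)]
            + [profile(f"d1_{i}", rng.uniform(0, 100, 4), "D1")
               for i in range(13)]
        )
        res = sw.cluster_enrichment(queries, refs)
        t = res.table.set_index("cluster")
        assert t.loc["B1", "comparisons"] == 144
        assert t.loc["D2", "comparisons"] == 408
        assert t.loc["D1", "comparisons"] == 312
        assert t["comparisons"].sum() == 24 * 36

    def test_empty_queries_all_zero(self, table1_profiles):
        res = sw.cluster_enrichment([], table1_profiles)
        assert (res.table["comparisons"] == 0).all()
        assert (res.table["fraction"] == 0.0).all()

    def test_clones_fully_significant(self, table1_profiles):
        d1 = [p for p in table1_profiles if p.cluster == "D1"]
        clones = [profile(f"clone{i}", p.vector()) for i, p in enumerate(d1)]
        res = sw.cluster_enrichment(clones, d1, alpha=0.05)
        row = res.table.set_index("cluster").loc["D1"]
        assert row["fraction"] == pytest.approx(1.0) or row["significant"] >= len(d1)


class TestBH:
    def test_single_value_unchanged(self):
        assert sw.bh_adjust([0.05]) == pytest.approx([0.05])

    def test_hand_worked_step_up(self):
        assert sw.bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            sw.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=30))
    def test_matches_closed_form(self, pvals):
        assert np.allclose(sw.bh_adjust(pvals), step_up_bh(pvals))

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=20))
    def test_adjusted_at_least_raw_and_order_preserving(self, pvals):
        adj = sw.bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(pvals)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestClassifyAll:
    def test_adjusted_ge_raw(self, table1_profiles):
        qs = table1_profiles[:5]
        _, matrix = sw.classify_all(qs, table1_profiles[:10])
        ok = matrix["comparable"]
        assert (matrix.loc[ok, "p_adjusted"]
                >= matrix.loc[ok, "p_one_tailed"] - 1e-12).all()

    def test_per_query_family(self, table1_profiles):
        qs = table1_profiles[:3]
        _, matrix = sw.classify_all(qs, table1_profiles[:10], bh="per-query")
        assert matrix["p_adjusted"].notna().all()
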