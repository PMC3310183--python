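"""Hypergeometric tails, gene-set enrichment, coverage, and hub depletion."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.enrichment import (
    GeneSet,
    coverage,
    enrich_gene_sets,
    hub_depletion,
    hypergeom_tail,
    known_targets_by_atc,
)
from netpharm.network import top_fraction_nodes
from netpharm.space import DrugRecord, DrugSpace
from oracles import exact_hypergeom_tails


class TestHypergeomTail:
    def test_upper_at_zero_is_one(self):
        assert hypergeom_tail(10, 4, 5, 0, "upper") == 1.0

    def test_worked_upper(self):
        # (C(4,3)C(6,2) + C(4,4)C(6,1)) / C(10,5) = 66/252
        assert hypergeom_tail(10, 4, 5, 3, "upper") == pytest.approx(66 / 252, rel=1e-12)

    def test_worked_lower(self):
        # C(6,5) / C(10,5) = 6/252
        assert hypergeom_tail(10, 4, 5, 0, "lower") == pytest.approx(6 / 252, rel=1e-12)

    def test_parameter_bounds_enforced(self):
        with pytest.raises(ValueError, match="K <= N"):
            hypergeom_tail(10, 11, 5, 0)
        with pytest.raises(ValueError, match="n <= N"):
            hypergeom_tail(10, 4, 11, 0)
        with pytest.raises(ValueError, match="min"):
            hypergeom_tail(10, 4, 5, 5)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 4, 5, 2, tail="middle")

    @settings(derandomize=True, max_examples=100)
    @given(data=st.data())
    def test_matches_exact_enumeration(self, data):
        N = data.draw(st.integers(2, 35))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        upper, lower = exact_hypergeom_tails(N, K, n)
        for k in range(min(K, n) + 1):
            assert hypergeom_tail(N, K, n, k, "upper") == pytest.approx(upper[k], rel=1e-10)
            got_lo = hypergeom_tail(N, K, n, k, "lower")
            if lower[k] == 0.0:  # below the support; reported as tiny, not 0
                assert got_lo <= 1e-300
            else:
                assert got_lo == pytest.approx(lower[k], rel=1e-10)

    @settings(derandomize=True, max_examples=100)
    @given(data=st.data())
    def test_upper_tail_monotone_in_k(self, data):
        N = data.draw(st.integers(3, 30))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        ks = range(min(K, n) + 1)
        ps = [hypergeom_tail(N, K, n, k, "upper") for k in ks]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


class TestCoverage:
    def test_full_coverage(self):
        assert coverage(7, 7) == 1.0

    @pytest.mark.parametrize("k, K, printed", [(5, 17, "0.2941"), (13, 41, "0.3171")])
    def test_four_decimal_convention(self, k, K, printed):
        assert f"{coverage(k, K):.4f}" == printed

    def test_bounds(self):
        with pytest.raises(ValueError):
            coverage(1, 0)
        with pytest.raises(ValueError):
            coverage(5, 4)


class TestEnrichGeneSets:
    universe = frozenset(f"G{i}" for i in range(50))

    def _collection(self):
        return [
            GeneSet("S1", "set one", frozenset({"G1", "G2", "G3", "G4"})),
            GeneSet("S2", "set two", frozenset({"G10", "G11"})),
        ]

    def test_full_membership_hit(self):
        res = enrich_gene_sets({"G1", "G2", "G3", "G4"}, self._collection(), self.universe)
        top = res[0]
        assert top.set_id == "S1"
        assert top.overlap_k == top.set_K
        assert top.coverage == 1.0
        assert top.p_value < 0.05

    def test_disjoint_candidates_p_one(self):
        res = enrich_gene_sets({"G40", "G41"}, self._collection(), self.universe)
        by_id = {r.set_id: r for r in res}
        assert by_id["S1"].overlap_k == 0
        assert by_id["S1"].p_value == 1.0

    def test_sorted_by_increasing_p(self):
        res = enrich_gene_sets({"G1", "G2", "G10"}, self._collection(), self.universe)
        ps = [r.p_value for r in res]
        assert ps == sorted(ps)

    def test_collection_order_irrelevant(self):
        cand = {"G1", "G10", "G11"}
        fwd = enrich_gene_sets(cand, self._collection(), self.universe)
        rev = enrich_gene_sets(cand, self._collection()[::-1], self.universe)
        assert [(r.set_id, r.p_value) for r in fwd] == [(r.set_id, r.p_value) for r in rev]

    def test_out_of_universe_candidates_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="outside the universe"):
            res = enrich_gene_sets({"G1", "ALIEN"}, self._collection(), self.universe)
        assert all(r.sample_n == 1 for r in res)

    def test_rows_internally_consistent(self):
        res = enrich_gene_sets({"G1", "G2", "G10"}, self._collection(), self.universe)
        for r in res:
            assert r.coverage == pytest.approx(r.overlap_k / r.set_K, abs=0)
            assert r.p_value == pytest.approx(
                hypergeom_tail(r.universe_N, r.set_K, r.sample_n, r.overlap_k, r.tail),
                rel=1e-12,
            )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich_gene_sets({"G1"}, self._collection(), frozenset())


class TestKnownTargetsByAtc:
    space = DrugSpace(
        [
            DrugRecord("D1", frozenset({1}), frozenset({"A", "B"}), ("C01",)),
            DrugRecord("D2", frozenset({2}), frozenset({"C"}), ("c07AB",)),
            DrugRecord("D3", frozenset({3}), frozenset({"D"}), ("N02",)),
            DrugRecord("D4", frozenset({4}), frozenset({"E"})),
        ]
    )

    def test_prefix_union_case_insensitive(self):
        assert known_targets_by_atc(self.space, "C") == {"A", "B", "C"}
        assert known_targets_by_atc(self.space, "c01") == {"A", "B"}

    def test_no_match_empty(self):
        assert known_targets_by_atc(self.space, "J") == frozenset()

    def test_empty_prefix_rejected(self):
        with pytest.raises(ValueError):
            known_targets_by_atc(self.space, "")


class TestHubDepletion:
    def _net(self):
        return nx.barabasi_albert_graph(120, 3, seed=1)

    def test_candidates_containing_all_hubs(self):
        net = self._net()
        hubs = top_fraction_nodes(net, "degree", 0.05)
        res = hub_depletion(hubs, net, "degree", 0.05)
        assert res.overlap_k == min(res.set_K, res.sample_n)
        assert res.p_value > 0.5  # maximal overlap: no depletion signal

    def test_non_hub_candidates_match_exact_enumeration(self):
        net = self._net()
        hubs = top_fraction_nodes(net, "degree", 0.05)
        non_hubs = sorted(set(net.nodes) - hubs)[:30]
        res = hub_depletion(non_hubs, net, "degree", 0.05)
        assert res.overlap_k == 0
        _, lower = exact_hypergeom_tails(res.universe_N, res.set_K, res.sample_n)
        assert res.p_value == pytest.approx(lower[0], rel=1e-10)

    def test_out_of_network_candidates_dropped(self):
        net = self._net()
        with pytest.warns(UserWarning, match="not in the network"):
            res = hub_depletion([0, 1, "ALIEN"], net, "degree", 0.05)
        assert res.sample_n == 2

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            hub_depletion(["ALIEN"], self._net(), "degree", 0.05)


class TestComplementarity:
    @settings(derandomize=True, max_examples=150)
    @given(data=st.data())
    def test_upper_plus_lower_below_is_one(self, data):
        N = data.draw(st.integers(2, 60))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        kmax = min(K, n)
        if kmax == 0:
            return
        k = data.draw(st.integers(1, kmax))
        total = hypergeom_tail(N, K, n, k, "upper") + hypergeom_tail(N, K, n, k - 1, "lower")
        assert total == pytest.approx(1.0, rel=1e-10)
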