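"""Concordance scoring, genome-wide ranking, top-k selection and pooling."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from netpharm.prediction import (
    PooledTargets,
    concordance_score,
    mean_compounds_per_target,
    pool_targets,
    rank_targets,
    recovery_at_top,
    select_top_percent,
)
from netpharm.space import DrugRecord, DrugSpace


class TestConcordanceScore:
    def test_perfect_linear_relation(self):
        s = [0.1, 0.5, 0.9, 0.3]
        f = [2 * x + 1 for x in s]
        assert concordance_score(s, f) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        s = [0.1, 0.5, 0.9]
        assert concordance_score(s, [-x for x in s]) == pytest.approx(-1.0)

    def test_worked_triple_matches_independent_oracle(self):
        s, f = (0.1, 0.4, 0.9), (0.0, 1.0, 1.5)
        # exact value 525 / sqrt(294 * 1050) from integer covariance sums
        exact = 525 / math.sqrt(294 * 1050)
        assert concordance_score(s, f) == pytest.approx(exact, abs=1e-12)
        assert concordance_score(s, f) == pytest.approx(stats.pearsonr(s, f)[0], abs=1e-12)

    def test_zero_variance_is_degenerate_flag(self):
        assert math.isnan(concordance_score([1, 1, 1], [0, 1, 2]))
        assert math.isnan(concordance_score([0, 1, 2], [3, 3, 3]))

    def test_spearman_flavor(self):
        s = [0.1, 0.2, 0.9]
        f = [1.0, 2.0, 2.1]  # monotone but nonlinear
        assert concordance_score(s, f, method="spearman") == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            concordance_score([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            concordance_score([1, 2], [1, 2])
        with pytest.raises(ValueError):
            concordance_score([1, 2, 3], [1, 2, 3], method="kendall")


@pytest.fixture
def toy_world():
    """Drug D3's sole target G is far from everything else."""
    g = nx.Graph([("A", "B"), ("B", "C"), ("C", "A"), ("C", "D"), ("D", "E"), ("E", "G")])
    space = DrugSpace(
        [
            DrugRecord("D1", frozenset({1, 2}), frozenset({"A"})),
            DrugRecord("D2", frozenset({2, 3}), frozenset({"B"})),
            DrugRecord("D3", frozenset({10, 11}), frozenset({"G"})),
            DrugRecord("D4", frozenset({4}), frozenset({"C"})),
        ]
    )
    return g, space


class TestRankTargets:
    def test_planted_target_ranks_first(self, toy_world):
        g, space = toy_world
        r = rank_targets(frozenset({10, 11}), space, g, query_id="q")
        assert r.genes[0] == "G"
        assert not r.degenerate

    def test_output_is_permutation_of_nodes(self, toy_world):
        g, space = toy_world
        r = rank_targets(frozenset({1, 2}), space, g)
        assert sorted(r.genes) == sorted(g.nodes)
        assert [rank for _, _, rank in r.entries()] == list(range(1, len(g) + 1))

    def test_tied_scores_ordered_by_gene_id(self):
        # two leaves symmetric around the same hub get identical profiles
        g = nx.star_graph(["hub", "x", "y", "z"])
        space = DrugSpace(
            [
                DrugRecord("D1", frozenset({1}), frozenset({"hub"})),
                DrugRecord("D2", frozenset({1, 2}), frozenset({"x", "y", "z"})),
                DrugRecord("D3", frozenset({3}), frozenset({"hub", "x"})),
            ]
        )
        r = rank_targets(frozenset({1}), space, g)
        iy, iz = r.genes.index("y"), r.genes.index("z")
        assert r.scores[iy] == r.scores[iz]
        assert iy < iz

    def test_node_input_order_irrelevant(self, toy_world):
        g, space = toy_world
        g2 = nx.Graph()
        for a, b in reversed(list(g.edges)):
            g2.add_edge(a, b)
        r1 = rank_targets(frozenset({2, 3}), space, g)
        r2 = rank_targets(frozenset({2, 3}), space, g2)
        assert r1.genes == r2.genes
        assert r1.scores == r2.scores

    def test_disjoint_query_flagged_degenerate(self, toy_world):
        g, space = toy_world
        with pytest.warns(UserWarning, match="degenerate"):
            r = rank_targets(frozenset({999}), space, g)
        assert r.degenerate
        assert all(math.isnan(s) for s in r.scores)

    def test_small_space_rejected(self, toy_world):
        g, space = toy_world
        with pytest.raises(ValueError):
            rank_targets(frozenset({1}), space[:2], g)


def _ranking(genes, scores, query_id="q", degenerate=False):
    from netpharm.prediction import RankedTargets

    return RankedTargets(query_id=query_id, genes=tuple(genes), scores=tuple(scores), degenerate=degenerate)


class TestSelectTopPercent:
    def test_floor_rule_at_genome_scale(self):
        n = 11654
        genes = [f"G{i:05d}" for i in range(n)]
        scores = list(np.linspace(1, -1, n))
        assert len(select_top_percent(_ranking(genes, scores), 0.001)) == 11

    def test_floor_rule_small(self):
        genes = [f"G{i:03d}" for i in range(200)]
        r = _ranking(genes, list(np.linspace(1, 0, 200)))
        assert len(select_top_percent(r, 0.01)) == 2
        assert select_top_percent(r, 0.01) == {"G000", "G001"}

    def test_minimum_one(self):
        r = _ranking(["A", "B", "C"], [0.3, 0.2, 0.1])
        assert select_top_percent(r, 1e-6) == {"A"}

    def test_monotone_in_fraction(self):
        genes = [f"G{i:03d}" for i in range(100)]
        r = _ranking(genes, list(np.linspace(1, 0, 100)))
        prev = set()
        for frac in (0.01, 0.05, 0.2, 0.5, 0.9):
            cur = select_top_percent(r, frac)
            assert prev <= cur
            prev = cur

    def test_degenerate_entries_excluded(self):
        r = _ranking(["A", "B", "C", "D"], [0.5, 0.4, float("nan"), float("nan")])
        assert select_top_percent(r, 0.9) == {"A", "B"}

    def test_fully_degenerate_warns_empty(self):
        r = _ranking(["A", "B"], [float("nan")] * 2, degenerate=True)
        with pytest.warns(UserWarning):
            assert select_top_percent(r, 0.5) == frozenset()


class TestPooling:
    def test_identical_rankings_counts_two(self):
        genes = [f"G{i}" for i in range(10)]
        scores = list(np.linspace(1, 0, 10))
        p = pool_targets([_ranking(genes, scores, "a"), _ranking(genes, scores, "b")], 0.2)
        assert p.genes == {"G0", "G1"}
        assert all(c == 2 for c in p.counts.values())
        assert mean_compounds_per_target(p) == 2.0

    def test_disjoint_top_sets_sum(self):
        a = _ranking(["A", "B", "C", "D"], [0.9, 0.8, 0.2, 0.1], "a")
        b = _ranking(["C", "D", "A", "B"], [0.9, 0.8, 0.2, 0.1], "b")
        p = pool_targets([a, b], 0.5)
        assert p.genes == {"A", "B", "C", "D"}
        assert all(c == 1 for c in p.counts.values())

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(13)
        genes = [f"G{i:02d}" for i in range(40)]
        rankings = []
        for q in range(5):
            scores = rng.random(40)
            order = np.argsort(-scores)
            rankings.append(
                _ranking([genes[i] for i in order], [float(scores[i]) for i in order], f"q{q}")
            )
        frac = 0.2
        p = pool_targets(rankings, frac)
        tops = [select_top_percent(r, frac) for r in rankings]
        for g in p.genes:
            assert p.counts[g] == sum(g in t for t in tops)
        assert sum(p.counts.values()) / len(p.counts) == pytest.approx(
            mean_compounds_per_target(p)
        )

    def test_all_degenerate_rejected(self):
        r = _ranking(["A", "B"], [float("nan")] * 2, degenerate=True)
        with pytest.raises(ValueError):
            pool_targets([r], 0.5)

    def test_mean_of_mixed_counts(self):
        p = PooledTargets(fraction=0.1, counts={"A": 1, "B": 1, "C": 4})
        assert mean_compounds_per_target(p) == 2.0

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            mean_compounds_per_target(PooledTargets(fraction=0.1, counts={}))


class TestRecoveryAtTop:
    def test_extremes(self):
        genes = [f"G{i}" for i in range(10)]
        r = _ranking(genes, list(np.linspace(1, 0, 10)))
        assert recovery_at_top(r, {"G0", "G1"}, 0.2) == 1.0
        assert recovery_at_top(r, {"G8", "G9"}, 0.2) == 0.0
        assert recovery_at_top(r, {"G0", "G9"}, 0.2) == 0.5

    def test_empty_or_foreign_truth_rejected(self):
        r = _ranking(["A", "B", "C"], [0.3, 0.2, 0.1])
        with pytest.raises(ValueError):
            recovery_at_top(r, set(), 0.5)
        with pytest.raises(ValueError):
            recovery_at_top(r, {"Z"}, 0.5)
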