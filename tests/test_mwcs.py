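import networkx as nx
import numpy as np
import pytest

from ppimodules import NodeScores, mwcs
from ppimodules.io import GeneSetCollection
from ppimodules.mwcs import MwcsSizeError, brute_force_optimum
from tests.conftest import random_scored_graph


def make_scores(d):
    return NodeScores(tau=0.05, alpha_used=0.5, scores=d)


class TestAlignInputs:
    def test_off_network_genes_excluded(self):
        net = nx.Graph([("A", "B")])
        aligned, sc = mwcs.align_inputs(net, make_scores({"A": 1.0, "B": -1.0, "C": 2.0}))
        assert set(aligned.nodes) == {"A", "B"}
        assert set(sc.scores) == {"A", "B"}

    def test_drop_restricts_to_scored(self):
        net = nx.Graph([("A", "B"), ("B", "C")])
        aligned, _ = mwcs.align_inputs(net, make_scores({"A": 1.0, "B": -1.0}), "drop")
        assert set(aligned.nodes) == {"A", "B"}

    def test_impute_zero_keeps_unscored_with_warning(self):
        net = nx.Graph([("A", "B"), ("B", "C")])
        with pytest.warns(UserWarning, match="imputed"):
            aligned, sc = mwcs.align_inputs(
                net, make_scores({"A": 1.0, "B": -1.0}), "impute_zero"
            )
        assert set(aligned.nodes) == {"A", "B", "C"}
        assert sc.scores["C"] == 0.0

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            mwcs.align_inputs(nx.Graph([("A", "B")]), make_scores({"X": 1.0}))


class TestSolveExact:
    def test_path_optimum_spans_negative_interior(self, path_graph_scores):
        result = mwcs.solve_exact(*path_graph_scores)
        assert result.members == frozenset({"B", "C", "D"})
        assert result.total_score == pytest.approx(2.5)

    def test_star_tie_broken_lexicographically(self):
        g = nx.star_graph(3)
        g = nx.relabel_nodes(g, {0: "E", 1: "F", 2: "G", 3: "H"})
        sc = make_scores({"E": -3.0, "F": 1.0, "G": 1.0, "H": 1.0})
        result = mwcs.solve_exact(g, sc)
        assert result.members == frozenset({"F"})
        assert result.total_score == pytest.approx(1.0)

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("X")
        result = mwcs.solve_exact(g, make_scores({"X": 0.7}))
        assert result.members == frozenset({"X"})
        assert result.total_score == pytest.approx(0.7)

    def test_size_limit_enforced(self):
        g = nx.path_graph(25)
        sc = make_scores({v: 1.0 for v in g.nodes})
        with pytest.raises(MwcsSizeError, match="heuristic"):
            mwcs.solve_exact(g, sc)

    def test_matches_naive_enumeration_oracle(self):
        for seed in range(40):
            g, sc = random_scored_graph(seed)
            result = mwcs.solve_exact(g, sc)
            assert result.total_score == pytest.approx(
                brute_force_optimum(g, sc), abs=1e-9
            ), f"instance seed {seed}"

    def test_disconnected_graph_returns_best_component(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        sc = make_scores({"A": 1.0, "B": 1.0, "C": 5.0, "D": -0.1})
        result = mwcs.solve_exact(g, sc)
        assert result.members == frozenset({"C"})


class TestSolveHeuristic:
    def test_matches_exact_on_path(self, path_graph_scores):
        result = mwcs.solve_heuristic(*path_graph_scores)
        assert result.members == frozenset({"B", "C", "D"})
        assert result.total_score == pytest.approx(2.5)

    def test_all_negative_falls_back_to_best_single_node(self):
        g = nx.path_graph(3)
        g = nx.relabel_nodes(g, {0: "A", 1: "B", 2: "C"})
        sc = make_scores({"A": -1.0, "B": -0.2, "C": -3.0})
        with pytest.warns(UserWarning, match="non-positive"):
            result = mwcs.solve_heuristic(g, sc)
        assert result.members == frozenset({"B"})
        assert result.total_score == pytest.approx(-0.2)

    def test_unprofitable_bridge_not_crossed(self):
        g = nx.Graph([("P", "X"), ("X", "Q")])
        sc = make_scores({"P": 3.0, "X": -4.0, "Q": 2.0})
        result = mwcs.solve_heuristic(g, sc)
        assert result.members == frozenset({"P"})

    def test_profitable_bridge_crossed(self):
        g = nx.Graph([("P", "X"), ("X", "Q")])
        sc = make_scores({"P": 3.0, "X": -1.0, "Q": 2.0})
        result = mwcs.solve_heuristic(g, sc)
        assert result.members == frozenset({"P", "X", "Q"})
        assert result.total_score == pytest.approx(4.0)

    def test_guarantees_on_random_instances(self):
        for seed in range(60):
            g, sc = random_scored_graph(seed)
            exact = mwcs.solve_exact(g, sc)
            heur = mwcs.solve_heuristic(g, sc)
            # never exceeds the optimum, always beats the best single node
            assert heur.total_score <= exact.total_score + 1e-9
            assert heur.total_score >= max(sc.scores.values()) - 1e-9
            # connectivity
            assert nx.is_connected(g.subgraph(heur.members))
            # no removable non-positive leaf
            sub = g.subgraph(heur.members)
            if len(heur.members) > 1:
                for v in heur.members:
                    if sub.degree(v) <= 1:
                        assert sc.scores[v] > 0
            # positive components wholly inside or outside
            positives = [v for v in g.nodes if sc.scores[v] > 0]
            for comp in nx.connected_components(g.subgraph(positives)):
                inside = comp & heur.members
                assert not inside or inside == comp

    def test_deterministic(self, synthetic_instance):
        from ppimodules import bum

        inst = synthetic_instance
        fit = bum.fit_bum(inst.table.p_values, seed=0)
        scores = bum.score_nodes(inst.table, fit, bum.bonferroni_threshold(len(inst.table)))
        r1 = mwcs.solve_heuristic(inst.network, scores)
        r2 = mwcs.solve_heuristic(inst.network, scores)
        assert r1.members == r2.members and r1.total_score == r2.total_score


class TestModuleReport:
    def test_counts(self, path_graph_scores):
        g, sc = path_graph_scores
        result = mwcs.solve_exact(g, sc)
        sets = GeneSetCollection({"X": frozenset({"B"})})
        report = mwcs.module_report(result, g, sets)
        assert report["n_members"] == 3
        assert report["n_positive_members"] == 2
        assert report["per_set"]["X"] == 1

    def test_without_gene_sets(self, path_graph_scores):
        g, sc = path_graph_scores
        report = mwcs.module_report(mwcs.solve_exact(g, sc), g)
        assert report["per_set"] == {}

    def test_module_covering_full_set(self, path_graph_scores):
        g, sc = path_graph_scores
        result = mwcs.solve_exact(g, sc)
        sets = GeneSetCollection({"all": frozenset(result.members)})
        assert mwcs.module_report(result, g, sets)["per_set"]["all"] == len(result.members)


class TestModuleResult:
    def test_total_score_consistency_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            mwcs.ModuleResult(
                members=frozenset({"A"}),
                total_score=99.0,
                solver="exact",
                node_scores={"A": 1.0},
            )

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mwcs.ModuleResult(
                members=frozenset(), total_score=0.0, solver="exact", node_scores={}
            )
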