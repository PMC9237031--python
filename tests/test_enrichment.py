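import math

import networkx as nx
import numpy as np
import pytest

from ppimodules import enrichment
from ppimodules.io import GeneSetCollection
from tests.conftest import toy_table


def expression_table(values: dict[str, float]):
    return toy_table({g: 0.5 for g in values}, expression=values)


class TestDeciles:
    def test_equal_partition(self):
        table = expression_table({f"G{i:03d}": float(i) for i in range(100)})
        bins = enrichment.assign_expression_deciles(table)
        counts = np.bincount(list(bins.assignment.values()))[1:]
        assert counts.tolist() == [10] * 10

    def test_twenty_genes_two_per_bin(self):
        table = expression_table({f"G{i:02d}": float(i) for i in range(20)})
        bins = enrichment.assign_expression_deciles(table)
        assert sorted(np.bincount(list(bins.assignment.values()))[1:]) == [2] * 10

    def test_monotone_relabeling_invariance(self):
        raw = {f"G{i:02d}": float(i + 1) for i in range(30)}
        squashed = {g: math.log(v) for g, v in raw.items()}  # strictly monotone
        b1 = enrichment.assign_expression_deciles(expression_table(raw))
        b2 = enrichment.assign_expression_deciles(expression_table(squashed))
        assert b1.assignment == b2.assignment

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            enrichment.assign_expression_deciles(
                expression_table({f"G{i}": float(i) for i in range(9)})
            )


class TestMatchedSampling:
    @pytest.fixture
    def table(self):
        rng = np.random.default_rng(0)
        return expression_table(
            {f"G{i:03d}": float(v) for i, v in enumerate(rng.lognormal(2, 1, 200))}
        )

    def test_decile_histogram_preserved_per_draw(self, table):
        bins = enrichment.assign_expression_deciles(table)
        universe = set(bins.assignment)
        target = set(list(universe)[:15])
        sets = enrichment.sample_matched_set(bins, target, universe, "decile", 20, seed=1)
        want = bins.histogram(target)
        for s in sets:
            assert len(s) == len(target)
            assert not s & target
            assert np.array_equal(bins.histogram(s), want)

    def test_single_bin_target_stays_in_bin(self, table):
        bins = enrichment.assign_expression_deciles(table)
        universe = set(bins.assignment)
        bin3 = bins.members(3)
        target = set(bin3[:5])
        (sampled,) = enrichment.sample_matched_set(bins, target, universe, "decile", 1, seed=2)
        assert all(bins.assignment[g] == 3 for g in sampled)

    def test_reproducible_given_seed(self, table):
        bins = enrichment.assign_expression_deciles(table)
        universe = set(bins.assignment)
        target = set(list(universe)[:10])
        a = enrichment.sample_matched_set(bins, target, universe, "decile", 100, seed=7)
        b = enrichment.sample_matched_set(bins, target, universe, "decile", 100, seed=7)
        assert a == b and len(a) == 100

    def test_exhausted_bin_is_an_error_naming_it(self):
        # 10 distinct expression levels, one gene per bin: no candidate left in
        # the target gene's bin
        table = expression_table({f"G{i}": float(i) for i in range(10)})
        bins = enrichment.assign_expression_deciles(table)
        with pytest.raises(ValueError, match="bin"):
            enrichment.sample_matched_set(bins, {"G0"}, set(bins.assignment), "decile", 1, seed=0)

    def test_pct10_window_respected(self):
        values = {"T": 100.0, "A": 95.0, "B": 108.0, "C": 111.0, "D": 50.0}
        table = expression_table(values)
        sets = enrichment.sample_matched_set(
            table, {"T"}, set(values), "pct10", 50, seed=3, table=table
        )
        for (g,) in map(tuple, sets):
            assert 90.0 <= values[g] <= 110.0

    def test_pct10_no_candidate_is_an_error(self):
        values = {"T": 100.0, "D": 50.0}
        table = expression_table(values)
        with pytest.raises(ValueError, match="T"):
            enrichment.sample_matched_set(table, {"T"}, set(values), "pct10", 1, seed=0, table=table)


class TestConnectivityStatistic:
    def test_hexagon_with_chord(self):
        g = nx.cycle_graph(6)
        g.add_edge(0, 3)
        g = nx.relabel_nodes(g, {i: str(i + 1) for i in g.nodes})
        stat = enrichment.connectivity_statistic(g, {"1", "2"}, {"4", "5"})
        assert stat == pytest.approx(1 / 7)

    def test_unconnected_sets_give_zero(self):
        g = nx.path_graph(5)
        assert enrichment.connectivity_statistic(g, {0}, {4}) == 0.0

    def test_all_edges_cross(self):
        g = nx.complete_bipartite_graph(3, 3)
        stat = enrichment.connectivity_statistic(g, {0, 1, 2}, {3, 4, 5})
        assert stat == 1.0

    def test_symmetric(self):
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        rng = np.random.default_rng(1)
        a = set(rng.choice(30, 8, replace=False).tolist())
        b = set(rng.choice(30, 8, replace=False).tolist()) - a
        assert enrichment.connectivity_statistic(g, a, b) == pytest.approx(
            enrichment.connectivity_statistic(g, b, a)
        )

    def test_overlap_removed_with_warning(self):
        g = nx.path_graph(4)
        with pytest.warns(UserWarning, match="both sets"):
            stat = enrichment.connectivity_statistic(g, {1, 2}, {2, 3})
        # overlap gene 2 counts for the first set only
        assert stat == enrichment.connectivity_statistic(g, {1, 2}, {3})

    def test_both_sets_empty_rejected(self):
        with pytest.raises(ValueError):
            enrichment.connectivity_statistic(nx.path_graph(3), {"X"}, {"Y"})


class TestConnectivityEnrichment:
    def test_bonferroni_over_number_of_disease_sets(self, synthetic_instance):
        inst = synthetic_instance
        genes = sorted(inst.network.nodes)
        disease = GeneSetCollection(
            {"set1": frozenset(genes[:20]), "set2": frozenset(genes[20:40])}
        )
        de = frozenset(genes[300:330])
        results = enrichment.connectivity_enrichment(
            inst.network, disease, de, inst.table, B=20, seed=9
        )
        assert len(results) == 2
        for r in results:
            assert r.adjusted_p == pytest.approx(min(1.0, 2 * r.empirical_p))
            assert len(r.null_stats) == 20

    def test_planted_excess_detected(self):
        from ppimodules import simulate

        inst = simulate.make_instance(seed=7, disease_size=30, cross_edge_excess=20)
        pv = inst.table.p_value_of()
        de = frozenset(pv.sort_values().index[:25])
        (r,) = enrichment.connectivity_enrichment(
            inst.network,
            GeneSetCollection({"disease": inst.disease_set}),
            de,
            inst.table,
            B=100,
            seed=5,
        )
        assert r.observed_stat > float(np.mean(r.null_stats))
        assert r.empirical_p <= 0.05


class TestOverlapTest:
    def hypergeom_tail_oracle(self, N, K, n, k):
        """Exact combinatorial summation, independent of scipy."""
        return sum(
            math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)
        ) / math.comb(N, n)

    def test_matches_combinatorial_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            N = int(rng.integers(20, 80))
            K = int(rng.integers(5, N - 5))
            n = int(rng.integers(5, N - 5))
            universe = [f"G{i}" for i in range(N)]
            reference = set(universe[:K])
            query = set(rng.choice(universe, n, replace=False).tolist())
            k = len(query & reference)
            rec = enrichment.overlap_test(query, reference, universe)
            assert rec["overlap_count"] == k
            assert rec["hypergeom_p"] == pytest.approx(
                self.hypergeom_tail_oracle(N, K, n, k), rel=1e-10
            )

    def test_saturated_overlap_has_p_one(self):
        universe = {f"G{i}" for i in range(50)}
        rec = enrichment.overlap_test(universe, universe, universe)
        assert rec["overlap_count"] == 50
        assert rec["hypergeom_p"] == pytest.approx(1.0)

    def test_worked_example(self):
        # universe 50, reference 10, query 10, overlap 5
        universe = [f"G{i}" for i in range(50)]
        reference = set(universe[:10])
        query = set(universe[5:15])
        rec = enrichment.overlap_test(query, reference, universe)
        assert rec["overlap_count"] == 5
        assert rec["hypergeom_p"] == pytest.approx(
            self.hypergeom_tail_oracle(50, 10, 10, 5), rel=1e-10
        )

    def test_zero_overlap_haldane_or_finite(self):
        universe = [f"G{i}" for i in range(40)]
        rec = enrichment.overlap_test(set(universe[:10]), set(universe[30:]), universe)
        assert rec["overlap_count"] == 0
        assert 0 < rec["odds_ratio"] < 1
        assert math.isfinite(rec["odds_ratio"])

    def test_binomial_probability_override(self):
        universe = [f"G{i}" for i in range(40)]
        rec = enrichment.overlap_test(
            set(universe[:10]), set(universe[:20]), universe, binom_prob=0.5
        )
        from scipy import stats

        assert rec["binomial_p"] == pytest.approx(
            stats.binomtest(10, 10, 0.5, alternative="greater").pvalue
        )

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrichment.overlap_test({"A"}, {"A"}, set())
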