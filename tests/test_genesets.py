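"""Gene-set statistics: local networks, hypergeometric enrichment against
an enumeration oracle, connectivity permutation tests, hub rankings."""

import itertools
import math

import numpy as np
import pytest

import ctinet as ct
from ctinet.core import ValidationError
from conftest import random_weighted_network


class TestLocalNetwork:
    def test_isolated_query_single_node(self):
        net = ct.network_from_edges("n", [("a", "b", 1.0)], extra_nodes=["z"])
        local = ct.local_network(net, "z")
        assert local.nodes == {"z"} and local.n_edges == 0

    def test_star_center_radius_one_includes_leaf_edges(self):
        edges = [("hub", leaf, 1.0) for leaf in "abcd"] + [("a", "b", 2.0)]
        net = ct.network_from_edges("n", edges)
        local = ct.local_network(net, "hub", radius=1)
        assert local.nodes == {"hub", "a", "b", "c", "d"}
        assert ("a", "b") in local.edges  # induced subgraph keeps leaf-leaf edges

    def test_radius_two_on_path_bfs_oracle(self):
        net = ct.network_from_edges(
            "n", [("A", "B", 1.0), ("B", "C", 1.0), ("C", "D", 1.0)]
        )
        local = ct.local_network(net, "A", radius=2)
        assert local.nodes == {"A", "B", "C"}

    def test_absent_gene_error_suggests_neighbors(self):
        net = ct.network_from_edges("n", [("GENE1", "GENE2", 1.0)])
        with pytest.raises(ValidationError, match="GENE"):
            ct.local_network(net, "GENE3")


def enumeration_hypergeom_sf(k, N, K, n):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws."""
    universe = range(N)
    marked = set(range(K))
    hits = sum(
        1 for draw in itertools.combinations(universe, n) if len(marked & set(draw)) >= k
    )
    return hits / math.comb(N, n)


class TestEnrichment:
    def test_query_equals_universe_p_one(self):
        universe = {f"g{i}" for i in range(8)}
        query = ct.GeneSet("q", "", set(universe))
        sets = [ct.GeneSet("s", "", {"g0", "g1", "g2"})]
        (row,) = ct.hypergeometric_enrichment(query, sets, universe)
        assert row.overlap == 3
        assert row.p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        """Closed-form upper-tail p equals exhaustive enumeration, N <= 12."""
        for N, K, n in [(10, 4, 5), (12, 6, 4), (8, 3, 3), (11, 5, 6)]:
            universe = {f"g{i}" for i in range(N)}
            s = ct.GeneSet("s", "", {f"g{i}" for i in range(K)})
            for k in range(max(0, n + K - N), min(K, n) + 1):
                query_genes = {f"g{i}" for i in range(k)} | {
                    f"g{K + i}" for i in range(n - k)
                }
                query = ct.GeneSet("q", "", query_genes)
                (row,) = ct.hypergeometric_enrichment(query, [s], universe)
                assert row.p == pytest.approx(
                    enumeration_hypergeom_sf(k, N, K, n), abs=1e-12
                ), (N, K, n, k)

    def test_bh_step_up_hand_case(self):
        """p = (0.01, 0.02, 0.03, 0.04), m=4 => all q = 0.04."""
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
        # and through the enrichment interface: q >= p, q monotone in p order
        universe = {f"g{i}" for i in range(12)}
        query = ct.GeneSet("q", "", {f"g{i}" for i in range(6)})
        sets = [
            ct.GeneSet(f"s{j}", "", {f"g{i}" for i in range(j, j + 4)}) for j in range(5)
        ]
        rows = ct.hypergeometric_enrichment(query, sets, universe)
        assert all(r.q >= r.p for r in rows)
        assert all(rows[i].q <= rows[i + 1].q or rows[i].p == rows[i + 1].p
                   for i in range(len(rows) - 1))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValidationError):
            ct.hypergeometric_enrichment(ct.GeneSet("q", "", {"a"}), [], set())


class TestConnectivity:
    def test_no_internal_edges_zero(self):
        net = ct.network_from_edges("n", [("a", "b", 1.0), ("c", "d", 1.0)])
        s = ct.GeneSet("s", "", {"a", "c"})
        assert ct.within_group_connectivity(net, s) == 0.0

    def test_triangle_per_gene_normalization(self, triangle):
        s = ct.GeneSet("s", "", {"A", "B", "C"})
        # internal weight 1+2+3 = 6, |S in V| = 3
        assert ct.within_group_connectivity(triangle, s) == pytest.approx(2.0)
        assert ct.within_group_connectivity(triangle, s, norm="sum") == pytest.approx(6.0)
        assert ct.within_group_connectivity(triangle, s, norm="per_pair") == pytest.approx(2.0)

    def test_absent_genes_do_not_change_connectivity(self, triangle):
        base = ct.GeneSet("s", "", {"A", "B"})
        padded = ct.GeneSet("s", "", {"A", "B", "NOT_THERE"})
        assert ct.within_group_connectivity(triangle, base) == ct.within_group_connectivity(
            triangle, padded
        )

    def test_fewer_than_two_members_undefined(self, triangle):
        assert ct.within_group_connectivity(triangle, ct.GeneSet("s", "", {"A"})) is None


class TestConnectivityPermutation:
    def test_full_node_set_p_one(self):
        net = random_weighted_network(30, 4, seed=31)
        s = ct.GeneSet("all", "", set(net.nodes))
        res = ct.connectivity_permutation_test(net, s, n_permutations=100, seed=0)
        assert res.empirical_p == pytest.approx(1.0)

    def test_p_never_zero_nor_above_one(self):
        net = random_weighted_network(100, 4, seed=32)
        rng = np.random.default_rng(0)
        genes = sorted(net.nodes)
        for i in range(5):
            s = ct.GeneSet("s", "", set(rng.choice(genes, 10, replace=False)))
            res = ct.connectivity_permutation_test(net, s, n_permutations=100, seed=i)
            assert 0.0 < res.empirical_p <= 1.0

    def test_deterministic_given_seed(self):
        net = random_weighted_network(50, 4, seed=33)
        s = ct.GeneSet("s", "", set(sorted(net.nodes)[:8]))
        a = ct.connectivity_permutation_test(net, s, n_permutations=200, seed=5)
        b = ct.connectivity_permutation_test(net, s, n_permutations=200, seed=5)
        assert a.empirical_p == b.empirical_p and a.null_mean == b.null_mean

    def test_planted_module_significant_only_in_own_cell_type(self, pipeline):
        """The planted module is cohesive in its own cell type's network; in
        other cell types it is either absent (undefined) or unremarkable."""
        for label, gene_set in pipeline.module_sets.items():
            own = ct.connectivity_permutation_test(
                pipeline.dense[label], gene_set, n_permutations=1000, seed=42
            )
            assert own.empirical_p <= 0.01
            for other, net in pipeline.dense.items():
                if other == label:
                    continue
                members = gene_set.genes & net.nodes
                if len(members) < 2:
                    continue  # module genes dropped from this cell type's network
                res = ct.connectivity_permutation_test(
                    net, gene_set, n_permutations=1000, seed=43
                )
                assert res.empirical_p > 0.05


class TestScaledConnectivity:
    def test_identical_networks_near_zero(self):
        net = random_weighted_network(60, 4, seed=34)
        nets = {c: net for c in "ABC"}
        s = ct.GeneSet("s", "", set(sorted(net.nodes)[:10]))
        out = ct.scaled_connectivity(nets, s, n_permutations=500, seed=1)
        vals = np.array(list(out.values()))
        # identical substrates: only permutation noise separates cell types
        assert np.abs(vals).max() <= 1.5  # standardized, no dominant type
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std() == pytest.approx(1.0)

    def test_planted_cell_type_attains_maximum(self):
        """Boosting a set's internal edges in one cell type's network makes
        that cell type the connectivity maximum."""
        base = random_weighted_network(80, 4, seed=40)
        genes = sorted(base.nodes)
        s = ct.GeneSet("s", "", set(genes[:12]))
        nets = {}
        for i, c in enumerate("ABC"):
            boost = 5.0 if c == "A" else 1.0
            nets[c] = ct.network_from_edges(
                c,
                [
                    (a, b, w * boost if (a in s.genes and b in s.genes) else w)
                    for (a, b), w in base.weight.items()
                ],
            )
        out = ct.scaled_connectivity(nets, s, n_permutations=500, seed=2)
        assert max(out, key=out.get) == "A"

    def test_output_standardized(self):
        nets = {c: random_weighted_network(60, 4, seed=35 + i) for i, c in enumerate("ABCD")}
        s = ct.GeneSet("s", "", set(sorted(nets["A"].nodes)[:12]))
        out = ct.scaled_connectivity(nets, s, n_permutations=200, seed=3)
        vals = np.array(list(out.values()))
        assert vals.mean() == pytest.approx(0.0, abs=1e-12)
        assert vals.std() == pytest.approx(1.0)


class TestHubRankings:
    def test_star_center_ranked_first(self):
        edges = [("hub", f"leaf{i}", 1.0) for i in range(5)]
        net = ct.network_from_edges("n", edges)
        members, _ = ct.hub_rankings(net, ct.GeneSet("s", "", {"hub", "leaf0"}))
        assert members[0] == ("hub", 5.0)

    def test_neighbor_ranked_by_total_connection_to_set(self):
        edges = [
            ("m1", "n1", 1.0), ("m2", "n1", 2.0), ("m3", "n1", 3.0),
            ("m1", "n2", 5.0),
        ]
        net = ct.network_from_edges("n", edges)
        s = ct.GeneSet("s", "", {"m1", "m2", "m3"})
        _, neighbors = ct.hub_rankings(net, s)
        assert neighbors[0] == ("n1", 6.0)
        assert neighbors[1] == ("n2", 5.0)

    def test_set_with_no_neighbors_empty_ranking(self):
        net = ct.network_from_edges("n", [("a", "b", 1.0)])
        _, neighbors = ct.hub_rankings(net, ct.GeneSet("s", "", {"a", "b"}))
        assert neighbors == []

    def test_no_intersection_rejected(self, triangle):
        with pytest.raises(ValidationError):
            ct.hub_rankings(triangle, ct.GeneSet("s", "", {"zzz"}))
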