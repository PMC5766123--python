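"""Median-joining network, interiority ranking, and NJ trees."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

from haplogeo.genealogy import (
    bipartitions,
    interior_rank,
    mj_network,
    nj_from_distances,
    nj_tree,
)
from haplogeo.model import (
    DistanceModel,
    Haplotype,
    HaplotypeMatrix,
    MutationSite,
    distance_matrix,
    pairwise_steps,
)


def _binary_matrix(rows: dict):
    nsites = len(next(iter(rows.values())))
    sites = [MutationSite(i + 1, "r", "substitution") for i in range(nsites)]
    haps = [Haplotype(k, tuple("T" if b else "C" for b in v))
            for k, v in rows.items()]
    return HaplotypeMatrix(sites, haps)


class TestMJNetwork:
    def test_survey_network_basics(self, dataset, network):
        obs = {n for n, a in network.nodes(data=True) if a["observed"]}
        assert obs == set(dataset.matrix.labels)
        assert nx.is_connected(network)
        total = sum(a["frequency"] for n, a in network.nodes(data=True)
                    if a["observed"])
        assert total == 256

    def test_most_divergent_pair_path_length(self, network):
        assert nx.shortest_path_length(network, "F", "K", weight="steps") == 4

    def test_edge_steps_equal_endpoint_distances(self, dataset, network):
        m = dataset.matrix
        for u, v, attrs in network.edges(data=True):
            if u in m and v in m:
                assert attrs["steps"] == pairwise_steps(m[u], m[v], m)

    def test_path_lengths_respect_triangle_property(self, dataset, network):
        m = dataset.matrix
        spl = dict(nx.all_pairs_dijkstra_path_length(network, weight="steps"))
        for a, b in itertools.combinations(m.labels, 2):
            assert spl[a][b] >= pairwise_steps(m[a], m[b], m) - 1e-9

    def test_two_haplotypes_single_edge(self):
        m = _binary_matrix({"X": (0, 0), "Y": (1, 1)})
        net = mj_network(m)
        assert set(net.nodes) == {"X", "Y"}
        assert net["X"]["Y"]["steps"] == 2

    def test_median_vector_completes_star(self):
        # three haplotypes pairwise two steps apart through a shared
        # unobserved intermediate: MJ infers exactly one median hub
        m = _binary_matrix({"X": (1, 0, 0), "Y": (0, 1, 0), "Z": (0, 0, 1)})
        net = mj_network(m)
        medians = [n for n, a in net.nodes(data=True) if not a["observed"]]
        assert medians == ["mv1"]
        assert sorted(net.degree(n) for n in "XYZ") == [1, 1, 1]
        assert net.degree("mv1") == 3

    def test_tree_like_data_returns_exactly_the_msn_tree(self):
        # chain X - Y - Z: the median of the triple is Y itself
        m = _binary_matrix({"X": (0, 0), "Y": (1, 0), "Z": (1, 1)})
        net = mj_network(m)
        assert set(net.nodes) == {"X", "Y", "Z"}
        assert set(map(frozenset, net.edges)) == {frozenset("XY"), frozenset("YZ")}

    def test_contains_a_steiner_spanning_tree(self, dataset, network):
        """The network's minimum spanning tree (medians allowed as Steiner
        points) is never heavier than the MST over observed haplotypes."""
        m = dataset.matrix
        d = distance_matrix(m)
        g_obs = nx.Graph()
        for i, j in itertools.combinations(range(len(m)), 2):
            g_obs.add_edge(m.labels[i], m.labels[j], weight=d[i, j])
        mst_obs = nx.minimum_spanning_tree(g_obs).size(weight="weight")
        mst_net = nx.minimum_spanning_tree(
            network, weight="steps").size(weight="steps")
        assert mst_net <= mst_obs + 1e-9

    def test_negative_epsilon_rejected(self, dataset):
        with pytest.raises(ValueError):
            mj_network(dataset.matrix, epsilon=-1)

    def test_ssr_expansion_restores_stepwise_distances(self, dataset):
        net = mj_network(dataset.matrix)
        m = dataset.matrix
        # C and D differ by two SSR repeat units at one site; the network
        # distance between them must be 2, not 1
        assert nx.shortest_path_length(net, "C", "D", weight="steps") == 2


class TestInteriorRank:
    def test_survey_ancestral_set(self, network):
        ranking, interior = interior_rank(network)
        assert interior == {"D", "E", "F"}
        assert [r[0] for r in ranking[:3]] == ["E", "D", "F"]

    def test_path_middle_ranks_first(self):
        m = _binary_matrix({"X": (0, 0), "Y": (1, 0), "Z": (1, 1)})
        ranking, _ = interior_rank(mj_network(m))
        assert ranking[0][0] == "Y"

    def test_star_hub_first_leaves_tied(self):
        m = _binary_matrix({"H": (0, 0, 0), "X": (1, 0, 0),
                            "Y": (0, 1, 0), "Z": (0, 0, 1)})
        ranking, interior = interior_rank(mj_network(m))
        assert ranking[0][0] == "H"
        leaf_ecc = {e for n, e, _ in ranking if n != "H"}
        assert len(leaf_ecc) == 1  # ties reported as ties
        assert "H" in interior


class TestNJ:
    def test_survey_tree_separates_the_two_lineages(self, dataset):
        tree, _ = nj_tree(dataset.matrix)
        assert frozenset("ABK") in bipartitions(tree, dataset.matrix.labels)

    def test_two_taxa_edge(self):
        t = nj_from_distances(np.array([[0.0, 3.0], [3.0, 0.0]]), ["X", "Y"])
        tips = {n.name: n.length for n in t.tips()}
        assert tips == {"X": 1.5, "Y": 1.5}

    def test_additive_distances_recover_unique_topology(self):
        # additive on ((A,B),(C,D)): internal edge 2
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 2, 5, 6],
            [2, 0, 5, 6],
            [5, 5, 0, 3],
            [6, 6, 3, 0],
        ], dtype=float)
        tree = nj_from_distances(d, labels)
        got = bipartitions(tree, labels)
        # brute force: of the three possible quartet topologies only AB|CD
        # fits the four-point condition
        best = min(
            [frozenset("AB"), frozenset("AC"), frozenset("AD")],
            key=lambda s: _quartet_cost(d, labels, s),
        )
        assert got == {best} == {frozenset("AB")}

    def test_ultrametric_input_recovers_topology(self):
        labels = ["A", "B", "C", "D", "E"]
        # clock-like: ((A,B),(C,D),E)
        d = np.array([
            [0, 2, 8, 8, 10],
            [2, 0, 8, 8, 10],
            [8, 8, 0, 4, 10],
            [8, 8, 4, 0, 10],
            [10, 10, 10, 10, 0],
        ], dtype=float)
        got = bipartitions(nj_from_distances(d, labels), labels)
        assert frozenset("AB") in got and frozenset("CD") in got

    def test_rejects_single_taxon(self):
        with pytest.raises(ValueError):
            nj_from_distances(np.zeros((1, 1)), ["X"])

    def test_bootstrap_supports_are_fractions(self, dataset):
        tree, supports = nj_tree(dataset.matrix, bootstrap=20, seed=0)
        assert supports
        assert all(0.0 <= v <= 1.0 for v in supports.values())
        abk = frozenset("ABK")
        assert supports.get(abk, 0.0) > 0.5


def _quartet_cost(d, labels, pair):
    i, j = (labels.index(x) for x in sorted(pair))
    k, l = (labels.index(x) for x in sorted(set(labels) - set(pair)))
    return d[i, j] + d[k, l]
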