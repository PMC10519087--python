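"""Five centrality measures against independent brute-force oracles."""

import networkx as nx
import numpy as np
import pytest

from dpnet.centrality import (
    CentralityConfig,
    MEASURES,
    betweenness_centrality,
    closeness_centrality,
    compute_all,
    degree_centrality,
    eigenvector_centrality,
    pagerank_centrality,
)
from dpnet.kg_model import ConceptNode, KnowledgeGraph

from conftest import kg_from_edges, path_kg, random_kg, star_kg
from oracles import (
    betweenness_enumeration_oracle,
    betweenness_oracle,
    closeness_oracle,
    degree_oracle,
    eigenvector_oracle,
    pagerank_oracle,
)


def _undirected_edges(kg):
    return [(e.source_id, e.target_id) for e in kg.undirected_view().edges()]


def _directed_edges(kg):
    return {(e.source_id, e.target_id) for e in kg.edges()}


class TestDegree:
    def test_star_hub(self):
        assert degree_centrality(star_kg(6))["hub"] == 6

    def test_isolated_node(self):
        kg = kg_from_edges([("a", "b")], nodes=["a", "b", "c"])
        assert degree_centrality(kg)["c"] == 0

    def test_triangle_uniform(self):
        kg = kg_from_edges([("a", "b"), ("b", "c"), ("c", "a")])
        assert set(degree_centrality(kg).values()) == {2.0}


class TestCloseness:
    def test_star_hub_is_one(self):
        assert closeness_centrality(star_kg(8))["hub"] == pytest.approx(1.0)

    def test_path3_values(self):
        """Middle node at distance 1 from both ends: 1.0; ends: 2/(1+2)=2/3."""
        scores = closeness_centrality(path_kg(3))
        assert scores["v2"] == pytest.approx(1.0)
        assert scores["v1"] == pytest.approx(2 / 3)
        assert scores["v3"] == pytest.approx(2 / 3)

    def test_singleton_component_scores_zero(self):
        kg = kg_from_edges([("a", "b")], nodes=["a", "b", "c"])
        assert closeness_centrality(kg)["c"] == 0.0


class TestBetweenness:
    def test_path3_middle_is_one(self):
        assert betweenness_centrality(path_kg(3))["v2"] == pytest.approx(1.0)

    def test_leaves_are_zero(self):
        scores = betweenness_centrality(star_kg(5))
        assert all(scores[f"leaf{i:02d}"] == 0.0 for i in range(5))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_path_enumeration(self, seed):
        kg = random_kg(15, 0.25, seed=seed, connected=True)
        got = betweenness_centrality(kg)
        expected = betweenness_enumeration_oracle(kg.node_ids(), _undirected_edges(kg))
        for n in kg.node_ids():
            assert got[n] == pytest.approx(expected[n], abs=1e-12)


class TestEigenvector:
    def test_cycle_uniform_by_symmetry(self):
        kg = kg_from_edges([(f"v{i}", f"v{(i+1)%6}") for i in range(6)])
        scores = eigenvector_centrality(kg)
        assert np.allclose(list(scores.values()), 1.0)

    def test_star_hub_max_normalized_to_one(self):
        scores = eigenvector_centrality(star_kg(9))
        assert scores["hub"] == pytest.approx(1.0)
        assert all(scores[f"leaf{i:02d}"] < 1.0 for i in range(9))

    def test_edgeless_graph_rejected(self):
        kg = KnowledgeGraph()
        kg.add_node(ConceptNode("a", "a"))
        with pytest.raises(ValueError, match="edgeless"):
            eigenvector_centrality(kg)

    def test_matches_dense_eigensolver(self):
        kg = random_kg(10, 0.3, seed=8, connected=True)
        got = eigenvector_centrality(kg)
        expected = eigenvector_oracle(kg.node_ids(), _undirected_edges(kg))
        for n in kg.node_ids():
            assert got[n] == pytest.approx(expected[n], abs=1e-3)

    @pytest.mark.parametrize("iters", [50, 200])
    def test_iteration_count_does_not_change_ranking(self, iters):
        """More iterations refine values but keep the node order."""
        kg = random_kg(20, 0.2, seed=13, connected=True)
        base = eigenvector_centrality(kg, CentralityConfig(eigenvector_iterations=100))
        other = eigenvector_centrality(kg, CentralityConfig(eigenvector_iterations=iters))
        order = lambda s: sorted(s, key=lambda n: (-s[n], n))
        assert order(base) == order(other)


class TestPageRank:
    def test_regular_strongly_connected_is_uniform(self):
        kg = kg_from_edges(
            [(f"v{i}", f"v{(i+1)%5}") for i in range(5)]
        )  # directed 5-cycle
        scores = pagerank_centrality(kg)
        assert np.allclose(list(scores.values()), 0.2, atol=1e-6)

    def test_scores_sum_to_one(self):
        kg = random_kg(25, 0.1, seed=3)
        assert sum(pagerank_centrality(kg).values()) == pytest.approx(1.0, abs=1e-9)

    def test_three_node_chain_fixed_point(self):
        """A->B->C with dangling C; exact fixed point from the linear system."""
        kg = path_kg(3)
        got = pagerank_centrality(kg, CentralityConfig(pagerank_epsilon=1e-14))
        expected = pagerank_oracle(kg.node_ids(), _directed_edges(kg))
        for n in kg.node_ids():
            assert got[n] == pytest.approx(expected[n], abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_solve(self, seed):
        kg = random_kg(20, 0.15, seed=seed, directed=True)
        got = pagerank_centrality(kg, CentralityConfig(pagerank_epsilon=1e-13))
        expected = pagerank_oracle(kg.node_ids(), _directed_edges(kg))
        for n in kg.node_ids():
            assert got[n] == pytest.approx(expected[n], abs=1e-9)


class TestComputeAll:
    def test_one_edge_graph_complete_table(self):
        table = compute_all(kg_from_edges([("a", "b")]))
        assert table.shape == (2, 5)
        assert list(table.columns) == list(MEASURES)
        assert not table.isna().any().any()

    def test_star_hub_tops_every_measure(self):
        table = compute_all(star_kg(10))
        for m in MEASURES:
            assert table[m].idxmax() == "hub"

    def test_bounds_contract(self):
        """Closeness/eigenvector/PageRank in [0,1]; PageRank sums to 1;
        degree equals the undirected adjacency count."""
        kg = random_kg(30, 0.1, seed=21)
        table = compute_all(kg)
        for m in ("closeness", "eigenvector", "pagerank"):
            assert ((table[m] >= 0) & (table[m] <= 1)).all()
        assert table["pagerank"].sum() == pytest.approx(1.0, abs=1e-9)
        und = kg.undirected_view().nx
        for n in kg.node_ids():
            assert table.at[n, "degree"] == und.degree(n)

    def test_betweenness_is_community_local(self):
        """Scores computed inside a community differ from whole-graph scores."""
        edges = (
            [(f"a{i}", f"a{j}") for i in range(4) for j in range(i + 1, 4)]
            + [(f"b{i}", f"b{j}") for i in range(4) for j in range(i + 1, 4)]
            + [("a0", "b0")]
        )
        kg = kg_from_edges(edges)
        whole = compute_all(kg)
        community = compute_all(kg.induced_subgraph([f"a{i}" for i in range(4)]))
        assert whole.at["a0", "betweenness"] > community.at["a0", "betweenness"]


def _connected_atlas_graphs():
    """Every connected graph on 2..7 nodes (the full small-graph atlas)."""
    from networkx.generators.atlas import graph_atlas_g

    return [
        g for g in graph_atlas_g()
        if 2 <= len(g) and g.number_of_edges() >= 1 and nx.is_connected(g)
    ]


class TestOracleEquivalence:
    """All five measures against brute force on an exhaustive small-graph
    sweep plus random 8- and 30-node graphs."""

    # high iteration count / tight epsilon isolate algorithmic correctness
    # from truncation of the fixed-point iterations
    CFG = CentralityConfig(eigenvector_iterations=500, pagerank_epsilon=1e-12)

    def _check(self, kg):
        und_nodes, und_edges = kg.node_ids(), _undirected_edges(kg)
        checks = {
            "degree": (degree_centrality(kg), degree_oracle(und_nodes, und_edges), 1e-12),
            "closeness": (
                closeness_centrality(kg), closeness_oracle(und_nodes, und_edges), 1e-12,
            ),
            "betweenness": (
                betweenness_centrality(kg), betweenness_oracle(und_nodes, und_edges), 1e-10,
            ),
            "eigenvector": (
                eigenvector_centrality(kg, self.CFG),
                eigenvector_oracle(und_nodes, und_edges),
                1e-5,
            ),
            "pagerank": (
                pagerank_centrality(kg, self.CFG),
                pagerank_oracle(und_nodes, _directed_edges(kg)),
                1e-8,
            ),
        }
        for measure, (got, expected, tol) in checks.items():
            for n in und_nodes:
                assert got[n] == pytest.approx(expected[n], abs=tol), (
                    f"{measure} mismatch at node {n}"
                )

    def test_exhaustive_small_graphs(self):
        graphs = _connected_atlas_graphs()
        assert len(graphs) > 900  # 1+2+6+21+112+853 connected graphs on <=7 nodes
        for g in graphs:
            self._check(kg_from_edges(list(g.edges), nodes=list(g.nodes)))

    @pytest.mark.parametrize("seed", range(20))
    def test_random_eight_node_graphs(self, seed):
        self._check(random_kg(8, 0.35, seed=seed, connected=True))

    @pytest.mark.parametrize("seed", range(50))
    def test_random_thirty_node_graphs(self, seed):
        self._check(random_kg(30, 0.12, seed=seed, connected=True))
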