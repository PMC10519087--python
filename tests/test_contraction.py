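"""Equivalence-component discovery, contraction rules 1-3, synonym filtering."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from dpnet.contraction import (
    MergedNode,
    MergePlan,
    contract,
    contraction_report,
    filter_synonyms,
    find_equivalence_components,
)
from dpnet.kg_model import ConceptNode, KnowledgeGraph
from dpnet.synthetic_kg import SynthConfig, generate_kg

from conftest import kg_from_edges
from oracles import UnionFind


def lafora_kg():
    """A disease merged with two genes and a drug via I_CODE links, plus two
    external neighbours."""
    kg = KnowledgeGraph()
    kg.add_node(ConceptNode("lafora", "Lafora disease", category="disease",
                            synonyms=["Lafora progressive myoclonus epilepsy"]))
    kg.add_node(ConceptNode("epm2a", "EPM2A", category="gene"))
    kg.add_node(ConceptNode("epm2b", "EPM2B", category="gene"))
    kg.add_node(ConceptNode("metformin", "Metformin", category="drug"))
    kg.add_node(ConceptNode("outside1", "Myoclonus", category="phenotype"))
    kg.add_node(ConceptNode("outside2", "Seizure", category="phenotype"))
    kg.add_edge("lafora", "epm2a", "I_CODE")
    kg.add_edge("lafora", "epm2b", "I_CODE")
    kg.add_edge("lafora", "metformin", "I_CODE")
    kg.add_edge("lafora", "outside1", "R_has_phenotype")
    kg.add_edge("epm2a", "outside2", "R_related")
    return kg


class TestFindComponents:
    def test_icode_component_of_four(self):
        plan = find_equivalence_components(lafora_kg())
        assert len(plan.components) == 1
        assert plan.components[0] == frozenset({"lafora", "epm2a", "epm2b", "metformin"})
        assert plan.predicates_used == frozenset({"I_CODE"})

    def test_no_equivalence_edges_empty_plan(self):
        plan = find_equivalence_components(kg_from_edges([("a", "b", "R_related")]))
        assert plan.components == []

    def test_chain_is_transitive(self):
        kg = kg_from_edges([("A", "B", "I_CODE"), ("B", "C", "N_Name")])
        plan = find_equivalence_components(kg)
        assert plan.components == [frozenset({"A", "B", "C"})]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_union_find_oracle(self, seed):
        kg, _ = generate_kg(
            SynthConfig(n_diseases=30, n_genes=20, n_drugs=10, n_phenotypes=5,
                        n_communities=2, duplication_prob=0.4, seed=seed)
        )
        plan = find_equivalence_components(kg)
        uf = UnionFind()
        from dpnet.kg_model import EQUIVALENCE_PREDICATES

        for e in kg.edges():
            if e.predicate in EQUIVALENCE_PREDICATES:
                uf.union(e.source_id, e.target_id)
        assert set(plan.components) == {c for c in uf.components() if len(c) >= 2}

    def test_empty_predicate_set_rejected(self):
        with pytest.raises(ValueError):
            find_equivalence_components(lafora_kg(), frozenset())


class TestContract:
    def test_fig_style_merge(self):
        """4-node component: internal edges vanish, 2 external edges reattach."""
        kg = lafora_kg()
        plan = find_equivalence_components(kg)
        out = contract(kg, plan)
        assert out.n_nodes == 3
        merged_id = "merged:epm2a"
        assert out.has_node(merged_id)
        edges = {(e.source_id, e.target_id, e.predicate) for e in out.edges()}
        assert edges == {
            (merged_id, "outside1", "R_has_phenotype"),
            (merged_id, "outside2", "R_related"),
        }
        node = out.node(merged_id)
        assert "Lafora disease" in [node.primary_label, *node.alt_labels]

    def test_empty_plan_is_identity(self):
        kg = lafora_kg()
        assert contract(kg, MergePlan()) == kg

    def test_overlapping_components_rejected(self):
        kg = lafora_kg()
        plan = MergePlan(components=[
            frozenset({"lafora", "epm2a"}), frozenset({"epm2a", "epm2b"}),
        ])
        with pytest.raises(ValueError, match="overlap"):
            contract(kg, plan)

    def test_mixed_category_merged_node_keeps_category_set(self):
        kg = lafora_kg()
        out = contract(kg, find_equivalence_components(kg))
        import json

        cats = json.loads(out.nx.nodes["merged:epm2a"]["categories"])
        assert set(cats) == {"disease", "gene", "drug"}

    @pytest.mark.parametrize("seed", range(50))
    def test_conservation_law(self, seed):
        """nodes_after = nodes_before − Σ(|component|−1); edge ledger balances."""
        kg, _ = generate_kg(
            SynthConfig(n_diseases=20, n_genes=15, n_drugs=10, n_phenotypes=5,
                        n_communities=2, duplication_prob=0.35, seed=seed)
        )
        plan = find_equivalence_components(kg)
        out = contract(kg, plan)
        assert out.n_nodes == kg.n_nodes - sum(len(c) - 1 for c in plan.components)

        mapping = {m: f"merged:{min(c)}" for c in plan.components for m in c}
        internal = 0
        mapped = set()
        collapsed = 0
        for e in kg.edges():
            u = mapping.get(e.source_id, e.source_id)
            v = mapping.get(e.target_id, e.target_id)
            if u == v:
                internal += 1
            elif (u, v, e.predicate) in mapped:
                collapsed += 1
            else:
                mapped.add((u, v, e.predicate))
        assert out.n_edges == kg.n_edges - internal - collapsed

        report = contraction_report(plan, kg, out)
        assert report["internal_edges_removed"] == internal
        assert report["parallel_edges_collapsed"] == collapsed

    @pytest.mark.parametrize("seed", range(10))
    def test_idempotence(self, seed):
        """Contracting a contracted graph finds nothing left to merge."""
        kg, _ = generate_kg(
            SynthConfig(n_diseases=20, n_genes=15, n_drugs=10, n_phenotypes=5,
                        n_communities=2, duplication_prob=0.4, seed=seed)
        )
        once = contract(kg, find_equivalence_components(kg))
        again_plan = find_equivalence_components(once)
        assert again_plan.components == []
        assert contract(once, again_plan) == once

    @pytest.mark.parametrize("seed", range(5))
    def test_connectivity_never_decreases(self, seed):
        import networkx as nx

        kg, _ = generate_kg(
            SynthConfig(n_diseases=15, n_genes=10, n_drugs=8, n_phenotypes=4,
                        n_communities=2, duplication_prob=0.4, seed=seed)
        )
        plan = find_equivalence_components(kg)
        out = contract(kg, plan)
        mapping = {m: f"merged:{min(c)}" for c in plan.components for m in c}
        before = kg.undirected_view().nx
        after = out.undirected_view().nx
        for u, v in zip(kg.node_ids()[:-1], kg.node_ids()[1:]):
            if nx.has_path(before, u, v):
                mu, mv = mapping.get(u, u), mapping.get(v, v)
                assert mu == mv or nx.has_path(after, mu, mv)


class TestFilterSynonyms:
    def _merged(self, labels):
        return MergedNode(new_id="m", member_ids=["a", "b"], labels=list(labels),
                          categories=frozenset({"disease"}))

    def test_recorded_synonym_dropped(self):
        merged = self._merged(["Addison's Disease", "Adrenal aplasia"])
        index = {"Addison's Disease": {"Adrenal aplasia"}}
        assert filter_synonyms(merged, index).labels == ["Addison's Disease"]

    def test_empty_index_unchanged(self):
        merged = self._merged(["X", "Y"])
        assert filter_synonyms(merged, {}).labels == ["X", "Y"]

    def test_mutually_synonymous_triple_all_orderings(self):
        """Whatever the order, exactly one of a mutually-synonymous triple stays."""
        names = ["A", "B", "C"]
        index = {n: set(names) - {n} for n in names}
        for perm in itertools.permutations(names):
            result = filter_synonyms(self._merged(perm), index)
            assert result.labels == [perm[0]]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(["A", "B", "C", "D"]), min_size=1, unique=True))
    def test_first_seen_always_retained(self, labels):
        index = {l: {"B"} for l in labels if l != "B"}
        result = filter_synonyms(self._merged(labels), index)
        assert result.labels[0] == labels[0]
        assert set(result.labels) <= set(labels)
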