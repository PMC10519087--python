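"""Node contraction over equivalence edges.

Concepts that appear under several source resources are linked by equivalence
predicates (``N_Name``, ``I_CODE``, ``R_equivalentClass``, ``R_exactMatch``).
Contraction replaces each connected component of the equivalence-edge
subgraph (direction ignored, transitively closed) by a single merged node:

1. the members' attributes are concatenated (labels de-duplicated and then
   synonym-filtered: a label recorded as a synonym of an already-retained
   label is dropped);
2. edges internal to a component are removed;
3. edges between a member and an outside node are reattached to the merged
   node, with parallel edges of identical predicate collapsed to one.

The merged node id is ``merged:<lexicographically smallest member id>`` so
that contraction is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx

from .kg_model import EQUIVALENCE_PREDICATES, ConceptNode, KnowledgeGraph, _dedup

__all__ = [
    "MergePlan",
    "MergedNode",
    "find_equivalence_components",
    "build_merged_node",
    "filter_synonyms",
    "contract",
    "contraction_report",
]


@dataclass
class MergePlan:
    """Connected components (size >= 2) of the equivalence-edge subgraph."""

    components: list[frozenset[str]] = field(default_factory=list)
    predicates_used: frozenset[str] = frozenset()

    def validate(self, graph: KnowledgeGraph) -> None:
        seen: set[str] = set()
        for comp in self.components:
            if len(comp) < 2:
                raise ValueError(f"component {sorted(comp)} smaller than 2 nodes")
            if seen & comp:
                raise ValueError(
                    f"overlapping components: {sorted(seen & comp)} appear twice"
                )
            seen |= comp
            for n in comp:
                if not graph.has_node(n):
                    raise ValueError(f"component member {n!r} not in graph")


@dataclass
class MergedNode:
    """A contracted node with provenance back to its members."""

    new_id: str
    member_ids: list[str]
    labels: list[str]
    categories: frozenset[str]
    provenance: dict[str, dict] = field(default_factory=dict)


def find_equivalence_components(
    graph: KnowledgeGraph, predicates: frozenset[str] | set[str] = EQUIVALENCE_PREDICATES
) -> MergePlan:
    """Connected components of the subgraph restricted to equivalence edges.

    Direction is ignored, so merging is transitive: A~B and B~C puts
    {A, B, C} in one component even if A and C are not directly linked.
    """
    if not predicates:
        raise ValueError("predicates set must be non-empty")
    h = nx.Graph()
    used: set[str] = set()
    for e in graph.edges():
        if e.predicate in predicates:
            h.add_edge(e.source_id, e.target_id)
            used.add(e.predicate)
    components = sorted(
        (frozenset(c) for c in nx.connected_components(h) if len(c) >= 2),
        key=lambda c: min(c),
    )
    return MergePlan(components=components, predicates_used=frozenset(used))


def filter_synonyms(merged: MergedNode, synonym_index: dict[str, set[str]]) -> MergedNode:
    """Drop labels that are recorded synonyms of an already-retained label.

    Retention is first-seen-wins over ``merged.labels``; at least one label
    always survives.  ``synonym_index`` maps a label to the set of strings
    known to be its synonyms.
    """
    retained: list[str] = []
    for label in merged.labels:
        if any(label in synonym_index.get(kept, ()) for kept in retained):
            continue
        retained.append(label)
    return replace(merged, labels=retained)


def build_merged_node(graph: KnowledgeGraph, component: frozenset[str]) -> MergedNode:
    """Concatenate member attributes into a merged node (rule 1) and
    synonym-filter its labels using the members' own synonym fields."""
    member_ids = sorted(component)
    members = [graph.node(m) for m in member_ids]
    labels: list[str] = []
    synonym_index: dict[str, set[str]] = {}
    for m in members:
        labels.append(m.primary_label)
        labels.extend(m.alt_labels)
        synonym_index.setdefault(m.primary_label, set()).update(m.synonyms)
    merged = MergedNode(
        new_id=f"merged:{member_ids[0]}",
        member_ids=member_ids,
        labels=_dedup(labels),
        categories=frozenset(m.category for m in members),
        provenance={m.node_id: m.to_attrs() for m in members},
    )
    return filter_synonyms(merged, synonym_index)


def _merged_concept(merged: MergedNode, members: list[ConceptNode]) -> ConceptNode:
    cats = sorted(merged.categories)
    return ConceptNode(
        node_id=merged.new_id,
        primary_label=merged.labels[0],
        alt_labels=merged.labels[1:],
        category=cats[0] if len(cats) == 1 else "other",
        source_resource=";".join(sorted({m.source_resource for m in members if m.source_resource})),
        synonyms=_dedup(s for m in members for s in m.synonyms),
        external_codes=_dedup(c for m in members for c in m.external_codes),
    )


def contract(graph: KnowledgeGraph, plan: MergePlan) -> KnowledgeGraph:
    """Contract each planned component into one merged node (rules 1–3).

    Nodes not covered by the plan are copied verbatim.  Intra-component edges
    disappear; boundary edges are reattached to the merged node, and parallel
    reattached edges with an identical predicate collapse to one (distinct
    predicates between the same pair are all kept).
    """
    plan.validate(graph)
    mapping: dict[str, str] = {}
    merged_nodes: dict[str, MergedNode] = {}
    for comp in plan.components:
        mn = build_merged_node(graph, comp)
        merged_nodes[mn.new_id] = mn
        for m in comp:
            mapping[m] = mn.new_id

    out = KnowledgeGraph(directed=graph.directed)
    for n in graph.node_ids():
        if n not in mapping:
            out.add_node(graph.node(n))
    for mn in merged_nodes.values():
        members = [graph.node(m) for m in mn.member_ids]
        out.add_node(
            _merged_concept(mn, members),
            member_ids=json.dumps(mn.member_ids),
            categories=json.dumps(sorted(mn.categories)),
            is_merged=True,
        )
    for e in graph.edges():
        u = mapping.get(e.source_id, e.source_id)
        v = mapping.get(e.target_id, e.target_id)
        if u == v:  # rule 2 (also drops reattachment self-loops)
            continue
        out.add_edge(u, v, e.predicate)  # rule 3; same-predicate parallels collapse
    return out


def contraction_report(
    plan: MergePlan, before: KnowledgeGraph, after: KnowledgeGraph
) -> dict:
    """JSON-able summary of a contraction: membership map plus the
    node/edge bookkeeping (merged-node count mirrors the pipeline ledger)."""
    internal = sum(
        1
        for e in before.edges()
        if any(e.source_id in c and e.target_id in c for c in plan.components)
    )
    merged_map = {
        f"merged:{min(c)}": sorted(c) for c in plan.components
    }
    return {
        "n_merged_nodes": len(plan.components),
        "merged": merged_map,
        "predicates_used": sorted(plan.predicates_used),
        "nodes_before": before.n_nodes,
        "nodes_after": after.n_nodes,
        "edges_before": before.n_edges,
        "edges_after": after.n_edges,
        "internal_edges_removed": internal,
        "parallel_edges_collapsed": before.n_edges - internal - after.n_edges,
    }


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return path
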