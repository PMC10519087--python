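"""Shared fixtures and small graph builders."""

from __future__ import annotations

import networkx as nx
import pytest

from dpnet.kg_model import ConceptNode, KnowledgeGraph


def kg_from_edges(edges, nodes=None, directed=True, categories=None):
    """Build a KnowledgeGraph from (u, v) or (u, v, predicate) tuples.

    Nodes default to the endpoints; labels default to the id; predicate
    defaults to "R_related".
    """
    categories = categories or {}
    kg = KnowledgeGraph(directed=directed)
    ids = list(nodes) if nodes is not None else []
    for e in edges:
        for endpoint in e[:2]:
            if endpoint not in ids:
                ids.append(endpoint)
    for n in ids:
        kg.add_node(
            ConceptNode(node_id=str(n), primary_label=str(n),
                        category=categories.get(n, "other"))
        )
    for e in edges:
        pred = e[2] if len(e) > 2 else "R_related"
        kg.add_edge(str(e[0]), str(e[1]), pred)
    return kg


def star_kg(n_leaves, hub="hub"):
    """Undirected star hub—leaf_i (community subgraphs carry symmetric ties)."""
    return kg_from_edges(
        [(hub, f"leaf{i:02d}") for i in range(n_leaves)], directed=False
    )


def path_kg(n):
    """Directed path v1 -> v2 -> ... -> vn."""
    return kg_from_edges([(f"v{i}", f"v{i+1}") for i in range(1, n)])


def random_kg(n, p, seed, directed=True, connected=False):
    """Erdős–Rényi graph as a KnowledgeGraph; optionally resampled until
    its undirected view is connected."""
    s = seed
    while True:
        g = nx.gnp_random_graph(n, p, seed=s, directed=directed)
        und = g.to_undirected() if directed else g
        if not connected or (len(und) and nx.is_connected(und)):
            break
        s += 10_000
    edges = [(f"n{u:03d}", f"n{v:03d}") for u, v in g.edges]
    return kg_from_edges(edges, nodes=[f"n{i:03d}" for i in range(n)], directed=directed)


@pytest.fixture
def two_cliques_kg():
    """Two 5-cliques joined by a single bridge edge."""
    edges = []
    for base in ("a", "b"):
        members = [f"{base}{i}" for i in range(5)]
        edges += [(members[i], members[j]) for i in range(5) for j in range(i + 1, 5)]
    edges.append(("a0", "b0"))
    return kg_from_edges(edges)


@pytest.fixture
def disconnected_cliques_kg():
    """Two 5-cliques with no edge between them (20 undirected edges total)."""
    edges = []
    for base in ("a", "b"):
        members = [f"{base}{i}" for i in range(5)]
        edges += [(members[i], members[j]) for i in range(5) for j in range(i + 1, 5)]
    return kg_from_edges(edges)
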