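"""Five node-centrality measures per community subgraph.

Conventions (matching the downstream normalization step):

* degree — raw undirected edge count per node (not normalized);
* closeness — Wasserman–Faust component-scaled inverse average distance,
  so disconnected subgraphs still yield values in [0, 1];
* betweenness — Brandes shortest-path counting divided by (n−1)(n−2)/2,
  i.e. the fraction of other-pair shortest paths passing through the node;
* eigenvector — fixed-iteration-count power iteration (default 100) on the
  undirected adjacency, max-normalized to [0, 1].  The iteration actually
  applies A + I: adding the identity leaves the principal eigenvector
  unchanged but guarantees convergence on bipartite subgraphs, where the
  plain iteration oscillates;
* PageRank — power iteration on the simple directed view (in-edges carry
  influence) with damping p (default 0.85), dangling mass redistributed
  uniformly, stopping when the L1 change drops below epsilon (default 1e-3);
  scores sum to 1.

Degree, closeness, betweenness and eigenvector use the undirected simple
view of the subgraph; PageRank keeps direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .kg_model import KnowledgeGraph

MEASURES = ("degree", "closeness", "betweenness", "eigenvector", "pagerank")


@dataclass
class CentralityConfig:
    eigenvector_iterations: int = 100
    pagerank_damping: float = 0.85
    pagerank_epsilon: float = 0.001

    def __post_init__(self) -> None:
        if self.eigenvector_iterations < 1:
            raise ValueError("eigenvector_iterations must be >= 1")
        if not 0.0 < self.pagerank_damping < 1.0:
            raise ValueError("pagerank_damping must be in (0, 1)")
        if self.pagerank_epsilon <= 0:
            raise ValueError("pagerank_epsilon must be > 0")


def _undirected_simple(graph: KnowledgeGraph) -> nx.Graph:
    return graph.nx if not graph.directed else nx.Graph(graph.nx.to_undirected(as_view=True))


def _directed_simple(graph: KnowledgeGraph) -> nx.DiGraph:
    return nx.DiGraph(graph.nx)


def degree_centrality(graph: KnowledgeGraph) -> dict[str, float]:
    """Number of (undirected, simple) edges attached to each node."""
    g = _undirected_simple(graph)
    return {n: float(d) for n, d in g.degree()}


def closeness_centrality(graph: KnowledgeGraph, wf_improved: bool = True) -> dict[str, float]:
    """Inverse average shortest-path distance, in [0, 1].

    With ``wf_improved`` (default) the per-component value is scaled by the
    fraction of the graph the component covers; nodes in singleton
    components score 0.  Set ``wf_improved=False`` for the raw
    per-component form.
    """
    g = _undirected_simple(graph)
    return nx.closeness_centrality(g, wf_improved=wf_improved)


def betweenness_centrality(graph: KnowledgeGraph) -> dict[str, float]:
    """Fraction of other-pair shortest paths running through each node."""
    g = _undirected_simple(graph)
    return nx.betweenness_centrality(g, normalized=True)


def eigenvector_centrality(
    graph: KnowledgeGraph, config: CentralityConfig | None = None
) -> dict[str, float]:
    """Fixed-count power iteration from the uniform vector, max-normalized."""
    config = config or CentralityConfig()
    g = _undirected_simple(graph)
    if g.number_of_edges() == 0:
        raise ValueError("eigenvector centrality undefined on an edgeless graph")
    nodes = sorted(g.nodes)
    a = nx.to_numpy_array(g, nodelist=nodes)
    x = np.full(len(nodes), 1.0 / len(nodes))
    for _ in range(config.eigenvector_iterations):
        x = x + a @ x  # (A + I) x: same fixed point, no bipartite oscillation
        x /= x.max()
    return dict(zip(nodes, x))


def pagerank_centrality(
    graph: KnowledgeGraph, config: CentralityConfig | None = None, max_iter: int = 1000
) -> dict[str, float]:
    """Damped random-walk stationary scores on the directed view; sum to 1."""
    config = config or CentralityConfig()
    g = _directed_simple(graph)
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("pagerank undefined on an empty graph")
    a = nx.to_numpy_array(g, nodelist=nodes)  # a[i, j] = edge i -> j
    out = a.sum(axis=1)
    dangling = out == 0
    p = config.pagerank_damping
    x = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        walk = np.zeros(n)
        nz = ~dangling
        if nz.any():
            walk = a[nz].T @ (x[nz] / out[nz])
        walk += x[dangling].sum() / n
        x_new = (1.0 - p) / n + p * walk
        if np.abs(x_new - x).sum() < config.pagerank_epsilon:
            x = x_new
            break
        x = x_new
    return dict(zip(nodes, x))


def compute_all(
    graph: KnowledgeGraph, config: CentralityConfig | None = None
) -> pd.DataFrame:
    """All five measures for every node of one community subgraph.

    Returns a DataFrame indexed by node id with one column per measure.
    Intended to be called on the induced subgraph of a single community, not
    on the whole network: betweenness and closeness are community-local.
    """
    config = config or CentralityConfig()
    nodes = sorted(graph.node_ids())
    table = pd.DataFrame(index=pd.Index(nodes, name="node_id"), columns=MEASURES, dtype=float)
    table["degree"] = pd.Series(degree_centrality(graph))
    table["closeness"] = pd.Series(closeness_centrality(graph))
    table["betweenness"] = pd.Series(betweenness_centrality(graph))
    table["eigenvector"] = pd.Series(eigenvector_centrality(graph, config))
    table["pagerank"] = pd.Series(pagerank_centrality(graph, config))
    return table
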