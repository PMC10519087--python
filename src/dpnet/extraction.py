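"""Profile-network extraction: union of fixed-radius ego graphs.

Given a seed cluster of related diseases, the profile network is the induced
subgraph of the knowledge graph on the union of all nodes within ``radius``
hops of any seed (radius 3 by default).  Traversal ignores edge direction by
default — equivalence edges are semantically symmetric — but out-only and
in-only traversal modes are available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .kg_model import KnowledgeGraph

logger = logging.getLogger(__name__)

DIRECTION_MODES = ("undirected", "out", "in")


@dataclass
class ExtractionConfig:
    radius: int = 3
    direction_mode: str = "undirected"

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")
        if self.direction_mode not in DIRECTION_MODES:
            raise ValueError(
                f"direction_mode must be one of {DIRECTION_MODES}, got "
                f"{self.direction_mode!r}"
            )


def _traversal_graph(graph: KnowledgeGraph, mode: str):
    g = graph.nx
    if not graph.directed or mode == "out":
        return g
    if mode == "in":
        return g.reverse(copy=False)
    return g.to_undirected(as_view=True)


def _ball(graph: KnowledgeGraph, center: str, config: ExtractionConfig) -> set[str]:
    g = _traversal_graph(graph, config.direction_mode)
    return set(
        nx.single_source_shortest_path_length(g, center, cutoff=config.radius)
    )


def ego_subgraph(
    graph: KnowledgeGraph, center: str, config: ExtractionConfig | None = None
) -> KnowledgeGraph:
    """Induced subgraph on all nodes within ``config.radius`` hops of ``center``."""
    config = config or ExtractionConfig()
    if not graph.has_node(center):
        raise KeyError(f"ego center {center!r} not in graph")
    return graph.induced_subgraph(_ball(graph, center, config))


def load_seed_cluster(path: str | Path) -> list[str]:
    """Read a seed cluster file: plain text, one node id per line."""
    seeds = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            seeds.append(line)
    return seeds


def build_profile_network(
    graph: KnowledgeGraph,
    seeds: Sequence[str] | Iterable[str],
    config: ExtractionConfig | None = None,
) -> KnowledgeGraph:
    """Union of per-seed ego graphs, as an induced subgraph of ``graph``.

    Seeds missing from the graph are skipped with a warning (their count is
    logged); if none resolve, this is an error.  The edge set is the set of
    all input-graph edges between retained nodes, so the result is an induced
    subgraph — for radius-limited balls this keeps frontier–frontier edges
    that a union of per-ego edge sets would drop.
    """
    config = config or ExtractionConfig()
    seeds = list(seeds)
    resolved = [s for s in seeds if graph.has_node(s)]
    missing = len(seeds) - len(resolved)
    if missing:
        logger.warning("%d of %d seed nodes not found in graph; skipped", missing, len(seeds))
    if not resolved:
        raise ValueError("no seed nodes could be resolved in the graph")
    union: set[str] = set()
    for s in resolved:
        union |= _ball(graph, s, config)
    return graph.induced_subgraph(union)
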