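"""Core knowledge-graph data model, readers/writers, and whole-graph statistics.

The in-memory container wraps a :class:`networkx.MultiDiGraph` (knowledge-graph
predicates are directed, and two concepts may be linked by several distinct
predicates).  Nodes are biomedical concepts — diseases, genes, drugs,
phenotypes — carrying labels, synonyms and external codes; edges carry a single
``predicate`` string.  Equivalence predicates (``N_Name``, ``I_CODE``,
``R_equivalentClass``, ``R_exactMatch``) declare that two nodes describe the
same concept in different source resources.

Supported on-disk formats: GraphML, GEXF (list-valued node attributes are
JSON-encoded, since both schemas only allow scalar attribute values), and a
TSV edge list (``source<TAB>target<TAB>predicate``) with a sidecar JSON node
table at ``<path>.nodes.json``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

CATEGORIES = ("disease", "gene", "drug", "phenotype", "other")

#: Predicates that declare two nodes equivalent across source resources.
EQUIVALENCE_PREDICATES = frozenset(
    {"N_Name", "I_CODE", "R_equivalentClass", "R_exactMatch"}
)

#: ConceptNode fields holding lists (JSON-encoded in GraphML/GEXF).
_LIST_FIELDS = ("alt_labels", "synonyms", "external_codes")
_STR_FIELDS = ("primary_label", "category", "source_resource")


def _dedup(items: Iterable[str]) -> list[str]:
    """Order-preserving de-duplication."""
    seen: set[str] = set()
    out: list[str] = []
    for it in items:
        if it not in seen:
            seen.add(it)
            out.append(it)
    return out


@dataclass
class ConceptNode:
    """One biomedical concept.

    Parameters
    ----------
    node_id : opaque unique identifier within a graph.
    primary_label : human-readable name (non-empty).
    category : one of ``disease, gene, drug, phenotype, other``; anything
        else is mapped to ``other`` with a logged warning.
    alt_labels, synonyms, external_codes : de-duplicated string lists.
    source_resource : name of the resource the concept came from.
    """

    node_id: str
    primary_label: str
    category: str = "other"
    alt_labels: list[str] = field(default_factory=list)
    source_resource: str = ""
    synonyms: list[str] = field(default_factory=list)
    external_codes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.node_id:
            raise ValueError("node_id must be non-empty")
        if not self.primary_label:
            raise ValueError(f"node {self.node_id!r}: primary_label must be non-empty")
        if self.category not in CATEGORIES:
            logger.warning(
                "node %s: unknown category %r mapped to 'other'",
                self.node_id,
                self.category,
            )
            self.category = "other"
        for f in _LIST_FIELDS:
            setattr(self, f, _dedup(getattr(self, f)))

    def to_attrs(self) -> dict:
        """Node attribute dict as stored in the underlying networkx graph."""
        d = {"primary_label": self.primary_label, "category": self.category,
             "source_resource": self.source_resource}
        for f in _LIST_FIELDS:
            d[f] = list(getattr(self, f))
        return d

    @classmethod
    def from_attrs(cls, node_id: str, attrs: dict) -> "ConceptNode":
        """Build from an attribute dict; missing optional fields default."""
        return cls(
            node_id=node_id,
            primary_label=attrs.get("primary_label", node_id) or node_id,
            category=attrs.get("category", "other") or "other",
            alt_labels=list(attrs.get("alt_labels", [])),
            source_resource=attrs.get("source_resource", "") or "",
            synonyms=list(attrs.get("synonyms", [])),
            external_codes=list(attrs.get("external_codes", [])),
        )


@dataclass(frozen=True)
class KGEdge:
    """A typed edge: ``source --predicate--> target``."""

    source_id: str
    target_id: str
    predicate: str


class KnowledgeGraph:
    """Directed typed multigraph of :class:`ConceptNode`.

    Parallel edges between the same ordered pair are permitted only with
    distinct predicates (the predicate is used as the multigraph edge key, so
    re-adding an identical edge is a no-op).  Self-loops are rejected on input.
    """

    def __init__(self, directed: bool = True):
        self.directed = directed
        self._g: nx.MultiDiGraph | nx.Graph = (
            nx.MultiDiGraph() if directed else nx.Graph()
        )

    # -- container basics ---------------------------------------------------

    @property
    def nx(self) -> nx.MultiDiGraph | nx.Graph:
        """The underlying networkx graph (shared, not a copy)."""
        return self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def __len__(self) -> int:
        return self.n_nodes

    def has_node(self, node_id: str) -> bool:
        return self._g.has_node(node_id)

    def node_ids(self) -> list[str]:
        return list(self._g.nodes)

    def node(self, node_id: str) -> ConceptNode:
        if not self._g.has_node(node_id):
            raise KeyError(f"node {node_id!r} not in graph")
        return ConceptNode.from_attrs(node_id, self._g.nodes[node_id])

    def concepts(self) -> Iterator[ConceptNode]:
        for n in self._g.nodes:
            yield self.node(n)

    def add_node(self, node: ConceptNode, **extra) -> None:
        self._g.add_node(node.node_id, **node.to_attrs(), **extra)

    def add_edge(self, source_id: str, target_id: str, predicate: str) -> None:
        if not predicate:
            raise ValueError("predicate must be non-empty")
        if source_id == target_id:
            raise ValueError(f"self-loop on {source_id!r} not allowed")
        for n in (source_id, target_id):
            if not self._g.has_node(n):
                raise KeyError(f"edge endpoint {n!r} not in graph")
        if self.directed:
            self._g.add_edge(source_id, target_id, key=predicate, predicate=predicate)
        else:
            preds = set(self._g.get_edge_data(source_id, target_id, {}).get("predicates", ()))
            preds.add(predicate)
            self._g.add_edge(source_id, target_id, predicates=tuple(sorted(preds)))

    def edges(self) -> Iterator[KGEdge]:
        if self.directed:
            for u, v, d in self._g.edges(data=True):
                yield KGEdge(u, v, d["predicate"])
        else:
            for u, v, d in self._g.edges(data=True):
                for p in d.get("predicates", ("",)):
                    yield KGEdge(u, v, p)

    # -- derived graphs -----------------------------------------------------

    def induced_subgraph(self, node_ids: Iterable[str]) -> "KnowledgeGraph":
        """Induced subgraph on ``node_ids`` (all retained edges kept)."""
        sub = KnowledgeGraph(directed=self.directed)
        sub._g = self._g.subgraph(list(node_ids)).copy()
        return sub

    def undirected_view(self) -> "KnowledgeGraph":
        """Collapse to a simple undirected graph.

        Each directed edge yields one undirected adjacency; reciprocal pairs
        collapse to a single adjacency.  The predicates observed on an
        adjacency are preserved in the edge attribute ``predicates``.
        """
        if not self.directed:
            return self.copy()
        view = KnowledgeGraph(directed=False)
        for n, d in self._g.nodes(data=True):
            view._g.add_node(n, **d)
        for u, v, d in self._g.edges(data=True):
            view.add_edge(*sorted((u, v)), predicate=d["predicate"])
        return view

    def copy(self) -> "KnowledgeGraph":
        new = KnowledgeGraph(directed=self.directed)
        new._g = self._g.copy()
        return new

    # -- equality (node attr dicts + typed edge sets) -----------------------

    def _node_set(self):
        return {n: ConceptNode.from_attrs(n, d) for n, d in self._g.nodes(data=True)}

    def __eq__(self, other) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            self.directed == other.directed
            and self._node_set() == other._node_set()
            and set(self.edges()) == set(other.edges())
        )


# ---------------------------------------------------------------------------
# Whole-graph statistics
# ---------------------------------------------------------------------------


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Edges per node, E/N (the convention used throughout this pipeline)."""
    if n_nodes <= 0:
        raise ValueError("average degree undefined for an empty graph")
    return n_edges / n_nodes


def directed_density(n_nodes: int, n_edges: int) -> float:
    """Directed graph density E/(N·(N−1)); 0 for a single-node graph."""
    if n_nodes <= 0:
        raise ValueError("density undefined for an empty graph")
    if n_nodes == 1:
        return 0.0
    return n_edges / (n_nodes * (n_nodes - 1))


@dataclass
class GraphStats:
    """Summary network properties.

    ``diameter`` and ``average_path_length`` are measured on the largest
    connected component of the undirected view; ``lcc_fraction`` records how
    much of the graph that component covers.
    """

    n_nodes: int
    n_edges: int
    average_degree: float
    diameter: int
    average_path_length: float
    density: float
    lcc_fraction: float = 1.0

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "average_degree": self.average_degree,
            "diameter": self.diameter,
            "average_path_length": self.average_path_length,
            "density": self.density,
            "lcc_fraction": self.lcc_fraction,
        }


def compute_stats(graph: KnowledgeGraph) -> GraphStats:
    """Compute the summary properties of a graph.

    Average degree is E/N and density is E/(N·(N−1)) on the directed graph;
    path-based properties use breadth-first distances on the undirected view,
    restricted to its largest connected component when disconnected.
    """
    n, e = graph.n_nodes, graph.n_edges
    if n == 0:
        raise ValueError("cannot compute stats of an empty graph")
    und = graph.undirected_view().nx
    components = sorted(nx.connected_components(und), key=lambda c: (-len(c), min(c)))
    lcc = und.subgraph(components[0])
    if len(components) > 1:
        logger.info(
            "graph disconnected: path stats computed on largest component "
            "(%d of %d nodes)", len(lcc), n,
        )
    if len(lcc) > 1:
        diam = nx.diameter(lcc)
        apl = nx.average_shortest_path_length(lcc)
    else:
        diam, apl = 0, 0.0
    return GraphStats(
        n_nodes=n,
        n_edges=e,
        average_degree=average_degree(n, e),
        diameter=diam,
        average_path_length=apl,
        density=directed_density(n, e),
        lcc_fraction=len(lcc) / n,
    )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

FORMATS = ("graphml", "gexf", "tsv")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("graphml", "gexf"):
        return suffix
    if suffix in ("tsv", "txt"):
        return "tsv"
    raise ValueError(f"cannot infer graph format from {path.name!r}; pass format=")


def _encode_attrs(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        out[k] = json.dumps(v) if isinstance(v, (list, tuple)) else v
    return out


def _decode_attrs(d: dict) -> dict:
    out = dict(d)
    for f in _LIST_FIELDS:
        v = out.get(f)
        if isinstance(v, str):
            out[f] = json.loads(v) if v else []
    return out


def write_graph(graph: KnowledgeGraph, path: str | Path, format: str | None = None) -> Path:
    """Serialize ``graph``; the output is re-readable losslessly by read_graph."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    if fmt == "tsv":
        return _write_tsv(graph, path)
    g = nx.MultiDiGraph() if graph.directed else nx.Graph()
    for n, d in graph.nx.nodes(data=True):
        g.add_node(n, **_encode_attrs(d))
    for u, v, k, d in (
        graph.nx.edges(keys=True, data=True)
        if graph.directed
        else ((u, v, None, d) for u, v, d in graph.nx.edges(data=True))
    ):
        g.add_edge(u, v, **({"key": k} if k is not None else {}), **_encode_attrs(d))
    if fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    else:
        nx.write_gexf(g, path)
    return path


def read_graph(path: str | Path, format: str | None = None) -> KnowledgeGraph:
    """Read a graph written by :func:`write_graph` (or any conforming file)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")
    if fmt == "tsv":
        return _read_tsv(path)
    try:
        if fmt == "graphml":
            raw = nx.read_graphml(path, force_multigraph=True)
        else:
            raw = nx.read_gexf(path)
    except Exception as exc:  # parse failures name the file and element
        raise ValueError(f"malformed {fmt} file {path}: {exc}") from exc
    kg = KnowledgeGraph(directed=True)
    for n, d in raw.nodes(data=True):
        attrs = _decode_attrs(d)
        extra = {
            k: v
            for k, v in attrs.items()
            if k not in _LIST_FIELDS and k not in _STR_FIELDS and k not in ("label", "id")
        }
        kg.add_node(ConceptNode.from_attrs(str(n), attrs), **extra)
    for u, v, d in raw.edges(data=True):
        pred = d.get("predicate", "")
        if not pred:
            raise ValueError(f"malformed {fmt} file {path}: edge {u}->{v} lacks a predicate")
        kg.add_edge(str(u), str(v), pred)
    return kg


def _nodes_sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".nodes.json")


def _write_tsv(graph: KnowledgeGraph, path: Path) -> Path:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tpredicate\n")
        for e in graph.edges():
            fh.write(f"{e.source_id}\t{e.target_id}\t{e.predicate}\n")
    nodes = {n: graph.nx.nodes[n] for n in graph.nx.nodes}
    with open(_nodes_sidecar(path), "w") as fh:
        json.dump(nodes, fh, indent=1, sort_keys=True)
    return path


def _read_tsv(path: Path) -> KnowledgeGraph:
    sidecar = _nodes_sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"node attribute sidecar {sidecar} not found")
    with open(sidecar) as fh:
        node_attrs = json.load(fh)
    kg = KnowledgeGraph(directed=True)
    for n, d in node_attrs.items():
        attrs = _decode_attrs(d)
        extra = {
            k: v
            for k, v in attrs.items()
            if k not in _LIST_FIELDS and k not in _STR_FIELDS
        }
        kg.add_node(ConceptNode.from_attrs(n, attrs), **extra)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.split("\t") != ["source", "target", "predicate"]:
            raise ValueError(f"malformed TSV {path}: line 1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed TSV {path}: line {lineno}: expected 3 columns")
            u, v, pred = parts
            for endpoint in (u, v):
                if not kg.has_node(endpoint):
                    raise ValueError(
                        f"malformed TSV {path}: line {lineno}: edge references "
                        f"unknown node {endpoint!r}"
                    )
            kg.add_edge(u, v, pred)
    return kg
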