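"""Synthetic multi-resource knowledge graphs with planted structure.

The generator emulates the two features of an integrated rare-disease
knowledge graph that the downstream pipeline depends on:

* the same concept appearing under several source resources, joined by
  equivalence predicates (``N_Name``, ``I_CODE``, ``R_equivalentClass``,
  ``R_exactMatch``) — this is what node contraction consumes;
* planted community structure (a planted-partition / stochastic-block layout
  over disease–gene–drug–phenotype concepts, with one deliberately
  high-degree hub per community) — this is what community detection and
  centrality ranking are validated against.

Everything is driven by a single :class:`numpy.random.Generator` seeded once
per call, so a given configuration is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .kg_model import EQUIVALENCE_PREDICATES, ConceptNode, KnowledgeGraph

__all__ = ["SynthConfig", "GroundTruth", "generate_kg", "generate_seed_cluster"]

# Domain predicate per unordered category pair; anything unlisted falls back
# to the generic relation.
_DOMAIN_PREDICATES = {
    frozenset({"disease", "gene"}): "R_associated_gene",
    frozenset({"disease", "drug"}): "R_indicated_for",
    frozenset({"gene", "drug"}): "R_drug_target",
    frozenset({"disease", "phenotype"}): "R_has_phenotype",
    frozenset({"disease"}): "R_related_disease",
}
_GENERIC_PREDICATE = "R_related"

_CATEGORY_PREFIX = {"disease": "DIS", "gene": "GENE", "drug": "DRUG", "phenotype": "HP"}


@dataclass
class SynthConfig:
    """Generator configuration.

    Defaults describe a 200-concept planted-partition graph with four
    communities (intra-community edge probability 0.3, inter 0.01), three
    source resources, and a 15% chance that a concept is re-emitted under an
    extra resource and tied to its original by an equivalence edge.
    """

    n_diseases: int = 80
    n_genes: int = 60
    n_drugs: int = 40
    n_phenotypes: int = 20
    n_resources: int = 3
    duplication_prob: float = 0.15
    n_communities: int = 4
    p_in: float = 0.3
    p_out: float = 0.01
    n_seed_diseases: int = 10
    seed: int = 0

    def validate(self) -> None:
        bad: list[str] = []
        counts = {
            "n_diseases": self.n_diseases,
            "n_genes": self.n_genes,
            "n_drugs": self.n_drugs,
            "n_phenotypes": self.n_phenotypes,
            "n_resources": self.n_resources,
            "n_communities": self.n_communities,
            "n_seed_diseases": self.n_seed_diseases,
        }
        for name, v in counts.items():
            if v < 1:
                bad.append(f"{name}={v} (must be >= 1)")
        for name in ("duplication_prob", "p_in", "p_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                bad.append(f"{name}={v} (must be in [0,1])")
        if self.p_in <= self.p_out:
            bad.append(f"p_in={self.p_in} must exceed p_out={self.p_out}")
        if self.n_seed_diseases > self.n_diseases:
            bad.append(
                f"n_seed_diseases={self.n_seed_diseases} exceeds n_diseases={self.n_diseases}"
            )
        if bad:
            raise ValueError("invalid SynthConfig: " + "; ".join(bad))

    @property
    def n_concepts(self) -> int:
        return self.n_diseases + self.n_genes + self.n_drugs + self.n_phenotypes

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What the generator planted, for use as a test oracle.

    ``hubs`` lists the one deliberately high-degree node per community (the
    expected top-ranked candidate); ``community_of`` covers every node,
    duplicates inheriting their original's community.
    """

    equivalence_components: list[set[str]] = field(default_factory=list)
    community_of: dict[str, int] = field(default_factory=dict)
    seed_cluster: list[str] = field(default_factory=list)
    hubs: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "equivalence_components": [sorted(c) for c in self.equivalence_components],
            "community_of": self.community_of,
            "seed_cluster": self.seed_cluster,
            "hubs": self.hubs,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            equivalence_components=[set(c) for c in d["equivalence_components"]],
            community_of=d["community_of"],
            seed_cluster=d["seed_cluster"],
            hubs=d.get("hubs", []),
        )


def _concept_nodes(config: SynthConfig) -> list[ConceptNode]:
    nodes = []
    for category, count in (
        ("disease", config.n_diseases),
        ("gene", config.n_genes),
        ("drug", config.n_drugs),
        ("phenotype", config.n_phenotypes),
    ):
        prefix = _CATEGORY_PREFIX[category]
        for i in range(count):
            label = f"{category.capitalize()} {prefix}{i:04d}"
            nodes.append(
                ConceptNode(
                    node_id=f"{prefix}:{i:04d}",
                    primary_label=label,
                    category=category,
                    source_resource="RES0",
                    synonyms=[f"{label} synonym A", f"{label} synonym B"],
                    external_codes=[f"XC:{prefix}{i:04d}"],
                )
            )
    return nodes


def _domain_predicate(cat_u: str, cat_v: str) -> str:
    return _DOMAIN_PREDICATES.get(frozenset({cat_u, cat_v}), _GENERIC_PREDICATE)


def generate_kg(config: SynthConfig) -> tuple[KnowledgeGraph, GroundTruth]:
    """Generate a synthetic knowledge graph and its planted ground truth.

    Concepts are split into near-equal communities; within a community each
    unordered pair is connected with probability ``p_in`` and across
    communities with ``p_out`` (edge orientation random).  One member per
    community is a planted hub connected to every other member.  Each concept
    is independently duplicated under a second resource with probability
    ``duplication_prob``; the duplicate copies the original's synonyms, takes
    one of them as its own primary label, gains one spurious alt-label, and is
    linked to the original by a uniformly chosen equivalence predicate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    kg = KnowledgeGraph(directed=True)
    truth = GroundTruth()

    concepts = _concept_nodes(config)
    for c in concepts:
        kg.add_node(c)

    # Community assignment: shuffle once, then split into near-equal chunks.
    ids = [c.node_id for c in concepts]
    order = rng.permutation(len(ids))
    chunks = np.array_split(order, config.n_communities)
    for comm, chunk in enumerate(chunks):
        for idx in chunk:
            truth.community_of[ids[idx]] = comm

    by_node = {c.node_id: c for c in concepts}
    members: dict[int, list[str]] = {c: [] for c in range(config.n_communities)}
    for nid in ids:  # stable insertion order
        members[truth.community_of[nid]].append(nid)

    def add_domain_edge(u: str, v: str) -> None:
        pred = _domain_predicate(by_node[u].category, by_node[v].category)
        if rng.random() < 0.5:
            u, v = v, u
        kg.add_edge(u, v, pred)

    # Planted hub per community: connected to every other member.
    planted: set[frozenset[str]] = set()
    for comm in range(config.n_communities):
        group = members[comm]
        hub = group[0]
        truth.hubs.append(hub)
        for other in group[1:]:
            add_domain_edge(hub, other)
            planted.add(frozenset({hub, other}))

    # Planted-partition edges over the remaining pairs.
    for i, u in enumerate(ids):
        for v in ids[i + 1 :]:
            if frozenset({u, v}) in planted:
                continue
            p = (
                config.p_in
                if truth.community_of[u] == truth.community_of[v]
                else config.p_out
            )
            if rng.random() < p:
                add_domain_edge(u, v)

    # Cross-resource duplicates joined by equivalence edges.
    eq_predicates = sorted(EQUIVALENCE_PREDICATES)
    for c in concepts:
        if rng.random() >= config.duplication_prob:
            continue
        res = int(rng.integers(1, config.n_resources)) if config.n_resources > 1 else 1
        dup_id = f"{c.node_id}@RES{res}"
        dup = ConceptNode(
            node_id=dup_id,
            primary_label=c.synonyms[0] if c.synonyms else f"{c.primary_label} (alt)",
            category=c.category,
            source_resource=f"RES{res}",
            synonyms=list(c.synonyms),
            alt_labels=[f"{c.primary_label} spurious variant"],
            external_codes=list(c.external_codes),
        )
        kg.add_node(dup)
        pred = eq_predicates[int(rng.integers(len(eq_predicates)))]
        if rng.random() < 0.5:
            kg.add_edge(c.node_id, dup_id, pred)
        else:
            kg.add_edge(dup_id, c.node_id, pred)
        truth.equivalence_components.append({c.node_id, dup_id})
        truth.community_of[dup_id] = truth.community_of[c.node_id]

    return kg, truth


def generate_seed_cluster(
    config: SynthConfig,
    truth: GroundTruth,
    path: str | Path | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Pick the seed disease cluster and optionally write it to ``path``.

    Diseases are drawn preferentially from planted community 0 (shuffled),
    topping up from the other communities only if community 0 runs out; this
    mirrors a disease cluster that is concentrated in one region of the graph.
    The file format is plain text, one node id per line.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    prefix = _CATEGORY_PREFIX["disease"]
    diseases = [
        n
        for n in truth.community_of
        if n.startswith(f"{prefix}:") and "@" not in n
    ]
    if config.n_seed_diseases > len(diseases):
        raise ValueError(
            f"n_seed_diseases={config.n_seed_diseases} exceeds available "
            f"diseases ({len(diseases)})"
        )
    preferred = sorted(d for d in diseases if truth.community_of[d] == 0)
    others = sorted(d for d in diseases if truth.community_of[d] != 0)
    preferred = [preferred[i] for i in rng.permutation(len(preferred))]
    others = [others[i] for i in rng.permutation(len(others))]
    pool = preferred + others
    seeds = pool[: config.n_seed_diseases]
    truth.seed_cluster = list(seeds)
    if path is not None:
        Path(path).write_text("".join(f"{s}\n" for s in seeds))
    return seeds


def study_scale_config(seed: int = 0) -> SynthConfig:
    """A larger configuration used by the worked analysis.

    700 concepts across 8 communities with a 92-disease seed cluster
    (mirroring a cluster of one target disease plus 91 related diseases),
    sparser than the default so that the contracted profile network has a
    realistic density for community detection.
    """
    return SynthConfig(
        n_diseases=300,
        n_genes=220,
        n_drugs=120,
        n_phenotypes=60,
        n_resources=4,
        duplication_prob=0.2,
        n_communities=8,
        p_in=0.15,
        p_out=0.005,
        n_seed_diseases=92,
        seed=seed,
    )
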