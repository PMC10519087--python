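"""TNCS candidate ranking.

Within each community, the top-k (default five) nodes per centrality measure
are identified, the measure's scores are min–max scaled to [0, 1], and each
node's Total Normalized Centrality Score (TNCS) is the sum of its five
normalized scores, so TNCS ranges over [0, 5].  A node that is the argmax of
every measure in its community attains exactly 5.

Two normalization scopes are provided:

* ``top5_union`` (default) — only the top-k raw scores of each measure are
  min–max scaled; nodes outside a measure's top-k contribute 0 for it;
* ``community_all`` — each measure is scaled over all nodes of the community.

When every raw score of a measure is identical, min–max scaling maps all of
them to 0 (a conservative floor, keeping TNCS a lower bound); the event is
logged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.preprocessing import minmax_scale

from .centrality import MEASURES
from .community import CommunityScore
from .kg_model import KnowledgeGraph

logger = logging.getLogger(__name__)

SCOPES = ("top5_union", "community_all")


@dataclass
class NormalizationConfig:
    scope: str = "top5_union"
    k: int = 5

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}, got {self.scope!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class TNCSRecord:
    node_id: str
    normalized: dict[str, float]
    tncs: float
    community: int

    def to_dict(self) -> dict:
        return {
            "node_id": self.node_id,
            **{m: self.normalized[m] for m in MEASURES},
            "tncs": self.tncs,
            "community": self.community,
        }


@dataclass
class CandidateReport:
    """Per-community candidate blocks, sorted by community score descending."""

    scope: str
    k: int
    communities: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(
            {"normalization_scope": self.scope, "k": self.k, "communities": self.communities},
            indent=1,
        ))
        return path

    def to_markdown(self, path: str | Path | None = None) -> str:
        lines = [
            "# Candidate report",
            "",
            f"Normalization scope: `{self.scope}` (top-{self.k} per measure)",
            "",
            "| Community | Modularity score | Candidate | TNCS |",
            "|---|---|---|---|",
        ]
        for block in self.communities:
            for cand in block["candidates"]:
                lines.append(
                    f"| {block['community']} | {block['community_score']:.4g} "
                    f"| {cand['description']} | {cand['tncs']:.3f} |"
                )
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def top_k_by_measure(table: pd.DataFrame, measure: str, k: int) -> list[str]:
    """The k nodes with the highest raw score for ``measure``.

    Ties break by node id ascending; if the table has fewer than k rows,
    all nodes are returned.
    """
    if table.empty:
        raise ValueError("centrality table is empty")
    if measure not in table.columns:
        raise KeyError(f"unknown measure {measure!r}")
    order = sorted(table.index, key=lambda n: (-table.at[n, measure], n))
    return order[:k]


def minmax_normalize(values: Sequence[float]) -> np.ndarray:
    """Min–max scale to [0, 1]; a constant list maps to all zeros."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot normalize an empty list")
    if arr.max() == arr.min():
        logger.info("degenerate min-max normalization (all values equal): mapped to 0")
        return np.zeros_like(arr)
    return minmax_scale(arr)


def normalize_table(table: pd.DataFrame, config: NormalizationConfig | None = None) -> pd.DataFrame:
    """Per-measure normalized scores under the configured scope.

    Under ``top5_union`` a node absent from a measure's top-k gets 0 for
    that measure.
    """
    config = config or NormalizationConfig()
    norm = pd.DataFrame(0.0, index=table.index, columns=list(MEASURES))
    for measure in MEASURES:
        if config.scope == "top5_union":
            top = top_k_by_measure(table, measure, config.k)
            norm.loc[top, measure] = minmax_normalize(table.loc[top, measure].to_numpy())
        else:
            norm[measure] = minmax_normalize(table[measure].to_numpy())
    return norm


def compute_tncs(
    normalized: pd.DataFrame, community_index: int
) -> list[TNCSRecord]:
    """TNCS per node (sum of the five normalized scores), sorted descending."""
    records = [
        TNCSRecord(
            node_id=str(n),
            normalized={m: float(normalized.at[n, m]) for m in MEASURES},
            tncs=float(normalized.loc[n, list(MEASURES)].sum()),
            community=community_index,
        )
        for n in normalized.index
    ]
    return sorted(records, key=lambda r: (-r.tncs, r.node_id))


def describe_node(graph: KnowledgeGraph, node_id: str) -> dict:
    """Legible description of a (possibly merged) node: labels + categories."""
    attrs = graph.nx.nodes[node_id]
    concept = graph.node(node_id)
    labels = [concept.primary_label, *concept.alt_labels]
    categories = (
        json.loads(attrs["categories"])
        if "categories" in attrs
        else [concept.category]
    )
    return {
        "node_id": node_id,
        "description": " + ".join(labels[:6]),
        "labels": labels,
        "categories": categories,
        "member_ids": json.loads(attrs["member_ids"]) if "member_ids" in attrs else [node_id],
    }


def rank_candidates(
    graph: KnowledgeGraph,
    ranked_communities: Sequence[CommunityScore],
    tables: dict[int, pd.DataFrame],
    config: NormalizationConfig | None = None,
) -> CandidateReport:
    """Build the per-community candidate report.

    ``tables`` maps community index to its raw centrality table.  For each
    ranked community the node(s) with the highest TNCS are flagged as
    candidates; each block also carries the per-measure top-k lists and
    node descriptions so merged disease/gene/drug bundles remain legible.
    """
    config = config or NormalizationConfig()
    if not ranked_communities:
        raise ValueError("need at least one ranked community")
    report = CandidateReport(scope=config.scope, k=config.k)
    for cs in ranked_communities:
        table = tables[cs.community]
        normalized = normalize_table(table, config)
        records = compute_tncs(normalized, cs.community)
        best = records[0].tncs
        candidates = [r for r in records if r.tncs == best]
        report.communities.append(
            {
                "community": cs.community,
                "community_score": cs.score,
                "n_nodes": cs.n_nodes,
                "candidates": [
                    {**describe_node(graph, r.node_id), "tncs": r.tncs}
                    for r in candidates
                ],
                "records": [
                    {**r.to_dict(), "description": describe_node(graph, r.node_id)["description"]}
                    for r in records
                ],
                "top_k_by_measure": {
                    m: top_k_by_measure(table, m, config.k) for m in MEASURES
                },
            }
        )
    return report
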