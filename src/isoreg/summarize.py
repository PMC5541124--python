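"""Offline downstream summaries: molecular-function breakdown and
interaction-network components.

Both operate on user-supplied files (an annotation table and a scored edge
list) rather than live PANTHER/STRING queries, whose results are database-
version-dependent and therefore not reproducible. A multi-category protein
contributes one hit per category, matching the hit-counting convention of
molecular-function breakdowns (percentages are hits / total hits x 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .psm_io import AnnotationRecord, NetworkEdge

__all__ = ["CategoryBreakdown", "NetworkSummary", "summarize_categories", "network_components"]


@dataclass(frozen=True)
class CategoryBreakdown:
    """Molecular-function hit counts over a protein set.

    ``recognized_proteins`` counts the input proteins present in the
    annotation; each contributes one hit per annotated category, so
    ``sum(hits.values()) == total_hits`` and percentages sum to 100 up to
    rounding.
    """

    total_proteins: int
    recognized_proteins: int
    total_hits: int
    hits: Mapping[str, int]
    percentages: Mapping[str, float]


@dataclass(frozen=True)
class NetworkSummary:
    """Connected components of the interaction subgraph on a protein set.

    Components are ordered by size descending, ties broken by the
    lexicographically smallest member; members are sorted within each
    component. Component sizes sum to ``n_nodes``.
    """

    n_nodes: int
    n_edges: int
    components: tuple[tuple[str, ...], ...]
    degree: Mapping[str, int]


def _annotation_map(annotation) -> Mapping[str, frozenset[str]]:
    if isinstance(annotation, Mapping):
        return {acc: frozenset(cats) for acc, cats in annotation.items()}
    return {rec.accession: rec.categories for rec in annotation}


def summarize_categories(
    accessions: Sequence[str],
    annotation: Iterable[AnnotationRecord] | Mapping[str, Iterable[str]],
) -> CategoryBreakdown:
    """Break a protein set down by molecular-function category.

    ``accessions`` may contain duplicates (e.g. verbatim table rows); they
    are counted once. Proteins absent from the annotation count toward
    ``total_proteins`` only. An empty accession list is an error.
    """
    unique = sorted(set(accessions))
    if not unique:
        raise ValueError("summarize_categories: empty accession list")
    mapping = _annotation_map(annotation)
    hits: dict[str, int] = {}
    recognized = 0
    for acc in unique:
        categories = mapping.get(acc)
        if not categories:
            continue
        recognized += 1
        for cat in sorted(categories):
            hits[cat] = hits.get(cat, 0) + 1
    total_hits = sum(hits.values())
    percentages = {cat: 100.0 * n / total_hits for cat, n in hits.items()} if total_hits else {}
    return CategoryBreakdown(
        total_proteins=len(unique), recognized_proteins=recognized,
        total_hits=total_hits, hits=dict(sorted(hits.items())),
        percentages=dict(sorted(percentages.items())),
    )


def network_components(
    accessions: Sequence[str],
    edges: Iterable[NetworkEdge],
    score_cutoff: float = 0.4,
) -> NetworkSummary:
    """Connected components of the induced interaction subgraph.

    Only edges with both endpoints in ``accessions`` and score >= the cutoff
    (default 0.4, a conventional medium-confidence interaction score) are
    kept; every input protein appears, isolated proteins as singleton
    components. Deterministic ordering throughout.
    """
    nodes = sorted(set(accessions))
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    node_set = set(nodes)
    for edge in edges:
        if (edge.score >= score_cutoff
                and edge.accession_a in node_set and edge.accession_b in node_set):
            graph.add_edge(edge.accession_a, edge.accession_b)
    components = [tuple(sorted(c)) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return NetworkSummary(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        components=tuple(components),
        degree={n: int(d) for n, d in sorted(graph.degree())},
    )
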