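"""Sequence similarity networks (SSNs) and subfamily calling.

Proteins are nodes; an edge joins two proteins whose all-vs-all search
E-value falls below a cutoff.  Within one family, connected clusters of at
least ten sequences are called subfamilies.  "Well-connected" is
operationalized as a connected component by default, with an optional
2-core refinement that discards tree-like fringes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import networkx as nx

MIN_SUBFAMILY_SIZE = 10
DEFAULT_CUTOFF = 1e-5


class EdgeParseError(ValueError):
    """Malformed pairwise search table."""


@dataclass(frozen=True)
class SimilarityEdge:
    """One undirected similarity edge (protein pair with best E-value)."""

    a: str
    b: str
    evalue: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self edge: {self.a}")
        if self.evalue < 0:
            raise ValueError(f"negative E-value: {self.evalue}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.a, self.b) if self.a <= self.b else (self.b, self.a)


@dataclass(frozen=True)
class Subfamily:
    """A called subfamily: >= min_size well-connected proteins of one family."""

    subfamily_id: str
    members: frozenset[str]
    contains_seed: bool = False


def load_edges(source: str | Path | IO[str] | Iterable[str]) -> list[SimilarityEdge]:
    """Read a tabular pairwise search output into a deduplicated edge list.

    Accepts either a minimal 3-column table (query, subject, evalue) or the
    standard 12-column tabular search dialect (E-value in column 11).
    Self-hits are dropped; duplicate unordered pairs collapse to the
    minimum E-value.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return load_edges(fh)
    best: dict[tuple[str, str], float] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) >= 12:
            query, subject, ev_str = fields[0], fields[1], fields[10]
        elif len(fields) >= 3:
            query, subject, ev_str = fields[0], fields[1], fields[2]
        else:
            raise EdgeParseError(f"line {lineno}: expected >= 3 columns")
        try:
            evalue = float(ev_str)
        except ValueError as exc:
            raise EdgeParseError(f"line {lineno}: bad E-value {ev_str!r}") from exc
        if evalue < 0:
            raise EdgeParseError(f"line {lineno}: negative E-value {evalue}")
        if query == subject:
            continue
        pair = (query, subject) if query <= subject else (subject, query)
        if pair not in best or evalue < best[pair]:
            best[pair] = evalue
    return [SimilarityEdge(a, b, e) for (a, b), e in sorted(best.items())]


def threshold_network(edges: Sequence[SimilarityEdge], cutoff: float = DEFAULT_CUTOFF) -> nx.Graph:
    """Build a graph over all proteins, keeping edges with E-value < cutoff.

    Every protein appearing in *edges* becomes a node even when all its
    edges are filtered out.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    graph = nx.Graph()
    for edge in edges:
        graph.add_node(edge.a)
        graph.add_node(edge.b)
        if edge.evalue < cutoff:
            graph.add_edge(edge.a, edge.b, evalue=edge.evalue)
    return graph


def call_subfamilies(
    graph: nx.Graph,
    family_id: str,
    min_size: int = MIN_SUBFAMILY_SIZE,
    mode: str = "component",
    seed_ids: Iterable[str] = (),
) -> list[Subfamily]:
    """Call subfamilies as large connected clusters of one family's network.

    ``component`` mode keeps connected components with >= *min_size* nodes;
    ``kcore`` mode first restricts to the 2-core, discarding nodes that hang
    off clusters by a single edge.  Subfamilies are numbered from 1 by
    decreasing size, ties broken by lexicographically smallest member, so
    numbering is invariant to node insertion order.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if mode not in ("component", "kcore"):
        raise ValueError(f"mode must be 'component' or 'kcore': {mode!r}")
    seeds = set(seed_ids)
    work = nx.k_core(graph, 2) if mode == "kcore" else graph
    clusters = [set(c) for c in nx.connected_components(work) if len(c) >= min_size]
    clusters.sort(key=lambda c: (-len(c), min(c)))
    return [
        Subfamily(
            subfamily_id=f"{family_id}_{i}",
            members=frozenset(cluster),
            contains_seed=bool(cluster & seeds),
        )
        for i, cluster in enumerate(clusters, start=1)
    ]


def export_network(
    graph: nx.Graph,
    subfamilies: Sequence[Subfamily],
    path: str | Path,
    format: str = "graphml",
    seed_ids: Iterable[str] = (),
    taxonomy: dict[str, str] | None = None,
) -> None:
    """Write the network with subfamily/seed/taxonomy node attributes.

    ``graphml`` produces a file loadable by Cytoscape and similar viewers;
    ``edge_tsv`` writes (query, subject, evalue) rows that round-trip
    through :func:`load_edges`.
    """
    if format not in ("graphml", "edge_tsv"):
        raise ValueError(f"format must be 'graphml' or 'edge_tsv': {format!r}")
    if format == "edge_tsv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for a, b, data in sorted(graph.edges(data=True)):
                writer.writerow([a, b, f"{data.get('evalue', 0.0):.6g}"])
        return
    membership = {m: sf.subfamily_id for sf in subfamilies for m in sf.members}
    seeds = set(seed_ids)
    export = graph.copy()
    for node in export.nodes:
        export.nodes[node]["subfamily_id"] = membership.get(node, "unclassified")
        export.nodes[node]["is_seed"] = node in seeds
        if taxonomy and node in taxonomy:
            export.nodes[node]["taxonomy"] = taxonomy[node]
    nx.write_graphml(export, path)
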