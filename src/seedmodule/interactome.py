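"""The consolidated interactome: a simple undirected graph with provenance.

An :class:`Interactome` merges binary gene/protein interactions from one or
more source databases into a single simple undirected graph. Self-loops are
dropped and parallel edges collapsed at ingestion time; each surviving edge
remembers the set of source-database labels that reported it, so the
provenance of a consolidated edge is never lost.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx

from .identifiers import normalize_symbol


class Interactome:
    """Simple undirected interaction graph over normalized gene symbols.

    The underlying container is a :class:`networkx.Graph`; every edge
    carries a ``sources`` attribute holding a set of source-database
    labels. Nodes are normalized gene symbols.
    """

    def __init__(self, graph: nx.Graph | None = None, name: str = "interactome"):
        self.graph = graph if graph is not None else nx.Graph()
        self.name = name

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        source_label: str,
        name: str = "interactome",
    ) -> "Interactome":
        """Build an interactome from raw symbol pairs under one source label.

        Symbols are normalized; self-loops are silently dropped and
        duplicate pairs merged (use :func:`seedmodule.io.read_edge_list`
        when the drop/merge counts matter).
        """
        inter = cls(name=name)
        for a, b in edges:
            inter.add_edge(normalize_symbol(a), normalize_symbol(b), source_label)
        return inter

    def add_edge(self, u: str, v: str, source_label: str) -> bool:
        """Add one undirected edge with provenance; returns False for self-loops.

        ``u`` and ``v`` must already be normalized. Adding an existing edge
        merges the source label into the edge's provenance set.
        """
        if u == v:
            return False
        if self.graph.has_edge(u, v):
            self.graph.edges[u, v]["sources"].add(source_label)
        else:
            self.graph.add_edge(u, v, sources={source_label})
        return True

    # -- accessors ---------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_sources(self, u: str, v: str) -> set[str]:
        return set(self.graph.edges[u, v]["sources"])

    def edge_set(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def degree(self, v: str) -> int:
        return self.graph.degree[v]

    def validate(self) -> None:
        """Assert the structural invariants; raises ValueError on violation."""
        for v in self.graph.nodes:
            if normalize_symbol(v) != v:
                raise ValueError(f"non-normalized node symbol: {v!r}")
        for u, v, data in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop on {u}")
            if not data.get("sources"):
                raise ValueError(f"edge {u}-{v} has no source label")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        if self.nodes != other.nodes or self.edge_set() != other.edge_set():
            return False
        return all(
            self.edge_sources(u, v) == other.edge_sources(u, v)
            for u, v in self.graph.edges
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Interactome({self.name!r}, n={self.n_nodes}, m={self.n_edges})"


def consolidate(interactomes: list[Interactome], name: str = "CI") -> Interactome:
    """Merge interactomes into one consolidated interactome (CI).

    Node and edge sets are unioned and per-edge source labels merged, so
    the operation is commutative, associative and idempotent. Raises
    ValueError on an empty input list.
    """
    if not interactomes:
        raise ValueError("consolidate() requires at least one interactome")
    merged = Interactome(name=name)
    for inter in interactomes:
        merged.graph.add_nodes_from(inter.graph.nodes)
        for u, v, data in inter.graph.edges(data=True):
            for label in data["sources"]:
                merged.add_edge(u, v, label)
    return merged
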