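"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from seedmodule import Interactome, SeedSet


def make_interactome(edges, source="test", extra_nodes=()):
    """Interactome from raw (already meaningful) symbol pairs."""
    inter = Interactome.from_edges(edges, source)
    inter.graph.add_nodes_from(extra_nodes)
    return inter


def random_interactome(n, p, seed, source="rand"):
    """G(n, p) interactome over letters/G-codes with a fixed RNG seed."""
    g = nx.gnp_random_graph(n, p, seed=seed)
    inter = Interactome(name=source)
    inter.graph.add_nodes_from(f"N{i:03d}" for i in range(n))
    for u, v in g.edges:
        inter.add_edge(f"N{u:03d}", f"N{v:03d}", source)
    return inter


def seed_set(genes, name="seeds"):
    return SeedSet(name, set(genes))


def all_graphs_on(n):
    """Every labelled simple graph on n nodes (as edge tuples)."""
    nodes = [f"N{i}" for i in range(n)]
    pairs = list(itertools.combinations(nodes, 2))
    for bits in itertools.product((0, 1), repeat=len(pairs)):
        yield nodes, [p for p, b in zip(pairs, bits) if b]


@pytest.fixture
def toy_interactome():
    """A small two-cluster interactome with one bridge node."""
    edges = [
        ("A", "B"), ("B", "C"), ("C", "A"),        # triangle
        ("C", "H"), ("H", "D"),                    # bridge H
        ("D", "E"), ("E", "F"), ("F", "D"),        # second triangle
        ("X", "Y"),                                # separate component
    ]
    return make_interactome(edges)
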