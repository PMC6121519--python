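"""Seed-gene disease-network construction by LCC extraction and expansion.

The procedure mirrors the standard network-medicine recipe for building a
disease module from curated seed genes:

1. map the seed genes onto the consolidated interactome;
2. take the largest connected component (LCC) of the subgraph induced on
   the mapped seeds as the anchor;
3. iteratively recruit first-degree interactors (connectors) from the
   interactome that reconnect otherwise disconnected seed genes, until
   every reachable seed has been folded in.

Step 3 is a deterministic greedy: at each iteration every interactome node
adjacent to the current network is scored by how many disconnected seeds it
would reconnect (a disconnected seed that is itself adjacent to the network
is a candidate and counts itself); the best candidate is added, ties broken
by higher interactome degree, then lexicographically. When no candidate
reconnects a seed outright, the expansion grows one hop along a shortest
path toward a disconnected seed (so connector chains are permitted), but
only while each added node strictly reduces the interactome distance from
the network to some disconnected seed. Seeds in a different interactome
component — or beyond the optional chain-length bound — are reported as
excluded, never silently dropped. The whole construction is deterministic:
no randomness, all order dependence removed by sorting.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import networkx as nx

from .interactome import Interactome
from .genesets import SeedSet


class NoSeedMappedError(ValueError):
    """No seed gene could be found in the interactome."""


@dataclass
class ExpandedNetwork:
    """A connected seed network with per-node provenance.

    Node attributes on ``graph``: ``is_seed`` (bool) and ``addition_rank``
    (0 for members of the initial seed LCC; k >= 1 for the k-th connector
    and for any seeds it reconnected, which share its rank). Edges are
    exactly the interactome-induced edges on the node set. Seeds that could
    not be connected are listed in ``excluded_seeds``.
    """

    graph: nx.Graph
    excluded_seeds: set[str] = field(default_factory=set)
    source_interactome_id: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def seeds(self) -> set[str]:
        return {v for v, d in self.graph.nodes(data=True) if d.get("is_seed")}

    @property
    def connectors(self) -> set[str]:
        return {v for v, d in self.graph.nodes(data=True) if not d.get("is_seed")}

    def rank_of(self, v: str) -> int:
        return int(self.graph.nodes[v]["addition_rank"])

    def is_connected(self) -> bool:
        return self.graph.number_of_nodes() > 0 and nx.is_connected(self.graph)

    def validate(self, interactome: Interactome | None = None) -> None:
        """Check the structural invariants; raises ValueError on violation."""
        if not self.is_connected():
            raise ValueError("expanded network is not connected")
        for v, data in self.graph.nodes(data=True):
            rank = int(data["addition_rank"])
            if not data.get("is_seed") and rank < 1:
                raise ValueError(f"non-seed {v} has addition_rank {rank}")
            if rank >= 1 and not data.get("is_seed"):
                # connectors must attach to strictly earlier material
                if not any(self.rank_of(u) < rank for u in self.graph.neighbors(v)):
                    raise ValueError(f"connector {v} not adjacent to a lower rank")
        if self.excluded_seeds & self.nodes:
            raise ValueError("excluded seed appears in the network")
        if interactome is not None:
            induced = {frozenset(e)
                       for e in interactome.graph.subgraph(self.nodes).edges}
            actual = {frozenset(e) for e in self.graph.edges}
            if induced != actual:
                raise ValueError("edges are not the interactome-induced edges")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpandedNetwork):
            return NotImplemented
        if self.nodes != other.nodes:
            return False
        if {frozenset(e) for e in self.graph.edges} != {
            frozenset(e) for e in other.graph.edges
        }:
            return False
        for v in self.graph.nodes:
            a, b = self.graph.nodes[v], other.graph.nodes[v]
            if bool(a.get("is_seed")) != bool(b.get("is_seed")):
                return False
            if int(a["addition_rank"]) != int(b["addition_rank"]):
                return False
        return self.excluded_seeds == other.excluded_seeds


def map_seeds(interactome: Interactome, seeds: SeedSet) -> tuple[set[str], set[str]]:
    """Split a seed set into interactome-present and absent symbols.

    The absent symbols are recorded on ``seeds.unmapped``. Raises
    :class:`NoSeedMappedError` when nothing maps.
    """
    if not seeds.genes:
        raise ValueError("empty seed set")
    present = seeds.genes & interactome.nodes
    absent = seeds.genes - present
    seeds.unmapped = set(absent)
    if not present:
        raise NoSeedMappedError(
            f"no gene of seed set {seeds.name!r} maps into the interactome"
        )
    return present, absent


def seed_lcc(interactome: Interactome, present_seeds: set[str]) -> set[str]:
    """Largest connected component of the seed-induced subgraph.

    Ties on node count are broken by (a) larger induced edge count, then
    (b) lexicographically smallest sorted node list, so the anchor is
    deterministic.
    """
    if not present_seeds:
        raise ValueError("present_seeds is empty")
    missing = present_seeds - interactome.nodes
    if missing:
        raise ValueError(f"seeds not in interactome: {sorted(missing)[:5]}")
    sub = interactome.graph.subgraph(present_seeds)
    components = [set(c) for c in nx.connected_components(sub)]
    best_size = max(len(c) for c in components)
    components = [c for c in components if len(c) == best_size]
    if len(components) > 1:
        edge_counts = [sub.subgraph(c).number_of_edges() for c in components]
        best_edges = max(edge_counts)
        components = [c for c, m in zip(components, edge_counts) if m == best_edges]
    return min(components, key=lambda c: sorted(c))


def expand_network(
    interactome: Interactome,
    seeds: SeedSet,
    max_chain: int | None = None,
) -> ExpandedNetwork:
    """Build the expanded seed network (anchor LCC + greedy connectors).

    ``max_chain`` bounds the number of consecutive connectors the expansion
    may spend reaching one disconnected seed (None = unbounded, purely
    distance-guided). Returns a connected :class:`ExpandedNetwork`; seeds
    that cannot be reached end up in ``excluded_seeds``.
    """
    present, _absent = map_seeds(interactome, seeds)
    adj = interactome.graph.adj

    current = set(seed_lcc(interactome, present))
    ranks = {v: 0 for v in current}
    disconnected = set(present) - current
    rank = 0

    def recruit(k: int) -> None:
        # fold in every disconnected seed now touching the network (cascade)
        while True:
            reachable = {d for d in disconnected
                         if any(nb in current for nb in adj[d])}
            if not reachable:
                return
            for d in sorted(reachable):
                current.add(d)
                ranks[d] = k
                disconnected.discard(d)

    while disconnected:
        candidates = sorted(
            {nb for c in current for nb in adj[c]} - current
        )
        if not candidates:
            break

        # primary: how many disconnected seeds does the candidate reconnect
        score = {
            v: sum(1 for d in disconnected if d in adj[v]) + (1 if v in disconnected else 0)
            for v in candidates
        }
        best_score = max(score.values())
        if best_score >= 1:
            chosen = min(
                candidates,
                key=lambda v: (-score[v], -interactome.degree(v), v),
            )
        else:
            # distance-guided: grow only toward seeds whose interactome
            # distance to the network strictly decreases
            dist_from = {d: nx.single_source_shortest_path_length(interactome.graph, d)
                         for d in disconnected}
            dist_to_net = {
                d: min((dl[c] for c in current if c in dl), default=None)
                for d, dl in dist_from.items()
            }
            reductions: dict[str, int] = {}
            for v in candidates:
                n_reduced = 0
                for d in sorted(disconnected):
                    base = dist_to_net[d]
                    if base is None:
                        continue  # different component: unreachable
                    if max_chain is not None and base - 1 > max_chain:
                        continue  # chain toward d would exceed the bound
                    dv = dist_from[d].get(v)
                    # after adding v the network-to-d distance becomes dv
                    if dv is not None and dv < base:
                        n_reduced += 1
                if n_reduced:
                    reductions[v] = n_reduced
            if not reductions:
                break
            chosen = min(
                reductions,
                key=lambda v: (-reductions[v], -interactome.degree(v), v),
            )

        rank += 1
        current.add(chosen)
        ranks[chosen] = rank
        disconnected.discard(chosen)
        recruit(rank)

    graph = nx.Graph()
    for v in sorted(current):
        graph.add_node(v, is_seed=(v in present), addition_rank=ranks[v])
    graph.add_edges_from(
        tuple(sorted(e)) for e in interactome.graph.subgraph(current).edges
    )
    return ExpandedNetwork(
        graph=graph,
        excluded_seeds=set(disconnected),
        source_interactome_id=interactome.name,
    )


def network_stats(network: ExpandedNetwork) -> dict:
    """Headline counts for a seed network (genes, interactions, seeds...)."""
    degrees = [d for _, d in network.graph.degree]
    return {
        "n_genes": network.graph.number_of_nodes(),
        "n_interactions": network.graph.number_of_edges(),
        "n_seeds": len(network.seeds),
        "n_connectors": len(network.connectors),
        "n_excluded_seeds": len(network.excluded_seeds),
        "degree_min": min(degrees) if degrees else 0,
        "degree_max": max(degrees) if degrees else 0,
        "degree_mean": float(statistics.fmean(degrees)) if degrees else 0.0,
        "degree_median": float(statistics.median(degrees)) if degrees else 0.0,
    }
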