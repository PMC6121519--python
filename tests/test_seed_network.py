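"""Seed mapping, LCC extraction, greedy expansion and their invariants."""

import itertools
import random

import networkx as nx
import pytest

from seedmodule import (
    ModuleSpec,
    NoSeedMappedError,
    SyntheticSpec,
    expand_network,
    generate,
    map_seeds,
    network_stats,
    score_recovery,
    seed_lcc,
    seed_overlap_report,
)
from seedmodule.io import write_network

from conftest import make_interactome, random_interactome, seed_set


# ------------------------------------------------------------ test oracles


def union_find_lcc(edge_pairs, nodes):
    """Brute-force largest component via union-find (independent oracle).

    Applies the same tie-breaks as the contract: size, then edge count,
    then lexicographically smallest sorted node list.
    """
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in edge_pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for v in nodes:
        comps.setdefault(find(v), set()).add(v)
    comps = list(comps.values())

    def edge_count(c):
        return sum(1 for a, b in edge_pairs if a in c and b in c)

    best = max(len(c) for c in comps)
    comps = [c for c in comps if len(c) == best]
    best_m = max(edge_count(c) for c in comps)
    comps = [c for c in comps if edge_count(c) == best_m]
    return min(comps, key=sorted)


def reachable_from(adj, start_set):
    """Plain BFS reachability oracle over an adjacency dict."""
    seen = set(start_set)
    frontier = list(start_set)
    while frontier:
        v = frontier.pop()
        for w in adj[v]:
            if w not in seen:
                seen.add(w)
                frontier.append(w)
    return seen


# -------------------------------------------------------------- map_seeds


def test_map_seeds_partitions_present_and_absent(toy_interactome):
    seeds = seed_set({"A", "C", "Z"})
    present, absent = map_seeds(toy_interactome, seeds)
    assert present == {"A", "C"} and absent == {"Z"}
    assert seeds.unmapped == {"Z"}


def test_map_seeds_all_present(toy_interactome):
    present, absent = map_seeds(toy_interactome, seed_set({"A", "B"}))
    assert absent == set() and present == {"A", "B"}


def test_map_seeds_none_present_raises(toy_interactome):
    with pytest.raises(NoSeedMappedError):
        map_seeds(toy_interactome, seed_set({"Q1", "Q2"}))


def test_map_seeds_random_matches_set_algebra():
    inter = random_interactome(200, 0.02, seed=9)
    rng = random.Random(9)
    real = set(rng.sample(sorted(inter.nodes), 20))
    fake = {f"FAKE{i}" for i in range(10)}
    seeds = seed_set(real | fake)
    present, absent = map_seeds(inter, seeds)
    assert present == real and absent == fake
    assert len(present) + len(absent) == len(seeds.genes)


# --------------------------------------------------------------- seed_lcc


def test_seed_lcc_singleton_tie_break():
    inter = make_interactome([("A", "B"), ("B", "C")])
    assert seed_lcc(inter, {"A", "C"}) == {"A"}


def test_seed_lcc_triangle():
    inter = make_interactome([("A", "B"), ("B", "C"), ("C", "A")])
    assert seed_lcc(inter, {"A", "B", "C"}) == {"A", "B", "C"}


def test_seed_lcc_edge_count_tie_break():
    # two 3-node components, same size; {D,E,F} is a triangle (3 edges)
    inter = make_interactome(
        [("A", "B"), ("B", "C"), ("D", "E"), ("E", "F"), ("F", "D")])
    assert seed_lcc(inter, {"A", "B", "C", "D", "E", "F"}) == {"D", "E", "F"}


def test_seed_lcc_empty_raises(toy_interactome):
    with pytest.raises(ValueError):
        seed_lcc(toy_interactome, set())


def test_seed_lcc_matches_union_find_oracle():
    inter = random_interactome(40, 0.08, seed=7)
    rng = random.Random(7)
    seeds = set(rng.sample(sorted(inter.nodes), 15))
    induced = [tuple(sorted(e)) for e in inter.graph.subgraph(seeds).edges]
    assert seed_lcc(inter, seeds) == union_find_lcc(induced, seeds)


# ---------------------------------------------------------- expand_network


def test_expand_star_forces_unique_connector():
    inter = make_interactome([("H", "S1"), ("H", "S2"), ("H", "S3")])
    net = expand_network(inter, seed_set({"S1", "S2", "S3"}))
    assert net.nodes == {"H", "S1", "S2", "S3"}
    assert net.graph.number_of_edges() == 3
    assert net.excluded_seeds == set()
    assert net.rank_of("S1") == 0          # lexicographic anchor tie-break
    assert net.rank_of("H") == 1
    assert net.rank_of("S2") == 1 and net.rank_of("S3") == 1
    assert not net.graph.nodes["H"]["is_seed"]


def test_expand_connected_seeds_is_identity():
    inter = make_interactome([("A", "B"), ("B", "C"), ("C", "D"), ("D", "X")])
    net = expand_network(inter, seed_set({"A", "B", "C"}))
    assert net.nodes == {"A", "B", "C"}
    assert all(net.rank_of(v) == 0 for v in net.nodes)
    assert net.connectors == set()


def test_expand_excludes_seed_in_other_component(toy_interactome):
    net = expand_network(toy_interactome, seed_set({"A", "B", "X"}))
    assert net.excluded_seeds == {"X"}
    assert net.is_connected()
    assert "X" not in net.nodes


def test_expand_follows_connector_chain():
    # seeds two hops apart: expansion must chain through u and w
    inter = make_interactome([("S1", "U"), ("U", "W"), ("W", "S2")])
    net = expand_network(inter, seed_set({"S1", "S2"}))
    assert net.nodes == {"S1", "U", "W", "S2"}
    assert net.excluded_seeds == set()
    ranks = [net.rank_of(v) for v in ("U", "W")]
    assert sorted(ranks) == [1, 2]


def test_expand_max_chain_bound_excludes_distant_seed():
    inter = make_interactome([("S1", "U"), ("U", "W"), ("W", "S2")])
    net = expand_network(inter, seed_set({"S1", "S2"}), max_chain=1)
    assert net.excluded_seeds == {"S2"}
    assert net.nodes == {"S1"}
    unbounded = expand_network(inter, seed_set({"S1", "S2"}), max_chain=2)
    assert unbounded.excluded_seeds == set()


def _two_module_instance(rng_seed=11):
    """Two dense modules joined through dedicated bridge nodes."""
    rng = random.Random(rng_seed)
    mod_a = [f"A{i}" for i in range(10)]
    mod_b = [f"B{i}" for i in range(10)]
    edges = []
    for mod in (mod_a, mod_b):
        for x, y in itertools.combinations(mod, 2):
            if rng.random() < 0.8:
                edges.append((x, y))
    edges += [("A0", "ZC1"), ("ZC1", "B0"), ("A1", "ZC2"), ("ZC2", "B1")]
    inter = make_interactome(edges)
    seeds = set(rng.sample(mod_a, 6)) | set(rng.sample(mod_b, 6))
    return inter, seed_set(seeds)


def exhaustive_min_connectors(inter, seeds, max_extra=3):
    """Smallest number of non-seed nodes whose addition connects all seeds."""
    present = seeds.genes & inter.nodes
    non_seeds = sorted(inter.nodes - present)
    for k in range(0, max_extra + 1):
        for extra in itertools.combinations(non_seeds, k):
            sub = inter.graph.subgraph(present | set(extra))
            comps = list(nx.connected_components(sub))
            if any(present <= c for c in comps):
                return k
    return None


def test_expand_two_bridged_modules_matches_minimal_connector_oracle():
    inter, seeds = _two_module_instance(rng_seed=11)
    net = expand_network(inter, seeds)
    assert net.excluded_seeds == set()
    assert seeds.genes <= net.nodes
    minimum = exhaustive_min_connectors(inter, seeds)
    assert minimum is not None
    assert len(net.connectors) == minimum


# ------------------------------------------------- invariants & properties


def _random_instances(n_instances, seed=0):
    rng = random.Random(seed)
    for i in range(n_instances):
        n = rng.randint(8, 40)
        p = rng.uniform(0.03, 0.25)
        inter = random_interactome(n, p, seed=seed * 1000 + i)
        k = rng.randint(2, max(2, n // 3))
        seeds = seed_set(rng.sample(sorted(inter.nodes), k))
        yield inter, seeds


@pytest.mark.parametrize("case", range(25))
def test_expansion_invariants_on_random_instances(case):
    inter, seeds = next(itertools.islice(_random_instances(25, seed=case), case, None))
    net = expand_network(inter, seeds)
    net.validate(interactome=inter)
    # excluded seeds are exactly those in another component than the anchor
    present = seeds.genes & inter.nodes
    anchor = seed_lcc(inter, present)
    reachable = reachable_from(inter.graph.adj, anchor)
    assert net.excluded_seeds == present - reachable


def test_expansion_idempotence_and_determinism(tmp_path):
    inter = random_interactome(60, 0.06, seed=13)
    seeds = seed_set(sorted(inter.nodes)[::5])
    net1 = expand_network(inter, seeds)
    net2 = expand_network(inter, seeds)
    assert net1 == net2
    p1, p2 = tmp_path / "a.graphml", tmp_path / "b.graphml"
    write_network(net1, p1)
    write_network(net2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    # re-expanding the result's node set as seeds adds nothing
    re_net = expand_network(inter, seed_set(net1.nodes))
    assert re_net.nodes == net1.nodes
    assert re_net.connectors == set()


def test_expansion_small_graph_oracle_equivalence():
    """On every 4-node graph and seed subset, connected vs excluded seeds
    agree with brute-force reachability from the anchor component."""
    from conftest import all_graphs_on

    for nodes, edges in all_graphs_on(4):
        inter = make_interactome(edges, extra_nodes=nodes)
        for r in range(1, 5):
            for subset in itertools.combinations(nodes, r):
                seeds = seed_set(set(subset))
                net = expand_network(inter, seeds)
                net.validate(interactome=inter)
                anchor = seed_lcc(inter, set(subset))
                reachable = reachable_from(inter.graph.adj, anchor)
                assert net.excluded_seeds == set(subset) - reachable
                assert (set(subset) & net.nodes) == set(subset) & reachable


def test_last_connector_is_necessary():
    """Removing the last-added connector disconnects a seed of >= its rank."""
    for case in (3, 5, 8, 12):
        inter, seeds = next(_random_instances(1, seed=case))
        net = expand_network(inter, seeds)
        connectors = net.connectors
        if not connectors:
            continue
        last = max(connectors, key=net.rank_of)
        pruned = net.graph.copy()
        pruned.remove_node(last)
        anchor = {v for v in net.nodes if net.rank_of(v) == 0}
        comps = list(nx.connected_components(pruned))
        anchor_comp = next(c for c in comps if anchor <= c)
        late_seeds = {v for v in net.seeds if net.rank_of(v) >= net.rank_of(last)}
        assert late_seeds - anchor_comp, "last connector was redundant"


def test_planted_module_recovery_in_fragmented_regime():
    """With a sparse-enough planted module the observed seeds fragment and
    the connectors recruited to rejoin them are enriched in hidden module
    members far beyond a uniform draw."""
    recalls, chances = [], []
    for rng_seed in range(10):
        spec = SyntheticSpec(
            rng_seed=rng_seed,
            modules=[ModuleSpec(20, 0.35, 3)],
        )
        ds = generate(spec)
        net = expand_network(ds.interactome, ds.seed_sets[0])
        assert net.excluded_seeds == set()
        _, recall = score_recovery(ds.truth, net)
        pool = len(ds.interactome.nodes) - len(ds.seed_sets[0].genes)
        chances.append(len(net.connectors) / pool)
        recalls.append(recall)
    mean_recall = sum(recalls) / len(recalls)
    mean_chance = sum(chances) / len(chances)
    assert mean_recall >= 5 * mean_chance
    assert mean_recall > 0


# ------------------------------------------------------------------- stats


def test_network_stats_star():
    inter = make_interactome([("H", "S1"), ("H", "S2"), ("H", "S3")])
    net = expand_network(inter, seed_set({"S1", "S2", "S3"}))
    stats = network_stats(net)
    assert stats["n_genes"] == 4 and stats["n_interactions"] == 3
    assert stats["n_seeds"] == 3 and stats["n_connectors"] == 1
    assert stats["n_excluded_seeds"] == 0
    assert stats["degree_max"] == 3


def test_network_stats_no_connectors():
    inter = make_interactome([("A", "B")])
    net = expand_network(inter, seed_set({"A", "B"}))
    assert network_stats(net)["n_connectors"] == 0


def test_network_stats_matches_recount():
    inter = random_interactome(50, 0.08, seed=21)
    net = expand_network(inter, seed_set(sorted(inter.nodes)[::6]))
    stats = network_stats(net)
    assert stats["n_genes"] == len(net.graph.nodes)
    assert stats["n_interactions"] == len(net.graph.edges)
    assert stats["n_seeds"] + stats["n_connectors"] == stats["n_genes"]


# --------------------------------------------------------- overlap report


def test_seed_overlap_report_examples():
    a = seed_set({"A", "B", "C"}, name="a")
    b = seed_set({"B", "C", "D"}, name="b")
    assert seed_overlap_report(a, b) == (3, 3, 2)
    assert seed_overlap_report(a, a) == (3, 3, 3)


def test_seed_overlap_report_forced_overlap():
    rng = random.Random(37)
    pool = [f"G{i:04d}" for i in range(500)]
    common = set(rng.sample(pool, 37))
    rest = [g for g in pool if g not in common]
    a = seed_set(common | set(rng.sample(rest, 63)), name="a")
    b = seed_set(common | set(rng.sample(sorted(set(rest) - a.genes), 63)), name="b")
    assert seed_overlap_report(a, b) == (100, 100, 37)
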