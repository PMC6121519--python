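"""Synthetic interactomes with planted disease modules and enriched gene sets.

The generator emulates the statistical setting the seed-network workflow
assumes: a sparse background interactome with a heavy-tailed degree
distribution (preferential attachment; Erdős–Rényi as an alternative),
one or more planted densely connected modules attached to the background by
bridge edges, partial observation of each module's members as seed genes,
a split of the edge set across several source files (so consolidation can
be exercised), and a GMT collection in which one set is enriched in a
planted module while the decoy sets are uniform draws.

Everything is driven by a single mandatory RNG seed; the same spec and seed
reproduce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .interactome import Interactome
from .genesets import GeneSetCollection, SeedSet
from .expansion import ExpandedNetwork


@dataclass
class ModuleSpec:
    size: int
    within_density: float
    n_bridges: int


@dataclass
class GmtSpec:
    n_sets: int = 20
    set_size_range: tuple[int, int] = (10, 40)
    planted_overlap_fraction: float = 0.8


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic benchmark instance.

    Defaults are the package's reference benchmark conditions: a 300-node
    preferential-attachment background (m = 2), one planted module of 20
    genes with within-module density 0.8 attached by 3 bridges, half of the
    module observed as seeds, edges split over 3 source files, and a GMT of
    20 decoy sets plus one set overlapping the module at fraction 0.8.
    """

    rng_seed: int
    n_background: int = 300
    backbone: str = "preferential_attachment"
    backbone_param: float = 2
    modules: list[ModuleSpec] = field(
        default_factory=lambda: [ModuleSpec(20, 0.8, 3)])
    seed_observation_rate: float = 0.5
    n_sources: int = 3
    gmt: GmtSpec = field(default_factory=GmtSpec)

    def validate(self) -> None:
        errors = []
        if self.n_background < 2:
            errors.append("n_background must be >= 2")
        if self.backbone not in ("preferential_attachment", "er"):
            errors.append(f"unknown backbone {self.backbone!r}")
        if not 0 < self.seed_observation_rate <= 1:
            errors.append("seed_observation_rate must be in (0, 1]")
        if self.n_sources < 1:
            errors.append("n_sources must be >= 1")
        for i, mod in enumerate(self.modules):
            if mod.size < 2:
                errors.append(f"module {i}: size must be >= 2")
            if not 0 < mod.within_density <= 1:
                errors.append(f"module {i}: within_density must be in (0, 1]")
            if mod.n_bridges < 1:
                errors.append(f"module {i}: n_bridges must be >= 1")
            if mod.n_bridges > mod.size * self.n_background:
                errors.append(f"module {i}: more bridges than available pairs")
        if self.gmt.n_sets < 1:
            errors.append("gmt.n_sets must be >= 1")
        lo, hi = self.gmt.set_size_range
        if not 1 <= lo <= hi:
            errors.append("gmt.set_size_range must satisfy 1 <= lo <= hi")
        if not 0 < self.gmt.planted_overlap_fraction <= 1:
            errors.append("gmt.planted_overlap_fraction must be in (0, 1]")
        if errors:
            raise ValueError("; ".join(errors))


@dataclass
class GroundTruth:
    """What the generator planted, for scoring recovery."""

    module_members: list[set[str]]
    observed_seeds: list[set[str]]
    bridge_nodes: set[str]
    planted_gmt_set: str

    def hidden_members(self) -> set[str]:
        members = set().union(*self.module_members) if self.module_members else set()
        observed = set().union(*self.observed_seeds) if self.observed_seeds else set()
        return members - observed

    def to_dict(self) -> dict:
        return {
            "module_members": [sorted(m) for m in self.module_members],
            "observed_seeds": [sorted(s) for s in self.observed_seeds],
            "bridge_nodes": sorted(self.bridge_nodes),
            "planted_gmt_set": self.planted_gmt_set,
        }


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    interactome: Interactome
    source_edges: list[list[tuple[str, str]]]
    seed_sets: list[SeedSet]
    collection: GeneSetCollection
    truth: GroundTruth
    paths: dict[str, list[str] | str] = field(default_factory=dict)


def _gene(i: int) -> str:
    return f"G{i + 1:06d}"


def generate(spec: SyntheticSpec, outdir: str | Path | None = None) -> SyntheticDataset:
    """Generate one synthetic benchmark instance (optionally writing files).

    Writes, when ``outdir`` is given: one TSV edge list per source
    (``edges_src<i>.tsv``; their union reconstructs the full graph), one
    observed-seed list per module (``seeds_module<i>.txt``), the annotation
    collection (``annotations.gmt``) and the ground truth
    (``ground_truth.json``). Every file header records the RNG seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)

    # background backbone
    nx_seed = int(spec.rng_seed) % (2**31)
    if spec.backbone == "preferential_attachment":
        backbone = nx.barabasi_albert_graph(
            spec.n_background, int(spec.backbone_param), seed=nx_seed)
    else:
        backbone = nx.gnp_random_graph(
            spec.n_background, float(spec.backbone_param), seed=nx_seed)
    graph = nx.Graph()
    graph.add_nodes_from(_gene(i) for i in range(spec.n_background))
    graph.add_edges_from((_gene(u), _gene(v)) for u, v in backbone.edges)
    background_nodes = sorted(graph.nodes)

    # planted modules
    module_members: list[set[str]] = []
    observed_seeds: list[set[str]] = []
    bridge_nodes: set[str] = set()
    next_id = spec.n_background
    for mod in spec.modules:
        members = [_gene(next_id + j) for j in range(mod.size)]
        next_id += mod.size
        graph.add_nodes_from(members)
        for a_idx in range(mod.size):
            for b_idx in range(a_idx + 1, mod.size):
                if rng.random() < mod.within_density:
                    graph.add_edge(members[a_idx], members[b_idx])
        # bridges: uniform module x background pairs, without replacement
        total_pairs = mod.size * spec.n_background
        chosen = rng.choice(total_pairs, size=mod.n_bridges, replace=False)
        for flat in sorted(int(c) for c in chosen):
            m_node = members[flat // spec.n_background]
            b_node = background_nodes[flat % spec.n_background]
            graph.add_edge(m_node, b_node)
            bridge_nodes.update((m_node, b_node))
        module_members.append(set(members))
        n_obs = round(spec.seed_observation_rate * mod.size)
        obs = rng.choice(sorted(members), size=n_obs, replace=False)
        observed_seeds.append({str(g) for g in obs})

    all_nodes = sorted(graph.nodes)

    # split edges across source files
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    if len(edges) < spec.n_sources:
        raise ValueError("fewer edges than requested source files")
    perm = rng.permutation(len(edges))
    source_edges = [
        [edges[int(j)] for j in perm[i::spec.n_sources]]
        for i in range(spec.n_sources)
    ]

    interactome = Interactome(name=f"synthetic_seed{spec.rng_seed}")
    interactome.graph.add_nodes_from(all_nodes)
    for i, batch in enumerate(source_edges):
        for u, v in batch:
            interactome.add_edge(u, v, f"SRC{i + 1}")

    # GMT: one planted set over module 0, uniform decoys
    gmt_sets: dict[str, tuple[str, set[str]]] = {}
    planted_members = sorted(module_members[0])
    planted_size = len(planted_members)
    k_in = round(spec.gmt.planted_overlap_fraction * planted_size)
    in_module = [str(g) for g in rng.choice(planted_members, size=k_in, replace=False)]
    non_module = sorted(set(all_nodes) - module_members[0])
    fillers = [str(g) for g in rng.choice(non_module, size=planted_size - k_in,
                                          replace=False)]
    planted_name = "GS000"
    gmt_sets[planted_name] = ("planted enriched set", set(in_module) | set(fillers))
    lo, hi = spec.gmt.set_size_range
    for i in range(spec.gmt.n_sets):
        size = int(rng.integers(lo, hi + 1))
        genes = {str(g) for g in rng.choice(all_nodes, size=size, replace=False)}
        gmt_sets[f"GS{i + 1:03d}"] = (f"decoy set {i + 1}", genes)
    collection = GeneSetCollection(gmt_sets, universe=set(all_nodes))

    seed_sets = [
        SeedSet(f"module{i}_seeds", set(obs),
                {g: {"synthetic"} for g in obs})
        for i, obs in enumerate(observed_seeds)
    ]
    truth = GroundTruth(module_members, observed_seeds, bridge_nodes, planted_name)
    dataset = SyntheticDataset(spec, interactome, source_edges, seed_sets,
                               collection, truth)
    if outdir is not None:
        _write_dataset(dataset, Path(outdir))
    return dataset


def _write_dataset(ds: SyntheticDataset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# rng_seed={ds.spec.rng_seed}"
    edge_paths = []
    for i, batch in enumerate(ds.source_edges):
        path = outdir / f"edges_src{i + 1}.tsv"
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(header + f" source=SRC{i + 1}\n")
            for u, v in batch:
                handle.write(f"{u}\t{v}\n")
        edge_paths.append(str(path))
    seed_paths = []
    for i, seeds in enumerate(ds.seed_sets):
        path = outdir / f"seeds_module{i}.txt"
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(header + f" module={i}\n")
            for g in sorted(seeds.genes):
                handle.write(g + "\n")
        seed_paths.append(str(path))
    gmt_path = outdir / "annotations.gmt"
    with open(gmt_path, "w", encoding="utf-8") as handle:
        handle.write(header + "\n")
        for name in sorted(ds.collection.sets):
            desc, genes = ds.collection.sets[name]
            handle.write("\t".join([name, desc, *sorted(genes)]) + "\n")
    truth_path = outdir / "ground_truth.json"
    with open(truth_path, "w", encoding="utf-8") as handle:
        json.dump({"rng_seed": ds.spec.rng_seed, **ds.truth.to_dict()},
                  handle, indent=1, sort_keys=True)
        handle.write("\n")
    ds.paths = {
        "edges": edge_paths,
        "seeds": seed_paths,
        "gmt": str(gmt_path),
        "ground_truth": str(truth_path),
    }


def score_recovery(truth: GroundTruth, network: ExpandedNetwork
                   ) -> tuple[float | None, float | None]:
    """(precision, recall) of hidden module members among the connectors.

    Precision is None when the network recruited no connectors; recall is
    None when the ground truth has no hidden members (observation rate 1).
    """
    hidden = truth.hidden_members()
    connectors = network.connectors
    found = len(connectors & hidden)
    precision = found / len(connectors) if connectors else None
    recall = found / len(hidden) if hidden else None
    return precision, recall
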