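"""Partitioning a query network against reference disease networks.

Given an expanded query network (built from the union of heritable-disease
factors and microRNA target genes), every gene is classified by membership
in two reference networks — here a pulmonary-hypertension (PH) network and
a fibrosis network: common to both (``BOTH``), to one only (``PH_only`` /
``FIB_only``), or to neither (``OUTER``, the outer ring of genes). The
outer-ring list is the query of the second enrichment round.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .expansion import ExpandedNetwork, expand_network
from .genesets import SeedSet
from .interactome import Interactome

CLASSES = ("PH_only", "FIB_only", "BOTH", "OUTER")


@dataclass
class PartitionedNetwork:
    """A query network with a four-way reference-membership classification.

    ``class_of`` is total over the network's nodes; ``is_mir_target`` and
    ``is_heritable_factor`` carry the input metadata flags (rendered in the
    source figure style as thick borders / node colors).
    """

    network: ExpandedNetwork
    class_of: dict[str, str]
    is_mir_target: dict[str, bool] = field(default_factory=dict)
    is_heritable_factor: dict[str, bool] = field(default_factory=dict)

    def genes_in_class(self, cls: str) -> set[str]:
        if cls not in CLASSES:
            raise ValueError(f"unknown partition class {cls!r}")
        return {v for v, c in self.class_of.items() if c == cls}

    def validate(self) -> None:
        nodes = self.network.nodes
        if set(self.class_of) != nodes:
            raise ValueError("class_of is not total over the network nodes")
        bad = {c for c in self.class_of.values() if c not in CLASSES}
        if bad:
            raise ValueError(f"unknown partition classes: {bad}")


def build_query_network(
    interactome: Interactome,
    heritable_factors: SeedSet,
    mir_targets: SeedSet,
) -> ExpandedNetwork:
    """Expand the union of heritable factors and miR targets into one network.

    Delegates to :func:`seedmodule.expansion.expand_network` on the union
    seed set; each node of the result is flagged ``is_heritable_factor`` /
    ``is_mir_target`` by membership in the two input lists (a gene present
    in both lists carries both flags and is counted once).
    """
    union = heritable_factors.union(mir_targets)
    network = expand_network(interactome, union)
    for v in network.graph.nodes:
        network.graph.nodes[v]["is_heritable_factor"] = v in heritable_factors.genes
        network.graph.nodes[v]["is_mir_target"] = v in mir_targets.genes
    return network


def partition(
    network: ExpandedNetwork,
    ph_net_nodes: set[str],
    fib_net_nodes: set[str],
) -> PartitionedNetwork:
    """Classify every network gene by reference-network membership.

    Membership is tested against the reference networks' full node sets
    (inner circles); genes in neither form the outer ring. The class is
    also stored as the ``partition_class`` node attribute so serialized
    networks carry it.
    """
    class_of: dict[str, str] = {}
    for v in network.graph.nodes:
        in_ph = v in ph_net_nodes
        in_fib = v in fib_net_nodes
        if in_ph and in_fib:
            cls = "BOTH"
        elif in_ph:
            cls = "PH_only"
        elif in_fib:
            cls = "FIB_only"
        else:
            cls = "OUTER"
        class_of[v] = cls
        network.graph.nodes[v]["partition_class"] = cls
    mir = {v: bool(network.graph.nodes[v].get("is_mir_target", False))
           for v in network.graph.nodes}
    her = {v: bool(network.graph.nodes[v].get("is_heritable_factor", False))
           for v in network.graph.nodes}
    result = PartitionedNetwork(network=network, class_of=class_of,
                                is_mir_target=mir, is_heritable_factor=her)
    result.validate()
    return result


def partition_report(partitioned: PartitionedNetwork) -> dict:
    """Per-class counts plus the gene lists that feed the enrichment rounds."""
    counts = {cls: len(partitioned.genes_in_class(cls)) for cls in CLASSES}
    return {
        "n_genes": partitioned.network.graph.number_of_nodes(),
        "class_counts": counts,
        "both_genes": sorted(partitioned.genes_in_class("BOTH")),
        "outer_genes": sorted(partitioned.genes_in_class("OUTER")),
        "n_mir_targets": sum(partitioned.is_mir_target.values()),
        "n_heritable_factors": sum(partitioned.is_heritable_factor.values()),
    }
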