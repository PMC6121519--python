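"""Seed-gene lists and annotation gene-set collections."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SeedSet:
    """A named list of curated disease-relevant genes.

    ``genes`` holds normalized symbols; ``provenance`` maps each symbol to
    the labels of the sources that nominated it (e.g. a literature search
    versus a knowledge base). ``unmapped`` is populated when the set is
    mapped onto an interactome and records symbols absent from it.
    """

    name: str
    genes: set[str]
    provenance: dict[str, set[str]] = field(default_factory=dict)
    unmapped: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"seed set {self.name!r} is empty")
        for g in self.genes:
            self.provenance.setdefault(g, set())

    def __len__(self) -> int:
        return len(self.genes)

    def union(self, other: "SeedSet", name: str | None = None) -> "SeedSet":
        """Union of two seed sets; provenance labels are merged per gene."""
        genes = self.genes | other.genes
        prov: dict[str, set[str]] = {g: set() for g in genes}
        for src in (self, other):
            for g, labels in src.provenance.items():
                prov[g] |= labels
        return SeedSet(name or f"{self.name}+{other.name}", genes, prov)


@dataclass
class GeneSetCollection:
    """Named annotation gene sets (GO/KEGG/REACTOME/BioCarta style, GMT-backed).

    ``sets`` maps a unique set name to ``(description, genes)`` where genes
    are normalized symbols. ``universe`` optionally pins an explicit
    background; when absent, callers supply one (typically the consolidated
    interactome's node set).
    """

    sets: dict[str, tuple[str, set[str]]]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty after normalization")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return sorted(self.sets)

    def genes_of(self, name: str) -> set[str]:
        return set(self.sets[name][1])


def seed_overlap_report(seeds_a: SeedSet, seeds_b: SeedSet) -> tuple[int, int, int]:
    """Cardinalities (|A|, |B|, |A ∩ B|) of two seed sets after normalization."""
    return len(seeds_a.genes), len(seeds_b.genes), len(seeds_a.genes & seeds_b.genes)
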