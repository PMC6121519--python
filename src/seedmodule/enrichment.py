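"""Over-representation analysis (ORA) of gene lists against GMT collections.

For an unranked query gene list the appropriate enrichment statistic is the
one-sided hypergeometric test: with a background universe of ``N`` genes of
which ``K`` belong to an annotation set, drawing ``n`` query genes and
observing ``k`` in the set, the p-value is ``P(X >= k)`` for
``X ~ Hypergeometric(N, K, n)``. P-values are corrected per analysis round
with the Benjamini–Hochberg step-up FDR procedure.

The two-round driver mirrors the disease-network workflow: round 1 queries
every gene of the partitioned query network, round 2 only the outer-ring
genes (those common to neither reference network), each round corrected
independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSetCollection
from .partition import PartitionedNetwork


@dataclass
class EnrichmentResult:
    set_name: str
    set_size_in_universe: int
    query_size_in_universe: int
    overlap: int
    universe_size: int
    p_raw: float
    p_adjusted: float
    overlap_genes: list[str]


def hypergeom_upper_tail(overlap: int, query: int, set_size: int, universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    ``X`` counts set members among ``query`` genes drawn without
    replacement from a ``universe`` containing ``set_size`` set members.
    Raises ValueError on inconsistent counts.
    """
    if min(overlap, query, set_size, universe) < 0:
        raise ValueError("counts must be non-negative")
    if overlap > min(query, set_size):
        raise ValueError(
            f"overlap {overlap} exceeds min(query={query}, set={set_size})")
    if query > universe or set_size > universe:
        raise ValueError("query and set sizes must not exceed the universe")
    if overlap <= 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe, set_size, query))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values (order preserved).

    Adjusted values satisfy ``adj >= raw``, are capped at 1 and are
    monotone non-decreasing when read in rank order of the raw values.
    Raises ValueError if any input is outside [0, 1].
    """
    if len(pvalues) == 0:
        return []
    if any(p < 0 or p > 1 for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(pvalues, method="fdr_bh")
    return [float(p) for p in adjusted]


def run_enrichment(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str],
    min_set: int = 5,
    max_set: int = 500,
) -> list[EnrichmentResult]:
    """Test every eligible annotation set for over-representation in ``query``.

    Annotation sets and the query are first intersected with the universe;
    sets whose in-universe size falls outside ``[min_set, max_set]`` are not
    tested. Results are BH-adjusted across all tested sets and sorted by
    raw p-value, ties by set name. Raises ValueError when the query or the
    universe is empty after filtering, or when no set is eligible.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query_u = set(query) & universe
    if not query_u:
        raise ValueError(
            f"query empty after intersecting with the universe "
            f"(|query|={len(query)}, |universe|={len(universe)})")

    rows: list[EnrichmentResult] = []
    for name in sorted(collection.sets):
        genes_u = collection.sets[name][1] & universe
        if not (min_set <= len(genes_u) <= max_set):
            continue
        overlap_genes = sorted(query_u & genes_u)
        p = hypergeom_upper_tail(
            len(overlap_genes), len(query_u), len(genes_u), len(universe))
        rows.append(EnrichmentResult(
            set_name=name,
            set_size_in_universe=len(genes_u),
            query_size_in_universe=len(query_u),
            overlap=len(overlap_genes),
            universe_size=len(universe),
            p_raw=p,
            p_adjusted=p,  # overwritten below
            overlap_genes=overlap_genes,
        ))
    if not rows:
        raise ValueError(
            f"no annotation set of size in [{min_set}, {max_set}] within the universe")
    adjusted = bh_adjust([r.p_raw for r in rows])
    for row, p_adj in zip(rows, adjusted):
        row.p_adjusted = p_adj
    rows.sort(key=lambda r: (r.p_raw, r.set_name))
    return rows


def two_round_enrichment(
    partitioned: PartitionedNetwork,
    collection: GeneSetCollection,
    universe: set[str],
    min_set: int = 5,
    max_set: int = 500,
) -> tuple[list[EnrichmentResult], list[EnrichmentResult] | None]:
    """The two analysis rounds: all network genes, then outer-ring genes only.

    Round 2 is skipped (returned as None, with a warning) when the outer
    ring is empty. The rounds are corrected independently.
    """
    round1 = run_enrichment(partitioned.network.nodes, collection, universe,
                            min_set, max_set)
    outer = partitioned.genes_in_class("OUTER")
    if not outer:
        warnings.warn("no outer-ring genes: round-2 enrichment skipped",
                      stacklevel=2)
        return round1, None
    round2 = run_enrichment(outer, collection, universe, min_set, max_set)
    return round1, round2


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate ranked enrichment results (the TSV export layout)."""
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "set_size": r.set_size_in_universe,
                "query_size": r.query_size_in_universe,
                "overlap": r.overlap,
                "universe": r.universe_size,
                "p_raw": r.p_raw,
                "p_adj": r.p_adjusted,
                "overlap_genes": ";".join(r.overlap_genes),
            }
            for r in results
        ]
    )


def write_results_tsv(results: list[EnrichmentResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
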