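"""Readers and writers for interaction files, seed lists, GMT and networks.

Supported inputs
----------------
* two-column TSV edge lists (optional header, ``#`` comments),
* a PSI-MITAB 2.5 subset (IDs in columns 1-2, alt IDs/aliases in 3-6;
  gene symbols recovered from ``(gene name)``-tagged alias entries),
* GMT annotation collections (name TAB description TAB genes...),
* seed lists, one symbol per line.

Outputs are GraphML (typed node/edge attributes), TSV node/edge tables,
JSON, and GMT. Write-then-read round-trips reproduce networks exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .identifiers import MalformedIdentifierError, apply_synonyms, normalize_symbol
from .interactome import Interactome
from .genesets import GeneSetCollection, SeedSet


class ParseError(ValueError):
    """A line could not be parsed in strict mode."""


class EmptyInputError(ValueError):
    """An input file yielded no usable records."""


#: header tokens recognized (case-insensitively) in the first line of a TSV
_HEADER_TOKENS = {
    "gene_a", "gene_b", "genea", "geneb", "gene1", "gene2", "gene 1", "gene 2",
    "source", "target", "node1", "node2", "from", "to",
    "interactor_a", "interactor_b", "interactor a", "interactor b",
    "symbol_a", "symbol_b", "symbol1", "symbol2", "protein_a", "protein_b",
    "official symbol interactor a", "official symbol interactor b",
}


@dataclass
class LoadReport:
    """Counts produced while ingesting one interaction file."""

    path: str
    source_label: str
    format: str
    lines_read: int = 0
    edges_kept: int = 0
    self_loops_dropped: int = 0
    duplicates_merged: int = 0
    lines_skipped: int = 0
    organism_filtered: int = 0
    score_filtered: int = 0
    n_nodes: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _extract_mitab_symbol(fields: list[str], which: int) -> str | None:
    """Recover a gene symbol for interactor ``which`` (0 or 1) from MITAB columns.

    Preference order: a ``(gene name)``-tagged entry in the alias column
    (5/6) then the alt-ID column (3/4); otherwise the first alias value;
    otherwise the primary-ID value. Entries look like ``db:VALUE(desc)``
    and are pipe-separated.
    """

    def entries(col: int) -> list[str]:
        if col >= len(fields):
            return []
        raw = fields[col].strip()
        if not raw or raw == "-":
            return []
        return raw.split("|")

    def value_of(entry: str) -> str:
        body = entry.split("(", 1)[0]
        if ":" in body:
            body = body.split(":", 1)[1]
        return body.strip().strip('"')

    for col in (4 + which, 2 + which):
        for entry in entries(col):
            if "(gene name)" in entry.lower():
                val = value_of(entry)
                if val:
                    return val
    for col in (4 + which, 2 + which, which):
        for entry in entries(col):
            val = value_of(entry)
            if val:
                return val
    return None


def _mitab_taxids(fields: list[str], which: int) -> set[str] | None:
    """Parse the taxid column for interactor ``which``; None if absent."""
    col = 9 + which
    if col >= len(fields):
        return None
    raw = fields[col].strip()
    if not raw or raw == "-":
        return None
    taxids = set()
    for entry in raw.split("|"):
        body = entry.split("(", 1)[0]
        if ":" in body:
            body = body.split(":", 1)[1]
        taxids.add(body.strip())
    return taxids


def _mitab_score(fields: list[str]) -> float | None:
    if len(fields) < 15:
        return None
    raw = fields[14].strip()
    if not raw or raw == "-":
        return None
    for entry in raw.split("|"):
        body = entry.split("(", 1)[0]
        if ":" in body:
            body = body.rsplit(":", 1)[1]
        try:
            return float(body)
        except ValueError:
            continue
    return None


def read_edge_list(
    path: str | Path,
    source_label: str,
    fmt: str = "tsv",
    strict: bool = False,
    synonyms: dict[str, str] | None = None,
    taxid: str | None = "9606",
    min_score: float | None = None,
) -> tuple[Interactome, LoadReport]:
    """Read one interaction file into a simple undirected interactome.

    Self-loops are dropped and duplicate unordered pairs merged; every kept
    edge is labeled ``source_label``. Unparseable lines are counted and
    skipped (raised as :class:`ParseError` when ``strict``). For MITAB
    input, rows are kept only when both interactors match ``taxid``
    (applied only when taxid columns are present; pass ``None`` to disable)
    and, if ``min_score`` is given, when a confidence score is present and
    not below it.

    Returns the interactome together with a :class:`LoadReport`; raises
    :class:`EmptyInputError` when no edge survives.
    """
    if fmt not in ("tsv", "mitab"):
        raise ValueError(f"unknown edge-list format: {fmt!r}")
    path = Path(path)
    inter = Interactome(name=source_label)
    report = LoadReport(path=str(path), source_label=source_label, format=fmt)
    seen_pairs: set[frozenset] = set()
    first_data_line = True

    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            report.lines_read += 1
            fields = line.split("\t")
            if fmt == "tsv" and len(fields) < 2:
                fields = line.split()

            if fmt == "tsv" and first_data_line:
                first_data_line = False
                lowered = [f.strip().lower() for f in fields[:2]]
                if any(tok in _HEADER_TOKENS for tok in lowered):
                    continue

            try:
                if fmt == "tsv":
                    if len(fields) < 2:
                        raise ParseError(f"{path}:{lineno}: expected 2 columns")
                    a = normalize_symbol(fields[0])
                    b = normalize_symbol(fields[1])
                else:
                    if len(fields) < 2:
                        raise ParseError(f"{path}:{lineno}: too few MITAB columns")
                    if taxid is not None:
                        tax_a = _mitab_taxids(fields, 0)
                        tax_b = _mitab_taxids(fields, 1)
                        if tax_a is not None and tax_b is not None:
                            if taxid not in tax_a or taxid not in tax_b:
                                report.organism_filtered += 1
                                continue
                    if min_score is not None:
                        score = _mitab_score(fields)
                        if score is None or score < min_score:
                            report.score_filtered += 1
                            continue
                    raw_a = _extract_mitab_symbol(fields, 0)
                    raw_b = _extract_mitab_symbol(fields, 1)
                    if raw_a is None or raw_b is None:
                        raise ParseError(
                            f"{path}:{lineno}: could not recover interactor symbols"
                        )
                    a = normalize_symbol(raw_a)
                    b = normalize_symbol(raw_b)
            except (ParseError, MalformedIdentifierError) as exc:
                if strict:
                    raise ParseError(str(exc)) from exc
                report.lines_skipped += 1
                continue

            a = apply_synonyms(a, synonyms)
            b = apply_synonyms(b, synonyms)
            if a == b:
                report.self_loops_dropped += 1
                continue
            pair = frozenset((a, b))
            if pair in seen_pairs:
                report.duplicates_merged += 1
            else:
                seen_pairs.add(pair)
                report.edges_kept += 1
            inter.add_edge(a, b, source_label)

    if report.edges_kept == 0:
        raise EmptyInputError(f"no edges kept from {path}")
    report.n_nodes = inter.n_nodes
    return inter, report


def read_seed_list(
    path: str | Path,
    name: str | None = None,
    source_label: str | None = None,
    synonyms: dict[str, str] | None = None,
) -> SeedSet:
    """Read a one-symbol-per-line seed list (``#`` comments allowed)."""
    path = Path(path)
    name = name or path.stem
    source_label = source_label or name
    genes: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(apply_synonyms(normalize_symbol(line), synonyms))
    if not genes:
        raise EmptyInputError(f"no genes read from {path}")
    return SeedSet(name, genes, {g: {source_label} for g in genes})


def write_seed_list(seeds: SeedSet, path: str | Path, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        if header:
            handle.write(f"# {header}\n")
        for g in sorted(seeds.genes):
            handle.write(g + "\n")


def read_gmt(
    path: str | Path,
    strict: bool = False,
    synonyms: dict[str, str] | None = None,
) -> GeneSetCollection:
    """Read a GMT collection: one set per line, name TAB description TAB genes.

    Empty gene fields are dropped and symbols normalized. Lines with fewer
    than three fields are skipped with a warning (:class:`ParseError` when
    ``strict``); a duplicated set name is always an error.
    """
    sets: dict[str, tuple[str, set[str]]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            genes = {
                apply_synonyms(normalize_symbol(f), synonyms)
                for f in fields[2:]
                if f.strip()
            }
            if len(fields) < 3 or not genes:
                msg = f"{path}:{lineno}: GMT line with <3 usable fields, skipped"
                if strict:
                    raise ParseError(msg)
                warnings.warn(msg, stacklevel=2)
                continue
            name = fields[0].strip()
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = (fields[1].strip(), genes)
    if not sets:
        raise EmptyInputError(f"no gene sets read from {path}")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name in sorted(collection.sets):
            desc, genes = collection.sets[name]
            handle.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# --------------------------------------------------------------------------
# expanded-network serialization
# --------------------------------------------------------------------------

_NODE_ATTRS = ("is_seed", "addition_rank", "partition_class", "is_mir_target",
               "is_heritable_factor")


def _network_to_sorted_graph(network) -> nx.Graph:
    """Copy with deterministic node/edge insertion order for stable output."""
    g = nx.Graph()
    g.graph.update(network.graph.graph)
    g.graph["source_interactome_id"] = network.source_interactome_id
    g.graph["excluded_seeds"] = ";".join(sorted(network.excluded_seeds))
    g.graph.setdefault("tool_version", __version__)
    for v in sorted(network.graph.nodes):
        attrs = {
            k: network.graph.nodes[v][k]
            for k in _NODE_ATTRS
            if k in network.graph.nodes[v]
        }
        g.add_node(v, **attrs)
    for u, v in sorted(tuple(sorted(e)) for e in network.graph.edges):
        g.add_edge(u, v)
    return g


def write_network(network, path: str | Path, fmt: str = "graphml",
                  config_hash: str | None = None) -> None:
    """Serialize an ExpandedNetwork to GraphML, TSV tables, or JSON.

    ``graphml``/``json`` round-trip exactly (see :func:`read_network`).
    ``tsv`` writes the edge table at ``path`` and a node table at a sibling
    ``<stem>.nodes.tsv``. Every output records the tool version (and
    optionally a config hash).
    """
    path = Path(path)
    g = _network_to_sorted_graph(network)
    if config_hash is not None:
        g.graph["config_hash"] = config_hash
    if fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif fmt == "json":
        payload = {
            "tool_version": g.graph.get("tool_version"),
            "config_hash": g.graph.get("config_hash"),
            "source_interactome_id": g.graph["source_interactome_id"],
            "excluded_seeds": sorted(network.excluded_seeds),
            "nodes": [{"id": v, **g.nodes[v]} for v in g.nodes],
            "edges": [[u, v] for u, v in g.edges],
        }
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)
            handle.write("\n")
    elif fmt == "tsv":
        edge_df = pd.DataFrame([(u, v) for u, v in g.edges],
                               columns=["gene_a", "gene_b"])
        node_rows = []
        for v in g.nodes:
            row = {"gene": v}
            row.update({k: g.nodes[v].get(k) for k in _NODE_ATTRS})
            node_rows.append(row)
        node_df = pd.DataFrame(node_rows)
        header = (f"# seedmodule {g.graph.get('tool_version')}"
                  f" config={g.graph.get('config_hash', '-')}"
                  f" source={g.graph['source_interactome_id']}"
                  f" excluded={g.graph['excluded_seeds'] or '-'}\n")
        with open(path, "w", encoding="utf-8") as handle:
            handle.write(header)
            edge_df.to_csv(handle, sep="\t", index=False)
        nodes_path = path.with_suffix(".nodes.tsv")
        with open(nodes_path, "w", encoding="utf-8") as handle:
            handle.write(header)
            node_df.to_csv(handle, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format: {fmt!r}")


def read_network(path: str | Path, fmt: str | None = None):
    """Read an ExpandedNetwork written by :func:`write_network`."""
    from .expansion import ExpandedNetwork

    path = Path(path)
    if fmt is None:
        fmt = {".graphml": "graphml", ".json": "json", ".tsv": "tsv"}.get(
            path.suffix, "graphml")
    if fmt == "graphml":
        g = nx.read_graphml(path)
        excluded = set(filter(None, g.graph.get("excluded_seeds", "").split(";")))
        source = g.graph.get("source_interactome_id", "")
        graph = nx.Graph()
        graph.graph.update(g.graph)
        for v, data in g.nodes(data=True):
            graph.add_node(v, **data)
        graph.add_edges_from(g.edges)
        return ExpandedNetwork(graph=graph, excluded_seeds=excluded,
                               source_interactome_id=source)
    if fmt == "json":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        graph = nx.Graph()
        for node in payload["nodes"]:
            attrs = {k: v for k, v in node.items() if k != "id" and v is not None}
            graph.add_node(node["id"], **attrs)
        graph.add_edges_from(payload["edges"])
        return ExpandedNetwork(
            graph=graph,
            excluded_seeds=set(payload["excluded_seeds"]),
            source_interactome_id=payload.get("source_interactome_id", ""),
        )
    if fmt == "tsv":
        header = ""
        with open(path, encoding="utf-8") as handle:
            header = handle.readline()
        meta = dict(
            part.split("=", 1) for part in header.lstrip("# ").split()
            if "=" in part
        )
        edge_df = pd.read_csv(path, sep="\t", comment="#")
        node_df = pd.read_csv(path.with_suffix(".nodes.tsv"), sep="\t", comment="#")
        graph = nx.Graph()
        for _, row in node_df.iterrows():
            attrs = {}
            for k in _NODE_ATTRS:
                val = row.get(k)
                if pd.isna(val):
                    continue
                if k == "addition_rank":
                    attrs[k] = int(val)
                elif k == "partition_class":
                    attrs[k] = str(val)
                elif isinstance(val, str):
                    attrs[k] = val.strip().lower() == "true"
                else:
                    attrs[k] = bool(val)
            graph.add_node(str(row["gene"]), **attrs)
        graph.add_edges_from(
            (str(a), str(b)) for a, b in zip(edge_df["gene_a"], edge_df["gene_b"])
        )
        excluded_field = meta.get("excluded", "-")
        excluded = set() if excluded_field == "-" else set(excluded_field.split(";"))
        source = meta.get("source", "")
        return ExpandedNetwork(graph=graph, excluded_seeds=excluded,
                               source_interactome_id=source)
    raise ValueError(f"unknown network format: {fmt!r}")


# --------------------------------------------------------------------------
# interactome serialization
# --------------------------------------------------------------------------

def write_interactome(inter: Interactome, path: str | Path,
                      config_hash: str | None = None) -> None:
    """Write an interactome to GraphML, joining edge provenance with ';'."""
    g = nx.Graph()
    g.graph["name"] = inter.name
    g.graph["tool_version"] = __version__
    if config_hash is not None:
        g.graph["config_hash"] = config_hash
    g.add_nodes_from(sorted(inter.graph.nodes))
    for u, v in sorted(tuple(sorted(e)) for e in inter.graph.edges):
        g.add_edge(u, v, sources=";".join(sorted(inter.edge_sources(u, v))))
    nx.write_graphml(g, path, named_key_ids=True)


def read_interactome(path: str | Path) -> Interactome:
    g = nx.read_graphml(path)
    inter = Interactome(name=g.graph.get("name", Path(path).stem))
    inter.graph.add_nodes_from(g.nodes)
    for u, v, data in g.edges(data=True):
        sources = set(filter(None, str(data.get("sources", "")).split(";")))
        inter.graph.add_edge(u, v, sources=sources or {"unknown"})
    return inter


def write_json_report(report: dict, path: str | Path) -> None:
    """Write a machine-readable run report (stable key order)."""
    payload = {"tool_version": __version__, **report}
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle, indent=1, sort_keys=True)
        handle.write("\n")
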