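"""Gene-symbol normalization.

All identifiers moving through the package are plain gene symbols. The
normalization contract is deliberately minimal — uppercase plus whitespace
trimming — so that consolidation of edge lists from different source
databases never depends on an online identifier-mapping service. An
optional synonym map (two-column TSV: alias TAB canonical) can rewrite
known aliases after normalization.
"""

from __future__ import annotations

from pathlib import Path


class MalformedIdentifierError(ValueError):
    """Raised when a gene identifier is empty or whitespace-only."""


def normalize_symbol(raw: str) -> str:
    """Return the canonical form of a gene symbol.

    Uppercases and strips surrounding whitespace. Idempotent:
    ``normalize_symbol(normalize_symbol(s)) == normalize_symbol(s)``.

    Raises
    ------
    MalformedIdentifierError
        If ``raw`` is empty or contains only whitespace.
    """
    if raw is None:
        raise MalformedIdentifierError("identifier is None")
    symbol = raw.strip()
    if not symbol:
        raise MalformedIdentifierError(f"empty identifier: {raw!r}")
    return symbol.upper()


def read_synonym_map(path: str | Path) -> dict[str, str]:
    """Read a two-column alias->canonical TSV into a normalized dict.

    Lines starting with ``#`` and blank lines are ignored. Both columns
    are normalized, so lookups must use normalized symbols.
    """
    mapping: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                continue
            mapping[normalize_symbol(fields[0])] = normalize_symbol(fields[1])
    return mapping


def apply_synonyms(symbol: str, synonyms: dict[str, str] | None) -> str:
    """Map an already-normalized symbol through an optional synonym table."""
    if synonyms is None:
        return symbol
    return synonyms.get(symbol, symbol)
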