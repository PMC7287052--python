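"""Gene-symbol alias handling.

Immunology and metabolism papers mix protein names (CD45, GLUT1, Perforin)
with HGNC symbols (PTPRC, SLC2A1, PRF1). Every module that looks a gene up
in an expression matrix goes through :func:`resolve_symbol` so that panels
may be written in either vocabulary. Matching is case-sensitive after alias
substitution.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

#: protein/legacy name -> HGNC symbol. Extendable by the caller.
DEFAULT_ALIASES: dict[str, str] = {
    "CD45": "PTPRC",
    "GLUT1": "SLC2A1",
    "Perforin": "PRF1",
    "PFN1": "PRF1",  # the perforin gene is PRF1; PFN1 (profilin) is a common slip
    "Granzyme": "GZMB",
}


def canonical_symbol(symbol: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map a symbol to its canonical (HGNC) form; unknown symbols pass through."""
    table = DEFAULT_ALIASES if aliases is None else aliases
    return table.get(symbol, symbol)


def resolve_symbol(
    symbol: str,
    available: Iterable[str],
    aliases: Mapping[str, str] | None = None,
) -> str:
    """Return the name under which ``symbol`` appears in ``available``.

    Tries the symbol itself first, then its alias image, then any alias
    preimage (so a matrix that itself uses ``GLUT1`` still matches a panel
    written with ``SLC2A1``).

    Raises
    ------
    KeyError
        naming the gene, if no spelling of it is present.
    """
    table = DEFAULT_ALIASES if aliases is None else aliases
    pool = set(available)
    if symbol in pool:
        return symbol
    mapped = table.get(symbol)
    if mapped is not None and mapped in pool:
        return mapped
    for src, dst in table.items():
        if dst == symbol and src in pool:
            return src
    raise KeyError(f"gene {symbol!r} not present in the matrix (aliases checked)")
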