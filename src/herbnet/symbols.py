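"""Gene-symbol normalization.

Public target databases mix symbol styles ("IL-6" vs "IL6", "IL-1β" vs
"IL1B", "COX-2" vs "PTGS2").  Set intersections between a drug-target list
and a disease-gene list are only meaningful after the two sides agree on
symbol identity, so every reader in this package funnels symbols through
:func:`normalize_symbol`:

1. strip surrounding whitespace,
2. transliterate Greek letters (α -> A, β -> B, ...),
3. remove hyphens,
4. uppercase,
5. resolve through an alias table (built-in, user-extensible via TSV).

The built-in alias table is deliberately small; curation gaps are expected
and can be surfaced with :func:`alias_near_misses`.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Iterable, Mapping

from .errors import FormatError

#: Greek letters as they appear in protein names, mapped to the Latin letter
#: conventionally used in HGNC symbols (e.g. "IL-1β" -> IL1B).
GREEK_TRANSLITERATION: Mapping[str, str] = {
    "α": "A", "Α": "A",   # alpha
    "β": "B", "Β": "B",   # beta
    "γ": "G", "Γ": "G",   # gamma
    "δ": "D", "Δ": "D",   # delta
    "ε": "E", "Ε": "E",   # epsilon
    "κ": "K", "Κ": "K",   # kappa
    "λ": "L", "Λ": "L",   # lambda
    "μ": "M", "Μ": "M",   # mu
    "σ": "S", "Σ": "S",   # sigma
    "ω": "O", "Ω": "O",   # omega
}


def _casefold_form(symbol: str) -> str:
    s = symbol.strip()
    s = "".join(GREEK_TRANSLITERATION.get(ch, ch) for ch in s)
    s = s.replace("-", "")
    return s.upper()


def load_alias_table(path) -> dict[str, str]:
    """Read a two-column TSV mapping alias -> canonical symbol.

    Both columns are themselves normalized (sans alias lookup), so the table
    may be written in any of the styles the pipeline accepts.  Lines starting
    with ``#`` are skipped.
    """
    table: dict[str, str] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for i, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].lstrip().startswith("#")):
                continue
            if len(row) < 2:
                raise FormatError("alias table rows need 2 columns", path=path, line=i)
            table[_casefold_form(row[0])] = _casefold_form(row[1])
    return table


def _builtin_aliases() -> dict[str, str]:
    ref = resources.files("herbnet").joinpath("data/aliases.tsv")
    with resources.as_file(ref) as p:
        return load_alias_table(p)


_BUILTIN: dict[str, str] | None = None


def builtin_aliases() -> dict[str, str]:
    """The packaged alias table (loaded once, then cached)."""
    global _BUILTIN
    if _BUILTIN is None:
        _BUILTIN = _builtin_aliases()
    return _BUILTIN


def normalize_symbol(symbol: str, aliases: Mapping[str, str] | None = None) -> str:
    """Return the canonical form of a gene symbol.

    Parameters
    ----------
    symbol:
        Raw symbol as read from a file.
    aliases:
        Extra alias entries merged over the built-in table; pass ``{}``
        to use the built-in table alone.
    """
    s = _casefold_form(symbol)
    table = builtin_aliases()
    if aliases:
        table = {**table, **{_casefold_form(k): _casefold_form(v) for k, v in aliases.items()}}
    return table.get(s, s)


def normalize_symbols(symbols: Iterable[str], aliases=None) -> set[str]:
    """Normalize a collection of symbols, discarding blanks."""
    out = set()
    for s in symbols:
        n = normalize_symbol(s, aliases)
        if n:
            out.add(n)
    return out


def alias_near_misses(left: Iterable[str], right: Iterable[str],
                      extra_aliases: Mapping[str, str] | None = None) -> list[tuple[str, str]]:
    """Report symbols of ``left`` absent from ``right`` that an alias entry
    would have matched.

    Returns ``(left_symbol, matched_right_symbol)`` pairs.  Useful for
    auditing why a drug/disease target intersection is smaller than expected:
    database exports often disagree on symbols in ways the built-in alias
    table does not yet cover.
    """
    table = dict(builtin_aliases())
    if extra_aliases:
        table.update({_casefold_form(k): _casefold_form(v) for k, v in extra_aliases.items()})
    right_set = set(right)
    misses = []
    for sym in sorted(set(left) - right_set):
        mapped = table.get(_casefold_form(sym))
        if mapped and mapped in right_set and mapped != sym:
            misses.append((sym, mapped))
    return misses
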