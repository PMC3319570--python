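"""The packaged analysis geneset and gene-symbol canonicalization.

The analysis geneset collects 137 genes relevant to nuclear-receptor /
histone-methylation coregulation in the testis, organised in five functional
categories: nuclear receptors (41), histone demethylases (18), histone and
DNA methyltransferases (45), coregulators (7, the ASCOM structural core plus
Ncoa6 and two corepressors) and endocrine-disruptor phenotype genes (28).
Two genes carry dual category membership (a nuclear receptor can itself be a
phenotype endpoint), so category slots sum to 139 over 137 unique symbols.

Symbols follow rat-style mixed-case nomenclature; legacy demethylase names
(``Utx``, ``Jmjd3``, ``Aof2`` ...) are resolved to current symbols through a
static alias table carried by the fixture.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "CATEGORIES",
    "PHENOTYPE_CLASSES",
    "GeneEntry",
    "Geneset",
    "GenesetError",
    "load_geneset",
    "normalize_symbol",
    "gatekeeper_set",
    "GATEKEEPER_SET",
]

CATEGORIES = (
    "nuclear_receptor",
    "demethylase",
    "methyltransferase",
    "coregulator",
    "phenotype",
)

PHENOTYPE_CLASSES = (
    "sexual_differentiation",
    "embryonic_development",
    "obesity",
    "spermatogenesis",
    "steroidogenesis",
)

#: Coregulatory genes of the gatekeeper mechanism: the estrogen receptor beta,
#: the H3K9 methyltransferases conferring the repressive marks and the
#: demethylase that removes them.
GATEKEEPER_SET = ("Esr2", "Ehmt2", "Ehmt1", "Kdm1", "Prdm2", "Setdb1")


class GenesetError(ValueError):
    """Raised for malformed fixture rows or unusable symbol queries."""


@dataclass(frozen=True)
class GeneEntry:
    """One curated geneset member.

    Parameters
    ----------
    symbol
        Canonical gene symbol (rat-style mixed case).
    categories
        One or more of :data:`CATEGORIES`; most genes have exactly one,
        dual-membership genes record both.
    aliases
        Legacy symbols that resolve to ``symbol`` (e.g. ``Utx`` -> ``Kdm6a``).
    phenotype_class
        Sub-label for phenotype genes, ``None`` otherwise.
    source
        Provenance of the entry (``core`` for members named directly in the
        coexpression/differential-expression analyses this package
        implements, ``review`` for members curated from the functional
        review literature).
    """

    symbol: str
    categories: tuple[str, ...]
    aliases: tuple[str, ...] = ()
    phenotype_class: str | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.symbol:
            raise GenesetError("gene entry requires a non-empty symbol")
        for cat in self.categories:
            if cat not in CATEGORIES:
                raise GenesetError(f"unknown category {cat!r} for {self.symbol}")

    @property
    def category(self) -> str:
        """Primary (first-listed) category."""
        return self.categories[0]


class Geneset:
    """Immutable collection of :class:`GeneEntry`, indexed by symbol and alias."""

    def __init__(self, entries: Iterable[GeneEntry]):
        self._entries: dict[str, GeneEntry] = {}
        self._alias_map: dict[str, str] = {}
        for entry in entries:
            if entry.symbol in self._entries:
                raise GenesetError(f"duplicate symbol {entry.symbol!r} in geneset")
            self._entries[entry.symbol] = entry
        for entry in self._entries.values():
            self._alias_map[entry.symbol.lower()] = entry.symbol
        for entry in self._entries.values():
            for alias in entry.aliases:
                key = alias.lower()
                target = self._alias_map.get(key)
                if target is not None and target != entry.symbol:
                    raise GenesetError(
                        f"alias {alias!r} maps to both {target} and {entry.symbol}"
                    )
                self._alias_map[key] = entry.symbol

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[GeneEntry]:
        return iter(self._entries.values())

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._entries

    def __getitem__(self, symbol: str) -> GeneEntry:
        return self._entries[symbol]

    def symbols(self, category: str | None = None) -> list[str]:
        """All canonical symbols, optionally restricted to one category."""
        if category is None:
            return list(self._entries)
        if category not in CATEGORIES:
            raise GenesetError(f"unknown category {category!r}")
        return [e.symbol for e in self if category in e.categories]

    def category_counts(self) -> dict[str, int]:
        """Member count per category; dual-membership genes count in each."""
        return {cat: len(self.symbols(cat)) for cat in CATEGORIES}

    def dual_category_symbols(self) -> list[str]:
        """Genes recorded in more than one category."""
        return [e.symbol for e in self if len(e.categories) > 1]

    def resolve(self, raw: str) -> tuple[str, bool]:
        """Resolve ``raw`` to a canonical symbol, case-insensitively.

        Returns ``(canonical, True)`` when ``raw`` is a known symbol or
        alias, ``(raw, False)`` otherwise.
        """
        if not raw:
            raise GenesetError("cannot normalize an empty gene symbol")
        hit = self._alias_map.get(raw.lower())
        if hit is None:
            return raw, False
        return hit, True


def _parse_row(row: dict[str, str], lineno: int) -> GeneEntry:
    try:
        symbol = row["symbol"].strip()
        categories = tuple(c for c in row["categories"].split(";") if c)
        aliases = tuple(a for a in row.get("aliases", "").split(",") if a)
        phenotype_class = row.get("phenotype_class", "").strip() or None
        source = row.get("source", "").strip()
    except (KeyError, AttributeError) as exc:
        raise GenesetError(f"malformed geneset row at line {lineno}: {exc}") from exc
    if not symbol or not categories:
        raise GenesetError(f"malformed geneset row at line {lineno}: {row}")
    if phenotype_class is not None and phenotype_class not in PHENOTYPE_CLASSES:
        raise GenesetError(
            f"unknown phenotype_class {phenotype_class!r} at line {lineno}"
        )
    try:
        return GeneEntry(symbol, categories, aliases, phenotype_class, source)
    except GenesetError as exc:
        raise GenesetError(f"line {lineno}: {exc}") from exc


def load_geneset(path: str | Path | None = None) -> Geneset:
    """Load the analysis geneset from a TSV fixture.

    With no argument the packaged 137-gene fixture is used. The TSV header is
    ``symbol  categories  aliases  phenotype_class  source`` with
    semicolon-separated categories and comma-separated aliases.
    """
    if path is None:
        ref = resources.files("coexprofiler").joinpath("data/geneset.tsv")
        with resources.as_file(ref) as p:
            return load_geneset(p)
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "symbol" not in reader.fieldnames:
            raise GenesetError(f"{path}: missing TSV header with 'symbol' column")
        for lineno, row in enumerate(reader, start=2):
            entries.append(_parse_row(row, lineno))
    return Geneset(entries)


def normalize_symbol(raw: str, geneset: Geneset) -> str:
    """Convert a legacy gene symbol to current nomenclature.

    Known aliases and canonical symbols match case-insensitively; an unknown
    symbol is returned unchanged with a :class:`UserWarning`. Idempotent.
    """
    symbol, known = geneset.resolve(raw)
    if not known:
        warnings.warn(f"unrecognized gene symbol {raw!r}; kept as-is", stacklevel=2)
    return symbol


def gatekeeper_set() -> list[str]:
    """The six-gene gatekeeper coregulatory set."""
    return list(GATEKEEPER_SET)
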