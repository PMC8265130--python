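"""Reading and writing gene-set libraries, query sets, and symbol alias maps.

Gene-set libraries travel in GMT format (one tab-separated line per set:
name, description, members...), the de-facto exchange format for gene-set
collections. All symbols are uppercased and whitespace-stripped at
ingestion so that overlap computation is deterministic across sources that
mix human and mouse symbol casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

SOURCE_TYPES = ("KSI", "PPI", "coexpression", "mixed")


class GmtParseError(ValueError):
    """Raised for structurally invalid GMT input (short line, duplicate set name)."""


class SymbolMapError(ValueError):
    """Raised when an alias map is internally inconsistent."""


def _clean_symbol(token: str) -> str:
    return "".join(token.split()).upper()


@dataclass
class GeneSetLibrary:
    """A named collection of kinase -> substrate-set mappings.

    Parameters
    ----------
    name
        Library label (e.g. the source database).
    source_type
        One of ``KSI``, ``PPI``, ``coexpression``, ``mixed`` — the kind of
        evidence the member sets encode.
    sets
        Mapping from kinase symbol to an ordered, duplicate-free list of
        member symbols.
    """

    name: str
    source_type: str
    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.source_type not in SOURCE_TYPES:
            raise ValueError(
                f"source_type must be one of {SOURCE_TYPES}, got {self.source_type!r}"
            )
        self.validate()

    def validate(self) -> None:
        for kinase, members in self.sets.items():
            if not kinase or kinase != _clean_symbol(kinase):
                raise ValueError(f"invalid set name {kinase!r}")
            if len(set(members)) != len(members):
                raise ValueError(f"duplicate members in set {kinase!r}")
            for m in members:
                if not m or m != _clean_symbol(m):
                    raise ValueError(f"invalid member symbol {m!r} in set {kinase!r}")

    @property
    def k(self) -> int:
        """Number of sets in the library (the ranking denominator)."""
        return len(self.sets)

    def kinases(self) -> list[str]:
        return list(self.sets)


@dataclass
class QuerySet:
    """A normalized query protein set plus a record of rejected input tokens.

    ``discarded`` holds ``(original token, reason)`` pairs; reasons are
    ``"unmapped"`` (no alias-map entry) and ``"duplicate"`` (same canonical
    symbol already present).
    """

    symbols: list[str]
    discarded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("duplicate symbols in QuerySet")


@dataclass
class SymbolMap:
    """Alias -> canonical symbol mapping. Canonical symbols map to themselves."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        canonicals = set(self.entries.values())
        missing = [c for c in canonicals if self.entries.get(c) != c]
        if missing:
            raise SymbolMapError(
                f"canonical symbols must map to themselves; violators: {sorted(missing)[:5]}"
            )

    @classmethod
    def identity(cls, symbols: Iterable[str]) -> "SymbolMap":
        cleaned = [_clean_symbol(s) for s in symbols]
        return cls(entries={s: s for s in cleaned})


def read_gmt(path: str | Path, name: str | None = None,
             source_type: str = "mixed") -> GeneSetLibrary:
    """Parse a GMT file into a :class:`GeneSetLibrary`.

    Members are deduplicated preserving first occurrence and uppercased.
    The description field (column 2) is ignored on read.

    Raises
    ------
    GmtParseError
        If a line has fewer than 3 tab-separated fields or a set name
        repeats; the error message names the offending line number.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            set_name = _clean_symbol(fields[0])
            if not set_name:
                raise GmtParseError(f"{path}:{lineno}: empty set name")
            if set_name in sets:
                raise GmtParseError(f"{path}:{lineno}: duplicate set name {set_name!r}")
            seen: dict[str, None] = {}
            for token in fields[2:]:
                sym = _clean_symbol(token)
                if sym and sym not in seen:
                    seen[sym] = None
            sets[set_name] = list(seen)
    return GeneSetLibrary(name=name or path.stem, source_type=source_type, sets=sets)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> Path:
    """Write a library to GMT; the description column carries the source type."""
    library.validate()
    path = Path(path)
    with path.open("w") as fh:
        for kinase, members in library.sets.items():
            fh.write("\t".join([kinase, library.source_type, *members]) + "\n")
    return path


def normalize_symbols(tokens: Sequence[str], symbol_map: SymbolMap) -> QuerySet:
    """Map raw input tokens to canonical symbols, recording every rejection.

    Each token is uppercased, looked up in the alias map, and either kept
    (first occurrence of its canonical symbol), discarded as ``"duplicate"``
    (canonical already present), or discarded as ``"unmapped"``. The output
    satisfies ``len(symbols) + len(discarded) == len(tokens)``.
    """
    symbols: list[str] = []
    seen: set[str] = set()
    discarded: list[tuple[str, str]] = []
    for token in tokens:
        cleaned = _clean_symbol(token)
        canonical = symbol_map.entries.get(cleaned)
        if canonical is None:
            discarded.append((token, "unmapped"))
        elif canonical in seen:
            discarded.append((token, "duplicate"))
        else:
            seen.add(canonical)
            symbols.append(canonical)
    return QuerySet(symbols=symbols, discarded=discarded)


def read_query(path: str | Path) -> list[str]:
    """Read a plain-text query: one symbol per line, blanks skipped."""
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]


def read_symbol_map(path: str | Path) -> SymbolMap:
    """Load a 2-column TSV (alias, canonical) into a :class:`SymbolMap`.

    An alias mapping to two different canonicals is rejected with an error
    listing the collisions — a silent arbitrary choice would corrupt
    downstream overlap counts.
    """
    entries: dict[str, str] = {}
    collisions: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise SymbolMapError(f"{path}:{lineno}: expected 2 tab-separated fields")
            alias, canonical = _clean_symbol(fields[0]), _clean_symbol(fields[1])
            if alias in entries and entries[alias] != canonical:
                collisions.setdefault(alias, {entries[alias]}).add(canonical)
            entries[alias] = canonical
    if collisions:
        detail = "; ".join(
            f"{a} -> {sorted(cs)}" for a, cs in sorted(collisions.items())
        )
        raise SymbolMapError(f"alias collisions in {path}: {detail}")
    for canonical in set(entries.values()):
        entries.setdefault(canonical, canonical)
    return SymbolMap(entries=entries)
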