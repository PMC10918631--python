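"""Parsers for reference sources and gold standards.

Three plain-text inputs are supported:

* OBO 1.2/1.4 ontology files (Disease Ontology dialect), with ``is_a``
  based subtree extraction under a root accession such as ``DOID:162``;
* delimited synonym tables (identifier column + synonym column, in the
  style of ChEMBL / DrugBank exports);
* two-column gold-standard files ``query<TAB>identifier`` where the
  literal token ``NONE`` marks an expected no-match.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path

from .evaluation import GoldStandardRecord, NEGATIVE_MARKER

__all__ = [
    "Synonym",
    "OntologyTerm",
    "SynonymTableSpec",
    "OboParseError",
    "GoldFormatError",
    "parse_obo",
    "subtree",
    "ontology_to_pairs",
    "parse_synonym_table",
    "load_gold",
    "load_queries",
]

SYNONYM_SCOPES = ("EXACT", "RELATED", "NARROW", "BROAD")

_SYNONYM_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*([A-Z_]+)?')


class OboParseError(ValueError):
    pass


class GoldFormatError(ValueError):
    def __init__(self, message: str, line_numbers: list[int]):
        super().__init__(message)
        self.line_numbers = line_numbers


@dataclass(frozen=True)
class Synonym:
    text: str
    scope: str = "RELATED"


@dataclass
class OntologyTerm:
    id: str
    name: str | None = None
    synonyms: list[Synonym] = field(default_factory=list)
    parents: list[str] = field(default_factory=list)
    obsolete: bool = False


def _open_text(source):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8"), True
    if isinstance(source, io.TextIOBase) or hasattr(source, "read"):
        return source, False
    raise TypeError(f"cannot read from {type(source).__name__}")


def parse_obo(source) -> list[OntologyTerm]:
    """Parse ``[Term]`` stanzas from an OBO flat file.

    Captures term id, name, synonyms (quoted surface form plus scope
    qualifier), ``is_a`` parents and the obsolete flag. A stanza without
    an ``id:`` line raises :class:`OboParseError` naming its line number.
    """
    fh, should_close = _open_text(source)
    try:
        terms: list[OntologyTerm] = []
        current: dict | None = None
        stanza_line = 0
        in_term = False

        def flush(at_line: int):
            nonlocal current
            if not in_term or current is None:
                current = None
                return
            if current.get("id") is None:
                raise OboParseError(
                    f"[Term] stanza starting at line {stanza_line} has no id"
                )
            terms.append(
                OntologyTerm(
                    id=current["id"],
                    name=current.get("name"),
                    synonyms=current.get("synonyms", []),
                    parents=current.get("parents", []),
                    obsolete=current.get("obsolete", False),
                )
            )
            current = None

        for lineno, raw_line in enumerate(fh, 1):
            line = raw_line.strip()
            if line.startswith("!"):
                continue
            if line.startswith("["):
                flush(lineno)
                in_term = line == "[Term]"
                if in_term:
                    current = {}
                    stanza_line = lineno
                continue
            if not in_term or current is None or not line:
                continue
            key, sep, value = line.partition(":")
            if not sep:
                continue
            key = key.strip()
            value = value.split(" !")[0].strip()
            if key == "id":
                current["id"] = value
            elif key == "name":
                current["name"] = value
            elif key == "synonym":
                m = _SYNONYM_RE.match(value)
                if m:
                    scope = m.group(2) if m.group(2) in SYNONYM_SCOPES else "RELATED"
                    text = m.group(1).replace('\\"', '"')
                    current.setdefault("synonyms", []).append(Synonym(text, scope))
            elif key == "is_a":
                current.setdefault("parents", []).append(value)
            elif key == "is_obsolete":
                current["obsolete"] = value.lower() == "true"
        flush(-1)
        return terms
    finally:
        if should_close:
            fh.close()


def subtree(terms, root: str) -> list[OntologyTerm]:
    """All non-obsolete terms reachable from ``root`` via reversed ``is_a`` edges.

    The root itself is included; obsolete terms are excluded and not
    traversed through. Raises ``ValueError`` if ``root`` is absent.
    """
    terms = list(terms)
    by_id = {t.id: t for t in terms}
    if root not in by_id:
        raise ValueError(f"root term {root!r} not found in ontology")
    children: dict[str, list[str]] = {}
    for t in terms:
        if t.obsolete:
            continue
        for parent in t.parents:
            children.setdefault(parent, []).append(t.id)
    seen = set()
    stack = [root]
    while stack:
        tid = stack.pop()
        if tid in seen or by_id[tid].obsolete:
            continue
        seen.add(tid)
        stack.extend(children.get(tid, ()))
    # preserve file order for reproducible downstream output
    return [t for t in terms if t.id in seen]


def ontology_to_pairs(terms, scopes=None) -> list[tuple[str, str]]:
    """Emit ``(name, id)`` and ``(synonym, id)`` pairs for non-obsolete terms.

    ``scopes`` optionally restricts synonyms to a subset of
    EXACT/RELATED/NARROW/BROAD; by default all scopes are loaded.
    """
    pairs: list[tuple[str, str]] = []
    for t in terms:
        if t.obsolete:
            continue
        if t.name:
            pairs.append((t.name, t.id))
        for syn in t.synonyms:
            if scopes is not None and syn.scope not in scopes:
                continue
            if syn.text:
                pairs.append((syn.text, t.id))
    return pairs


@dataclass(frozen=True)
class SynonymTableSpec:
    """How to read a delimited synonym table."""

    delimiter: str = "\t"
    id_column: str | int = 0
    name_column: str | int = 1
    header: bool = False

    def __post_init__(self):
        if self.id_column == self.name_column:
            raise ValueError("id_column and name_column must differ")


def _resolve_column(col, header_row, spec) -> int:
    if isinstance(col, int):
        if header_row is not None and col >= len(header_row):
            raise ValueError(f"column index {col} out of range for header {header_row}")
        return col
    if header_row is None:
        raise ValueError(f"named column {col!r} requires header=True")
    try:
        return header_row.index(col)
    except ValueError:
        raise ValueError(f"column {col!r} not found in header {header_row}") from None


def parse_synonym_table(source, spec: SynonymTableSpec | None = None):
    """Read ``(name, identifier)`` pairs from a delimited table.

    Returns ``(pairs, skipped)`` where ``skipped`` counts rows with an
    empty name or identifier field.
    """
    if spec is None:
        spec = SynonymTableSpec()
    fh, should_close = _open_text(source)
    try:
        reader = csv.reader(fh, delimiter=spec.delimiter)
        header_row = next(reader, None) if spec.header else None
        if spec.header and header_row is None:
            raise ValueError("table declared a header but the file is empty")
        id_idx = _resolve_column(spec.id_column, header_row, spec)
        name_idx = _resolve_column(spec.name_column, header_row, spec)
        pairs: list[tuple[str, str]] = []
        skipped = 0
        for row in reader:
            if not row:
                continue
            if max(id_idx, name_idx) >= len(row):
                skipped += 1
                continue
            identifier = row[id_idx].strip()
            name = row[name_idx].strip()
            if not identifier or not name:
                skipped += 1
                continue
            pairs.append((name, identifier))
        return pairs, skipped
    finally:
        if should_close:
            fh.close()


def load_gold(source, delimiter: str = "\t") -> list[GoldStandardRecord]:
    """Read two-column gold records; ``NONE`` in column 2 marks a negative.

    Malformed rows (wrong column count or empty fields) abort the load
    with a :class:`GoldFormatError` listing the offending line numbers.
    """
    fh, should_close = _open_text(source)
    try:
        records: list[GoldStandardRecord] = []
        bad_lines: list[int] = []
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), 1):
            if not row:
                continue
            if len(row) != 2 or not row[0].strip() or not row[1].strip():
                bad_lines.append(lineno)
                continue
            query, expected = row[0].strip(), row[1].strip()
            records.append(
                GoldStandardRecord(
                    query=query,
                    expected=None if expected == NEGATIVE_MARKER else expected,
                )
            )
        if bad_lines:
            raise GoldFormatError(
                f"malformed gold-standard rows at lines {bad_lines}", bad_lines
            )
        return records
    finally:
        if should_close:
            fh.close()


def load_queries(source) -> list[str]:
    """Read a plain-text query list, one name per line; blank lines skipped."""
    fh, should_close = _open_text(source)
    try:
        return [line.strip() for line in fh if line.strip()]
    finally:
        if should_close:
            fh.close()
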