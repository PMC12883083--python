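"""Tolerant GEDCOM reading, normalization to 5.5.1, writing, and workspace extensions.

The parser accepts the common dialects in circulation (5.5, 5.5.1, lenient 7.0
headers) and never raises as long as at least one level-0 record can be read.
Normalization rewrites a parsed document into a single canonical 5.5.1 byte
form so that ``normalize`` is idempotent at the byte level.

Workspace metadata (layout coordinates, zoom, viewport, bookmarks, history and
DNA matches) is round-tripped through underscore extension tags: per-individual
``_POS x y`` lines plus one level-0 ``_OMAPS`` record. Readers that ignore
underscore tags see a plain 5.5.1 file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

from ._util import natural_key

__all__ = [
    "Dialect",
    "GedcomLine",
    "GedcomRecord",
    "GedcomDocument",
    "ParseReport",
    "WorkspaceMeta",
    "GedcomError",
    "parse_gedcom",
    "normalize",
    "normalize_with_report",
    "write_gedcom",
    "extract_workspace",
    "read_matches_tsv",
    "write_matches_tsv",
]


class GedcomError(ValueError):
    """Raised when the input cannot be interpreted as GEDCOM at all."""


class Dialect(str, Enum):
    v55 = "5.5"
    v551 = "5.5.1"
    v7 = "7.0"
    unknown = "unknown"


@dataclass
class GedcomLine:
    level: int
    xref_id: Optional[str]
    tag: str
    value: Optional[str]
    line_no: int


@dataclass
class GedcomRecord:
    """One node of a GEDCOM record tree."""

    tag: str
    xref_id: Optional[str] = None
    value: Optional[str] = None
    children: list["GedcomRecord"] = field(default_factory=list)
    line_no: int = 0

    def find(self, tag: str) -> Optional["GedcomRecord"]:
        for c in self.children:
            if c.tag == tag:
                return c
        return None

    def find_all(self, tag: str) -> list["GedcomRecord"]:
        return [c for c in self.children if c.tag == tag]

    def get(self, *tags: str) -> Optional[str]:
        """Value at a nested tag path, e.g. rec.get("BIRT", "DATE")."""
        node = self
        for t in tags:
            node = node.find(t)
            if node is None:
                return None
        return node.value

    def copy(self) -> "GedcomRecord":
        return GedcomRecord(
            self.tag, self.xref_id, self.value, [c.copy() for c in self.children], self.line_no
        )


@dataclass
class GedcomDocument:
    records: list[GedcomRecord] = field(default_factory=list)
    source_dialect: Dialect = Dialect.unknown
    encoding: str = "UTF-8"

    def record(self, xref_id: str) -> Optional[GedcomRecord]:
        for r in self.records:
            if r.xref_id == xref_id:
                return r
        return None

    def by_tag(self, tag: str) -> list[GedcomRecord]:
        return [r for r in self.records if r.tag == tag]

    def xrefs(self) -> set[str]:
        return {r.xref_id for r in self.records if r.xref_id}


@dataclass
class ParseReport:
    warnings: list[tuple[int, str, str]] = field(default_factory=list)
    repaired_count: int = 0
    dropped_count: int = 0
    kept_count: int = 0  # lines incorporated (tree nodes + merged CONC/CONT)

    def warn(self, line_no: int, code: str, message: str) -> None:
        self.warnings.append((line_no, code, message))


@dataclass
class WorkspaceMeta:
    positions: dict[str, tuple[int, int]] = field(default_factory=dict)
    zoom: float = 1.0
    viewport: tuple[int, int] = (0, 0)
    bookmarks: list[str] = field(default_factory=list)
    history: list[str] = field(default_factory=list)
    matches: list[tuple[str, float]] = field(default_factory=list)


# level [@xref@] TAG [value] -- tolerant: leading blanks, lowercase tags, tabs
_LINE_RE = re.compile(r"^\s*(\d+)\s+(?:(@[^@\s]+@)\s+)?([A-Za-z0-9_]+)(?:[ \t](.*))?$")

_POINTER_TAGS = {"FAMC", "FAMS", "CHIL", "HUSB", "WIFE", "SUBM", "ALIA", "ASSO"}


def _decode(source: bytes) -> tuple[str, str]:
    if source.startswith(b"\xef\xbb\xbf"):
        return source.decode("utf-8-sig"), "UTF-8"
    if source.startswith(b"\xff\xfe") or source.startswith(b"\xfe\xff"):
        return source.decode("utf-16"), "UTF-16"
    try:
        return source.decode("utf-8"), "UTF-8"
    except UnicodeDecodeError:
        # ANSEL and friends: latin-1 never fails; fidelity traded for tolerance
        return source.decode("latin-1"), "LATIN-1"


def parse_gedcom(source) -> tuple[GedcomDocument, ParseReport]:
    """Parse text or bytes into a record forest, repairing what can be repaired.

    Raises :class:`GedcomError` only when no level-0 record is present.
    """
    report = ParseReport()
    if isinstance(source, bytes):
        text, encoding = _decode(source)
    else:
        text, encoding = source, "UTF-8"
    if not text.strip():
        raise GedcomError("empty input: not a GEDCOM file")

    records: list[GedcomRecord] = []
    stack: list[GedcomRecord] = []  # stack[i] is the open node at level i
    for line_no, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        m = _LINE_RE.match(raw)
        if m is None:
            report.dropped_count += 1
            report.warn(line_no, "unparseable_line", f"cannot parse: {raw[:60]!r}")
            continue
        level = int(m.group(1))
        xref, tag, value = m.group(2), m.group(3).upper(), m.group(4)
        if value == "":
            value = None

        if level > 0 and not stack:
            report.dropped_count += 1
            report.warn(line_no, "orphan_line", "non-zero level before any record")
            continue
        if level > len(stack):
            # level jump >1: clamp to parent+1
            report.repaired_count += 1
            report.warn(line_no, "level_jump", f"level {level} clamped to {len(stack)}")
            level = len(stack)

        if tag in ("CONC", "CONT") and level > 0:
            parent = stack[level - 1]
            sep = "" if tag == "CONC" else "\n"
            parent.value = (parent.value or "") + sep + (value or "")
            report.kept_count += 1
            del stack[level:]
            continue

        report.kept_count += 1
        node = GedcomRecord(tag=tag, xref_id=xref, value=value, line_no=line_no)
        if level == 0:
            records.append(node)
            stack = [node]
        else:
            stack[level - 1].children.append(node)
            del stack[level:]
            stack.append(node)

    if not records:
        raise GedcomError("no level-0 record found: not a GEDCOM file")

    doc = GedcomDocument(records=records, encoding=encoding)
    doc.source_dialect = _detect_dialect(doc)
    _check_pointers(doc, report)
    return doc, report


def _detect_dialect(doc: GedcomDocument) -> Dialect:
    for head in doc.by_tag("HEAD"):
        vers = head.get("GEDC", "VERS")
        if vers:
            if vers.startswith("5.5.1"):
                return Dialect.v551
            if vers.startswith("5.5"):
                return Dialect.v55
            if vers.startswith("7"):
                return Dialect.v7
    return Dialect.unknown


def _iter_lines(rec: GedcomRecord, level: int = 0) -> Iterable[tuple[int, GedcomRecord]]:
    yield level, rec
    for c in rec.children:
        yield from _iter_lines(c, level + 1)


def _check_pointers(doc: GedcomDocument, report: ParseReport) -> None:
    defined = doc.xrefs()
    for rec in doc.records:
        for _, node in _iter_lines(rec):
            if node.tag in _POINTER_TAGS and node.value and node.value.startswith("@"):
                if node.value not in defined:
                    report.warn(node.line_no, "dangling_pointer",
                                f"{node.tag} points to undefined {node.value}")


# ---------------------------------------------------------------------------
# normalization

_MONTHS = ["JAN", "FEB", "MAR", "APR", "MAY", "JUN",
           "JUL", "AUG", "SEP", "OCT", "NOV", "DEC"]
_MONTH_NAMES = {m: i + 1 for i, m in enumerate(_MONTHS)}
_MONTH_NAMES.update({
    "JANUARY": 1, "FEBRUARY": 2, "MARCH": 3, "APRIL": 4, "JUNE": 6, "JULY": 7,
    "AUGUST": 8, "SEPTEMBER": 9, "OCTOBER": 10, "NOVEMBER": 11, "DECEMBER": 12,
})
_DATE_QUALIFIERS = ("ABT", "BEF", "AFT", "EST", "CAL")

_TAG_SYNONYMS = {
    "EMAI": "EMAIL",
    "EMAL": "EMAIL",
    "_EMAIL": "EMAIL",
    "URL": "WWW",
    "_URL": "WWW",
    "_WEB": "WWW",
}


def canonical_date(value: str) -> Optional[str]:
    """Re-express a date string as ``[QUAL ]D MON YYYY`` when parseable."""
    v = value.strip()
    qual = ""
    up = v.upper()
    for q in _DATE_QUALIFIERS:
        if up.startswith(q + " "):
            qual = q + " "
            v = v[len(q) + 1:].strip()
            up = v.upper()
            break
    if up.startswith("BET ") or up.startswith("FROM ") or up.startswith("TO "):
        return None  # ranges preserved as-is
    m = re.fullmatch(r"(\d{3,4})-(\d{1,2})-(\d{1,2})", v)
    if m:
        y, mo, d = int(m.group(1)), int(m.group(2)), int(m.group(3))
        if 1 <= mo <= 12 and 1 <= d <= 31:
            return f"{qual}{d} {_MONTHS[mo - 1]} {y}"
        return None
    m = re.fullmatch(r"(\d{1,2})[ /.-]([A-Za-z]+)[ /.-](\d{3,4})", v)
    if m:
        mo = _MONTH_NAMES.get(m.group(2).upper())
        if mo:
            return f"{qual}{int(m.group(1))} {_MONTHS[mo - 1]} {int(m.group(3))}"
        return None
    m = re.fullmatch(r"([A-Za-z]+)[ /.-](\d{3,4})", v)
    if m:
        mo = _MONTH_NAMES.get(m.group(1).upper())
        if mo:
            return f"{qual}{_MONTHS[mo - 1]} {int(m.group(2))}"
        return None
    if re.fullmatch(r"\d{3,4}", v):
        return f"{qual}{int(v)}"
    m = re.fullmatch(r"(\d{1,2}) ([A-Za-z]{3,}) (\d{3,4})", v)
    if m and m.group(2).upper() in _MONTH_NAMES:
        return f"{qual}{int(m.group(1))} {_MONTHS[_MONTH_NAMES[m.group(2).upper()] - 1]} {int(m.group(3))}"
    return None


_RECORD_ORDER = {"HEAD": 0, "SUBN": 1, "SUBM": 1, "INDI": 2, "FAM": 3}


def _record_sort_key(rec: GedcomRecord):
    rank = _RECORD_ORDER.get(rec.tag, 4)
    if rec.tag == "_OMAPS":
        rank = 5
    if rec.tag == "TRLR":
        rank = 6
    return (rank, rec.tag if rank == 4 else "", natural_key(rec.xref_id or ""))


def normalize_with_report(doc: GedcomDocument) -> tuple[GedcomDocument, ParseReport]:
    """Rewrite a parsed document in canonical 5.5.1 form (idempotent)."""
    report = ParseReport()
    records = [r.copy() for r in doc.records if r.tag not in ("HEAD", "TRLR")]
    defined = {r.xref_id for r in records if r.xref_id}

    def walk(node: GedcomRecord, parent_tag: str) -> None:
        node.tag = _TAG_SYNONYMS.get(node.tag, node.tag)
        kept = []
        for c in node.children:
            if (c.tag in _POINTER_TAGS and c.value and c.value.startswith("@")
                    and c.value not in defined):
                report.dropped_count += 1
                report.warn(c.line_no, "dangling_pointer_dropped",
                            f"dropped {c.tag} {c.value}")
                continue
            kept.append(c)
        node.children = kept
        for c in node.children:
            if c.tag == "DATE":
                canon = canonical_date(c.value or "")
                if canon is not None:
                    if canon != c.value:
                        report.repaired_count += 1
                    c.value = canon
                elif c.value:
                    report.warn(c.line_no, "date_unparsed",
                                f"date kept verbatim: {c.value!r}")
            walk(c, node.tag)

    for rec in records:
        walk(rec, "")

    head = GedcomRecord("HEAD")
    # keep source-system metadata from the original header, minus what we rewrite
    for orig in doc.by_tag("HEAD"):
        for c in orig.children:
            if c.tag not in ("GEDC", "CHAR", "CONC", "CONT"):
                head.children.append(c.copy())
    gedc = GedcomRecord("GEDC")
    gedc.children.append(GedcomRecord("VERS", value="5.5.1"))
    gedc.children.append(GedcomRecord("FORM", value="LINEAGE-LINKED"))
    head.children.append(gedc)
    head.children.append(GedcomRecord("CHAR", value="UTF-8"))

    out = [head] + sorted(records, key=_record_sort_key) + [GedcomRecord("TRLR")]
    return GedcomDocument(records=out, source_dialect=Dialect.v551, encoding="UTF-8"), report


def normalize(doc: GedcomDocument) -> GedcomDocument:
    return normalize_with_report(doc)[0]


# ---------------------------------------------------------------------------
# writing

def _emit(node: GedcomRecord, level: int, out: list[str]) -> None:
    value = node.value
    head_val, *rest = (value.split("\n") if value is not None else [None])
    parts = [str(level)]
    if node.xref_id and level == 0:
        parts.append(node.xref_id)
    parts.append(node.tag)
    if head_val not in (None, ""):
        parts.append(head_val)
    out.append(" ".join(parts))
    for cont in rest:
        out.append(f"{level + 1} CONT {cont}" if cont else f"{level + 1} CONT")
    for c in node.children:
        _emit(c, level + 1, out)


def write_gedcom(doc: GedcomDocument, meta: Optional[WorkspaceMeta] = None) -> str:
    """Serialize; when ``meta`` is given, embed workspace extension tags."""
    records = [r.copy() for r in doc.records]
    if meta is not None:
        known = {r.xref_id for r in records if r.xref_id}
        for nid in meta.positions:
            if nid not in known:
                raise GedcomError(f"workspace meta references unknown node {nid}")
        for seq in (meta.bookmarks, meta.history, [m[0] for m in meta.matches]):
            for nid in seq:
                if nid not in known:
                    raise GedcomError(f"workspace meta references unknown node {nid}")
        for rec in records:
            if rec.xref_id in meta.positions:
                rec.children = [c for c in rec.children if c.tag != "_POS"]
                x, y = meta.positions[rec.xref_id]
                rec.children.append(
                    GedcomRecord("_POS", value=f"{int(round(x))} {int(round(y))}"))
        records = [r for r in records if r.tag != "_OMAPS"]
        omaps = GedcomRecord("_OMAPS")
        omaps.children.append(GedcomRecord("_ZOOM", value=repr(float(meta.zoom))))
        vx, vy = meta.viewport
        omaps.children.append(GedcomRecord("_VIEW", value=f"{int(round(vx))} {int(round(vy))}"))
        for b in meta.bookmarks:
            omaps.children.append(GedcomRecord("_BOOK", value=b))
        for h in meta.history:
            omaps.children.append(GedcomRecord("_HIST", value=h))
        for mid, cm in meta.matches:
            omaps.children.append(GedcomRecord("_MATCH", value=f"{mid} {cm:g}"))
        trlr = [i for i, r in enumerate(records) if r.tag == "TRLR"]
        records.insert(trlr[0] if trlr else len(records), omaps)

    out: list[str] = []
    for rec in records:
        _emit(rec, 0, out)
    return "\n".join(out) + "\n"


def extract_workspace(doc: GedcomDocument) -> Optional[WorkspaceMeta]:
    """Recover workspace metadata from extension tags, or None when absent."""
    meta = WorkspaceMeta()
    found = False
    for rec in doc.records:
        if rec.xref_id:
            for pos in rec.find_all("_POS"):
                try:
                    x, y = (pos.value or "").split()
                    meta.positions[rec.xref_id] = (int(x), int(y))
                    found = True
                except ValueError:
                    continue  # malformed payload: skip, never crash
    for omaps in doc.by_tag("_OMAPS"):
        found = True
        for c in omaps.children:
            try:
                if c.tag == "_ZOOM" and c.value:
                    z = float(c.value)
                    if z > 0:
                        meta.zoom = z
                elif c.tag == "_VIEW" and c.value:
                    vx, vy = c.value.split()
                    meta.viewport = (int(vx), int(vy))
                elif c.tag == "_BOOK" and c.value:
                    meta.bookmarks.append(c.value)
                elif c.tag == "_HIST" and c.value:
                    meta.history.append(c.value)
                elif c.tag == "_MATCH" and c.value:
                    mid, cm = c.value.rsplit(" ", 1)
                    meta.matches.append((mid, float(cm)))
            except ValueError:
                continue
    return meta if found else None


# ---------------------------------------------------------------------------
# matches sidecar (TSV: individual_id <TAB> shared_cM)

def read_matches_tsv(text: str) -> list[tuple[str, float]]:
    out = []
    for ln in text.splitlines():
        ln = ln.strip()
        if not ln or ln.lower().startswith("individual_id"):
            continue
        ind, cm = ln.split("\t")
        out.append((ind, float(cm)))
    return out


def write_matches_tsv(matches: list[tuple[str, float]]) -> str:
    lines = ["individual_id\tshared_cM"]
    lines += [f"{mid}\t{cm:g}" for mid, cm in matches]
    return "\n".join(lines) + "\n"
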