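"""Bipartite individual/family pedigree graph and traversal primitives.

Individuals (INDI) and families (FAM) are the two node classes; edges exist
only between them. A full generational move is two half-edges:
``U`` = child -> child-of family -> partner (one generation up),
``D`` = partner -> partner-in family -> child (one generation down),
``S`` = partner step inside one family (zero generations).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from ._util import natural_key
from .gedcom_io import GedcomDocument

__all__ = [
    "Sex",
    "LivingStatus",
    "ChildLink",
    "IndividualNode",
    "FamilyNode",
    "PedigreeGraph",
    "MoveKind",
    "Move",
    "Match",
    "CycleError",
    "build_graph",
    "components",
    "step",
    "inverse",
    "to_edgelist",
]


class Sex(str, Enum):
    M = "M"
    F = "F"
    U = "U"


class LivingStatus(str, Enum):
    known_alive = "known_alive"
    known_dead = "known_dead"
    inferred_dead = "inferred_dead"
    unknown = "unknown"


class ChildLink(str, Enum):
    birth = "birth"
    adopted = "adopted"
    foster = "foster"
    unknown = "unknown"


class MoveKind(str, Enum):
    U = "U"
    D = "D"
    S = "S"


@dataclass(frozen=True)
class Move:
    kind: MoveKind
    half_edge: bool = False


@dataclass(frozen=True)
class Match:
    """A tested relative present in the graph with total shared centimorgans."""

    individual_id: str
    shared_cM: float

    def __post_init__(self):
        if self.shared_cM < 0:
            raise ValueError("shared_cM must be non-negative")


@dataclass
class IndividualNode:
    id: str
    given: str = ""
    surname: str = ""
    sex: Sex = Sex.U
    birth_year: Optional[int] = None
    death_year: Optional[int] = None
    living_status: LivingStatus = LivingStatus.unknown
    notes: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.birth_year is not None and self.death_year is not None
                and self.death_year < self.birth_year):
            raise ValueError(f"{self.id}: death year before birth year")


@dataclass
class FamilyNode:
    id: str
    partner_ids: list[str] = field(default_factory=list)
    child_ids: list[str] = field(default_factory=list)
    child_link_types: dict[str, ChildLink] = field(default_factory=dict)


@dataclass
class PedigreeGraph:
    individuals: dict[str, IndividualNode] = field(default_factory=dict)
    families: dict[str, FamilyNode] = field(default_factory=dict)
    child_of: dict[str, list[str]] = field(default_factory=dict)   # FAMC
    partner_in: dict[str, list[str]] = field(default_factory=dict)  # FAMS

    def is_individual(self, node_id: str) -> bool:
        return node_id in self.individuals

    def is_family(self, node_id: str) -> bool:
        return node_id in self.families

    def parents(self, indiv_id: str, include_nonbiological: bool = False) -> list[str]:
        out: list[str] = []
        for fid in self._birth_families(indiv_id, include_nonbiological):
            for p in self.families[fid].partner_ids:
                if p not in out:
                    out.append(p)
        return out

    def _birth_families(self, indiv_id: str, include_nonbiological: bool = False) -> list[str]:
        fams = []
        for fid in self.child_of.get(indiv_id, []):
            fam = self.families.get(fid)
            if fam is None:
                continue
            link = fam.child_link_types.get(indiv_id, ChildLink.birth)
            if include_nonbiological or link in (ChildLink.birth, ChildLink.unknown):
                fams.append(fid)
        return fams

    def children(self, indiv_id: str, include_nonbiological: bool = False) -> list[str]:
        out: list[str] = []
        for fid in self.partner_in.get(indiv_id, []):
            fam = self.families[fid]
            for c in fam.child_ids:
                link = fam.child_link_types.get(c, ChildLink.birth)
                if not include_nonbiological and link not in (ChildLink.birth, ChildLink.unknown):
                    continue
                if c not in out:
                    out.append(c)
        return out

    def all_node_ids(self) -> list[str]:
        return list(self.individuals) + list(self.families)


class CycleError(ValueError):
    """An individual is its own ancestor; the data is corrupt."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("ancestral cycle detected: " + " -> ".join(cycle))


_YEAR_RE = re.compile(r"(\d{3,4})")
_APPROX = ("ABT", "BEF", "AFT", "EST", "CAL")


def _extract_year(date_value: Optional[str]) -> tuple[Optional[int], bool]:
    if not date_value:
        return None, False
    approx = any(date_value.upper().startswith(q) for q in _APPROX)
    years = _YEAR_RE.findall(date_value)
    if not years:
        return None, approx
    return int(years[-1]), approx


_PEDI_MAP = {
    "birth": ChildLink.birth,
    "adopted": ChildLink.adopted,
    "foster": ChildLink.foster,
}


def build_graph(doc: GedcomDocument) -> PedigreeGraph:
    """Map INDI/FAM records and their pointers onto a :class:`PedigreeGraph`."""
    g = PedigreeGraph()
    pedi: dict[tuple[str, str], ChildLink] = {}

    for rec in doc.by_tag("INDI"):
        if not rec.xref_id:
            continue
        given, surname = _parse_name(rec.get("NAME") or "")
        sex_val = (rec.get("SEX") or "U").strip().upper()[:1]
        sex = Sex(sex_val) if sex_val in ("M", "F") else Sex.U
        birth_year, birth_approx = _extract_year(rec.get("BIRT", "DATE"))
        deat = rec.find("DEAT")
        death_year, death_approx = _extract_year(rec.get("DEAT", "DATE"))
        if birth_year and death_year and death_year < birth_year:
            death_year = None  # corrupt pair: keep birth, drop death year
        notes = "\n".join(n.value or "" for n in rec.find_all("NOTE"))
        ind = IndividualNode(
            id=rec.xref_id, given=given, surname=surname, sex=sex,
            birth_year=birth_year, death_year=death_year, notes=notes,
        )
        ind.attrs["birth_approx"] = birth_approx
        ind.attrs["death_approx"] = death_approx
        ind.attrs["has_death_record"] = deat is not None
        if deat is not None:
            ind.living_status = LivingStatus.known_dead
        g.individuals[ind.id] = ind
        for famc in rec.find_all("FAMC"):
            if famc.value:
                g.child_of.setdefault(ind.id, [])
                if famc.value not in g.child_of[ind.id]:
                    g.child_of[ind.id].append(famc.value)
                p = famc.find("PEDI")
                if p is not None and p.value:
                    pedi[(ind.id, famc.value)] = _PEDI_MAP.get(
                        p.value.strip().lower(), ChildLink.unknown)
        for fams in rec.find_all("FAMS"):
            if fams.value:
                g.partner_in.setdefault(ind.id, [])
                if fams.value not in g.partner_in[ind.id]:
                    g.partner_in[ind.id].append(fams.value)

    for rec in doc.by_tag("FAM"):
        if not rec.xref_id:
            continue
        fam = FamilyNode(id=rec.xref_id)
        for tag in ("HUSB", "WIFE"):
            for p in rec.find_all(tag):
                if p.value and p.value in g.individuals and p.value not in fam.partner_ids:
                    fam.partner_ids.append(p.value)
        for c in rec.find_all("CHIL"):
            if c.value and c.value in g.individuals and c.value not in fam.child_ids:
                fam.child_ids.append(c.value)
        g.families[fam.id] = fam

    # reconcile the two pointer directions (FAMC/FAMS vs CHIL/HUSB/WIFE)
    for iid, fams in list(g.child_of.items()):
        g.child_of[iid] = [f for f in fams if f in g.families]
        for fid in g.child_of[iid]:
            if iid not in g.families[fid].child_ids:
                g.families[fid].child_ids.append(iid)
        if not g.child_of[iid]:
            del g.child_of[iid]
    for iid, fams in list(g.partner_in.items()):
        g.partner_in[iid] = [f for f in fams if f in g.families]
        for fid in g.partner_in[iid]:
            if iid not in g.families[fid].partner_ids:
                g.families[fid].partner_ids.append(iid)
        if not g.partner_in[iid]:
            del g.partner_in[iid]
    for fam in g.families.values():
        for c in fam.child_ids:
            g.child_of.setdefault(c, [])
            if fam.id not in g.child_of[c]:
                g.child_of[c].append(fam.id)
        for p in fam.partner_ids:
            g.partner_in.setdefault(p, [])
            if fam.id not in g.partner_in[p]:
                g.partner_in[p].append(fam.id)
        fam.child_ids = [c for c in fam.child_ids if c not in fam.partner_ids]
        for (cid, fid), link in pedi.items():
            if fid == fam.id:
                fam.child_link_types[cid] = link

    _check_acyclic(g)
    return g


def _check_acyclic(g: PedigreeGraph) -> None:
    WHITE, GREY, BLACK = 0, 1, 2
    color = {i: WHITE for i in g.individuals}
    for start in g.individuals:
        if color[start] != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        path: list[str] = []
        while stack:
            node, idx = stack.pop()
            if idx == 0:
                color[node] = GREY
                path.append(node)
            parents = g.parents(node, include_nonbiological=True)
            if idx < len(parents):
                stack.append((node, idx + 1))
                nxt = parents[idx]
                if color.get(nxt) == GREY:
                    cycle = path[path.index(nxt):] + [nxt]
                    raise CycleError(cycle)
                if color.get(nxt) == WHITE:
                    stack.append((nxt, 0))
            else:
                color[node] = BLACK
                path.pop()


def _neighbors(g: PedigreeGraph, node_id: str) -> list[str]:
    if g.is_individual(node_id):
        return g.child_of.get(node_id, []) + g.partner_in.get(node_id, [])
    fam = g.families[node_id]
    return fam.partner_ids + fam.child_ids


def components(g: PedigreeGraph) -> list[set[str]]:
    """Undirected connected components, largest first, ties by smallest id."""
    seen: set[str] = set()
    comps: list[set[str]] = []
    for start in sorted(g.all_node_ids(), key=natural_key):
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        while queue:
            node = queue.pop()
            for nb in _neighbors(g, node):
                if nb not in comp:
                    comp.add(nb)
                    queue.append(nb)
        seen |= comp
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), natural_key(min(c, key=natural_key))))
    return comps


def step(g: PedigreeGraph, node_id: str, move: Move,
         include_nonbiological: bool = False) -> list[str]:
    """All nodes reachable by one move; empty list at a frontier."""
    if not (g.is_individual(node_id) or g.is_family(node_id)):
        raise KeyError(node_id)
    kind = move.kind
    if g.is_family(node_id):
        fam = g.families[node_id]
        if kind == MoveKind.U:
            return sorted(fam.partner_ids, key=natural_key)
        if kind == MoveKind.D:
            return sorted(fam.child_ids, key=natural_key)
        return []
    if kind == MoveKind.U:
        fams = g._birth_families(node_id, include_nonbiological)
        if move.half_edge:
            return sorted(fams, key=natural_key)
        return sorted(g.parents(node_id, include_nonbiological), key=natural_key)
    if kind == MoveKind.D:
        fams = g.partner_in.get(node_id, [])
        if move.half_edge:
            return sorted(fams, key=natural_key)
        return sorted(g.children(node_id, include_nonbiological), key=natural_key)
    # S: co-partners inside any shared family
    out = set()
    for fid in g.partner_in.get(node_id, []):
        out |= {p for p in g.families[fid].partner_ids if p != node_id}
    return sorted(out, key=natural_key)


def inverse(move: Move) -> Move:
    if move.kind == MoveKind.U:
        return Move(MoveKind.D, move.half_edge)
    if move.kind == MoveKind.D:
        return Move(MoveKind.U, move.half_edge)
    return move


def to_edgelist(g: PedigreeGraph) -> str:
    """Debug export: one ``INDI<->FAM role`` edge per line."""
    lines = []
    for fid in sorted(g.families, key=natural_key):
        fam = g.families[fid]
        for p in sorted(fam.partner_ids, key=natural_key):
            lines.append(f"{p}\t{fid}\tpartner")
        for c in fam.child_ids:
            lines.append(f"{c}\t{fid}\tchild")
    return "\n".join(lines) + ("\n" if lines else "")


def _parse_name(name_value: str) -> tuple[str, str]:
    m = re.match(r"([^/]*)(?:/([^/]*)/)?(.*)", name_value.strip())
    if not m:
        return name_value.strip(), ""
    given = (m.group(1) or "").strip()
    surname = (m.group(2) or "").strip()
    trailing = (m.group(3) or "").strip()
    if trailing and not surname:
        surname = trailing
    return given, surname
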