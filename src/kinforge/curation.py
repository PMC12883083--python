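"""Mortality inference, living-person redaction, and surname connectors.

Mortality follows three rules in precedence order: an explicit death record;
a descendant aged 85 or older found within five generations; a 110-year cap
on the individual's own age. Redaction is deny-by-default: anyone not known
or inferred dead is displayed as "Living" with birth details suppressed, as
a view over the data — the underlying graph keeps the originals.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from ._util import jaro_winkler, natural_key, normalize_surname
from .gedcom_io import GedcomDocument, GedcomRecord
from .pedigree_graph import PedigreeGraph

__all__ = [
    "MortalityStatus",
    "MortalityEvidence",
    "MortalityInference",
    "SurnameLink",
    "infer_mortality",
    "redact",
    "redact_document",
    "surname_connectors",
    "DESCENDANT_DEPTH_LIMIT",
    "OLD_DESCENDANT_AGE",
    "MAX_LIFESPAN_YEARS",
]

DESCENDANT_DEPTH_LIMIT = 5
OLD_DESCENDANT_AGE = 85
MAX_LIFESPAN_YEARS = 110
YEARS_PER_GENERATION = 28


class MortalityStatus(str, Enum):
    known_dead = "known_dead"
    inferred_dead = "inferred_dead"
    presumed_living = "presumed_living"
    unknown = "unknown"


class MortalityEvidence(str, Enum):
    death_record = "death_record"
    old_descendant = "old_descendant"
    birth_age_cap = "birth_age_cap"
    none = "none"


@dataclass(frozen=True)
class MortalityInference:
    individual_id: str
    status: MortalityStatus
    evidence: MortalityEvidence
    witness_id: Optional[str] = None


def _descendants_with_depth(g: PedigreeGraph, start: str,
                            max_depth: int) -> list[tuple[str, int]]:
    out = []
    seen = {start}
    frontier = [start]
    for depth in range(1, max_depth + 1):
        nxt = []
        for node in frontier:
            for c in g.children(node, include_nonbiological=True):
                if c not in seen:
                    seen.add(c)
                    out.append((c, depth))
                    nxt.append(c)
        frontier = nxt
        if not frontier:
            break
    return out


def infer_mortality(g: PedigreeGraph, reference_year: int) -> list[MortalityInference]:
    """One inference per individual, deterministic order by id."""
    out = []
    for iid in sorted(g.individuals, key=natural_key):
        ind = g.individuals[iid]
        if ind.attrs.get("has_death_record") or ind.death_year is not None:
            out.append(MortalityInference(iid, MortalityStatus.known_dead,
                                          MortalityEvidence.death_record))
            continue
        witness = None
        for desc, depth in sorted(_descendants_with_depth(g, iid, DESCENDANT_DEPTH_LIMIT),
                                  key=lambda t: (t[1], natural_key(t[0]))):
            dnode = g.individuals[desc]
            if dnode.birth_year is not None:
                age = reference_year - dnode.birth_year
            elif ind.birth_year is not None:
                # estimate from generational position below this ancestor
                age = reference_year - (ind.birth_year + YEARS_PER_GENERATION * depth)
            else:
                continue
            if age >= OLD_DESCENDANT_AGE:
                witness = desc
                break
        if witness is not None:
            out.append(MortalityInference(iid, MortalityStatus.inferred_dead,
                                          MortalityEvidence.old_descendant, witness))
            continue
        if ind.birth_year is not None:
            if reference_year - ind.birth_year >= MAX_LIFESPAN_YEARS:
                out.append(MortalityInference(iid, MortalityStatus.inferred_dead,
                                              MortalityEvidence.birth_age_cap))
            else:
                out.append(MortalityInference(iid, MortalityStatus.presumed_living,
                                              MortalityEvidence.none))
        else:
            out.append(MortalityInference(iid, MortalityStatus.unknown,
                                          MortalityEvidence.none))
    return out


_REDACT_STATUSES = (MortalityStatus.presumed_living, MortalityStatus.unknown)
REDACTED_NAME = "Living"


def _redacted_ids(inferences: list[MortalityInference]) -> set[str]:
    return {inf.individual_id for inf in inferences if inf.status in _REDACT_STATUSES}


def redact(g: PedigreeGraph, inferences: list[MortalityInference]) -> PedigreeGraph:
    """Redacted copy of the graph: same topology, display fields scrubbed for
    possibly-living individuals. The input graph is left untouched."""
    hide = _redacted_ids(inferences)
    out = PedigreeGraph(
        individuals={}, families={fid: f for fid, f in g.families.items()},
        child_of={k: list(v) for k, v in g.child_of.items()},
        partner_in={k: list(v) for k, v in g.partner_in.items()},
    )
    for iid, ind in g.individuals.items():
        if iid in hide:
            clone = type(ind)(id=iid, given=REDACTED_NAME, surname="", sex=ind.sex)
            clone.attrs = {"redacted": True}
            out.individuals[iid] = clone
        else:
            out.individuals[iid] = ind
    return out


_SUPPRESSED_TAGS = ("NAME", "BIRT", "CHR", "OCCU", "RESI", "NOTE")


def redact_document(doc: GedcomDocument,
                    inferences: list[MortalityInference]) -> GedcomDocument:
    """Redacted copy of a GEDCOM document for export."""
    hide = _redacted_ids(inferences)
    records = []
    for rec in doc.records:
        if rec.tag == "INDI" and rec.xref_id in hide:
            clone = GedcomRecord("INDI", xref_id=rec.xref_id)
            clone.children.append(GedcomRecord("NAME", value=f"{REDACTED_NAME} //"))
            for c in rec.children:
                if c.tag not in _SUPPRESSED_TAGS:
                    clone.children.append(c.copy())
            records.append(clone)
        else:
            records.append(rec.copy())
    return GedcomDocument(records=records, source_dialect=doc.source_dialect,
                          encoding=doc.encoding)


@dataclass(frozen=True)
class SurnameLink:
    component_a: int
    component_b: int
    surname_a: str
    surname_b: str
    similarity: float
    support_a: int
    support_b: int


def surname_connectors(g: PedigreeGraph, components: list[set[str]],
                       threshold: float = 0.9) -> list[SurnameLink]:
    """Shared or similar surnames across component pairs, ranked by
    similarity then by the smaller occurrence count."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if len(components) < 2:
        raise ValueError("need at least two components")
    counts: list[dict[str, int]] = []
    for comp in components:
        c: dict[str, int] = {}
        for nid in comp:
            ind = g.individuals.get(nid)
            if ind is None or not ind.surname:
                continue
            s = normalize_surname(ind.surname)
            if s:
                c[s] = c.get(s, 0) + 1
        counts.append(c)
    links = []
    for ia in range(len(components)):
        for ib in range(ia + 1, len(components)):
            for sa, na in counts[ia].items():
                for sb, nb in counts[ib].items():
                    sim = 1.0 if sa == sb else jaro_winkler(sa, sb)
                    if sim >= threshold:
                        links.append(SurnameLink(ia, ib, sa, sb, sim, na, nb))
    links.sort(key=lambda l: (-l.similarity, -min(l.support_a, l.support_b),
                              l.surname_a, l.surname_b, l.component_a, l.component_b))
    return links
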