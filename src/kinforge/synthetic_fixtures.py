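"""Seeded pedigree and test-case generators.

Everything downstream (parser fuzzing, relationship oracles, placement
recovery runs, layout invariants) is exercised on pedigrees produced here, so
no external data is ever needed. Generation is fully deterministic per seed:
the same config yields byte-identical GEDCOM output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._util import natural_key
from .cm_model import CalibrationTable, RelationshipClass, default_table
from .gedcom_io import GedcomDocument, GedcomRecord, normalize, write_matches_tsv
from .pedigree_graph import Match, PedigreeGraph, build_graph
from .relationship import relationship_paths

__all__ = ["SimConfig", "TruthManifest", "GGPSCase", "simulate_pedigree", "make_ggps_case"]

_GIVEN_M = ["James", "John", "Robert", "Michael", "William", "David", "Richard",
            "Joseph", "Thomas", "Charles", "Daniel", "Matthew", "Anthony", "Mark"]
_GIVEN_F = ["Mary", "Patricia", "Jennifer", "Linda", "Elizabeth", "Barbara",
            "Susan", "Jessica", "Sarah", "Karen", "Nancy", "Lisa", "Betty", "Helen"]
_SURNAMES = ["Smith", "Johnson", "Williams", "Brown", "Jones", "Garcia", "Miller",
             "Davis", "Rodriguez", "Martinez", "Hernandez", "Lopez", "Gonzalez",
             "Wilson", "Anderson", "Thomas", "Taylor", "Moore", "Jackson", "Martin"]


@dataclass(frozen=True)
class SimConfig:
    founders: int = 4
    generations: int = 4
    mean_children: float = 2.5
    p_remarriage: float = 0.0
    p_cousin_marriage: float = 0.0
    missing_parent_rate: float = 0.0
    seed: int = 0
    base_year: int = 1880
    years_per_generation: int = 28

    def __post_init__(self):
        for p in (self.p_remarriage, self.p_cousin_marriage, self.missing_parent_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.generations < 2:
            raise ValueError("generations must be >= 2")
        if self.mean_children <= 0 or self.founders < 1:
            raise ValueError("need positive mean_children and founders")


@dataclass
class TruthManifest:
    target_id: str
    true_relationships: dict[str, RelationshipClass]  # match id -> class (match's view)
    true_exit: tuple[str, int]                        # (node_v, remaining_moves_r)


@dataclass
class GGPSCase:
    document: GedcomDocument        # target already hidden
    full_document: GedcomDocument   # with the target, for replay checks
    matches: list[Match]
    truth: TruthManifest

    @property
    def matches_tsv(self) -> str:
        return write_matches_tsv([(m.individual_id, m.shared_cM) for m in self.matches])


class _Sim:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.people: dict[str, dict] = {}
        self.families: dict[str, dict] = {}
        self.generation: dict[str, int] = {}
        self._i = 0
        self._f = 0

    def new_person(self, sex: str, gen: int, surname: Optional[str] = None) -> str:
        self._i += 1
        pid = f"@I{self._i}@"
        pool = _GIVEN_M if sex == "M" else _GIVEN_F
        given = pool[int(self.rng.integers(len(pool)))]
        if surname is None:
            surname = _SURNAMES[int(self.rng.integers(len(_SURNAMES)))]
        year = (self.cfg.base_year + self.cfg.years_per_generation * gen
                + int(self.rng.integers(-5, 6)))
        self.people[pid] = {"given": given, "surname": surname, "sex": sex,
                            "year": year, "famc": [], "fams": []}
        self.generation[pid] = gen
        return pid

    def new_family(self, partners: list[str]) -> str:
        self._f += 1
        fid = f"@F{self._f}@"
        self.families[fid] = {"partners": list(partners), "children": []}
        for p in partners:
            self.people[p]["fams"].append(fid)
        return fid

    def marry(self, pid: str, gen: int, eligible: list[str]) -> str:
        """Create a family for pid; spouse is a cousin-marriage candidate, a
        new immigrant, or (frontier case) nobody."""
        cfg, rng = self.cfg, self.rng
        spouse: Optional[str] = None
        want_sex = "F" if self.people[pid]["sex"] == "M" else "M"
        if eligible and rng.random() < cfg.p_cousin_marriage:
            pool = [q for q in eligible
                    if self.people[q]["sex"] == want_sex
                    and not set(self.people[q]["famc"]) & set(self.people[pid]["famc"])]
            if pool:
                spouse = pool[int(rng.integers(len(pool)))]
        if spouse is None and rng.random() >= cfg.missing_parent_rate:
            spouse = self.new_person(want_sex, gen)
        return self.new_family([pid] + ([spouse] if spouse else []))

    def run(self) -> None:
        cfg, rng = self.cfg, self.rng
        cohort: list[str] = []
        for i in range(cfg.founders):
            sex = "M" if i % 2 == 0 else "F"
            cohort.append(self.new_person(sex, 0))
        couples = []
        for i in range(0, len(cohort) - 1, 2):
            couples.append(self.new_family([cohort[i], cohort[i + 1]]))

        for gen in range(1, cfg.generations):
            children: list[str] = []
            for fid in sorted(couples, key=natural_key):
                fam = self.families[fid]
                father = next((p for p in fam["partners"]
                               if self.people[p]["sex"] == "M"), None)
                surname = self.people[father]["surname"] if father else None
                n = int(rng.poisson(cfg.mean_children))
                for _ in range(n):
                    sex = "M" if rng.random() < 0.5 else "F"
                    c = self.new_person(sex, gen, surname)
                    fam["children"].append(c)
                    self.people[c]["famc"].append(fid)
                    children.append(c)
            if gen == cfg.generations - 1:
                break
            couples = []
            unmarried = list(children)
            for pid in list(children):
                if pid not in unmarried:
                    continue
                unmarried.remove(pid)
                fid = self.new_family_for(pid, gen, unmarried, couples)
            # guarantee at least one ongoing line
            if not couples and children:
                pid = children[0]
                spouse = self.new_person(
                    "F" if self.people[pid]["sex"] == "M" else "M", gen)
                couples.append(self.new_family([pid, spouse]))

    def new_family_for(self, pid, gen, unmarried, couples) -> Optional[str]:
        cfg, rng = self.cfg, self.rng
        fid = self.marry(pid, gen, unmarried)
        fam = self.families[fid]
        for q in fam["partners"]:
            if q in unmarried:
                unmarried.remove(q)
        couples.append(fid)
        if len(fam["partners"]) == 2 and rng.random() < cfg.p_remarriage:
            extra_sex = "F" if self.people[pid]["sex"] == "M" else "M"
            extra = self.new_person(extra_sex, gen)
            couples.append(self.new_family([pid, extra]))
        return fid

    def to_document(self) -> GedcomDocument:
        records = [GedcomRecord("HEAD")]
        for pid in sorted(self.people, key=natural_key):
            p = self.people[pid]
            rec = GedcomRecord("INDI", xref_id=pid)
            rec.children.append(GedcomRecord("NAME", value=f"{p['given']} /{p['surname']}/"))
            rec.children.append(GedcomRecord("SEX", value=p["sex"]))
            birt = GedcomRecord("BIRT")
            birt.children.append(GedcomRecord("DATE", value=str(p["year"])))
            rec.children.append(birt)
            for fid in p["famc"]:
                rec.children.append(GedcomRecord("FAMC", value=fid))
            for fid in p["fams"]:
                rec.children.append(GedcomRecord("FAMS", value=fid))
            records.append(rec)
        for fid in sorted(self.families, key=natural_key):
            f = self.families[fid]
            rec = GedcomRecord("FAM", xref_id=fid)
            for p in f["partners"]:
                tag = "HUSB" if self.people[p]["sex"] == "M" else "WIFE"
                rec.children.append(GedcomRecord(tag, value=p))
            for c in f["children"]:
                rec.children.append(GedcomRecord("CHIL", value=c))
            records.append(rec)
        records.append(GedcomRecord("TRLR"))
        return normalize(GedcomDocument(records=records))


def simulate_pedigree(config: SimConfig) -> tuple[GedcomDocument, PedigreeGraph]:
    """Generational pedigree with founder couples and Poisson offspring."""
    sim = _Sim(config)
    sim.run()
    if not sim.people:
        raise ValueError("configuration produced no individuals")
    doc = sim.to_document()
    return doc, build_graph(doc)


class CaseGenerationError(RuntimeError):
    """The pedigree cannot support the requested case; use a larger config."""


def _is_lineal(g: PedigreeGraph, a: str, b: str, max_depth: int = 12) -> bool:
    from .relationship import ancestor_depths
    return b in ancestor_depths(g, a, max_depth) or a in ancestor_depths(g, b, max_depth)


def make_ggps_case(config: SimConfig, n_matches: int = 3,
                   table: Optional[CalibrationTable] = None) -> GGPSCase:
    """Hide one individual, pick branch-diverse relatives as matches, and
    sample their shared cM from the true-class distributions."""
    table = table or default_table()
    doc, g = simulate_pedigree(config)
    rng = np.random.default_rng([config.seed, 104729])

    leaf_targets = [iid for iid in sorted(g.individuals, key=natural_key)
                    if not g.partner_in.get(iid)
                    and len(g.child_of.get(iid, [])) == 1
                    and len(g.families[g.child_of[iid][0]].partner_ids) == 2]
    rng.shuffle(leaf_targets)

    for target in leaf_targets:
        famc = g.child_of[target][0]
        candidates = []
        for mid in sorted(g.individuals, key=natural_key):
            if mid == target or mid in g.families[famc].child_ids \
                    or mid in g.families[famc].partner_ids:
                continue
            paths = relationship_paths(g, mid, target, max_depth=6)
            if len(paths) != 1:
                continue  # keep the ground truth unambiguous
            p = paths[0]
            if p.g_up < 1 or p.g_down < 1:
                continue  # lineal or affine: convergence degenerates
            if p.total_generations < 3 or p.total_generations > 7:
                continue
            key = (min(p.g_up, p.g_down), max(p.g_up, p.g_down), p.half)
            if key not in table.likelihood:
                continue
            candidates.append((mid, p))
        rng.shuffle(candidates)
        chosen: list[tuple[str, object]] = []
        for mid, p in candidates:
            if any(_is_lineal(g, mid, other) for other, _ in chosen):
                continue
            chosen.append((mid, p))
            if len(chosen) == n_matches:
                break
        if len(chosen) < n_matches:
            continue

        matches = []
        truth_rel = {}
        for mid, p in sorted(chosen, key=lambda t: natural_key(t[0])):
            cls = RelationshipClass(g_up=p.g_up, g_down=p.g_down, half=p.half)
            cm = table.sample_cm(cls, rng)
            matches.append(Match(individual_id=mid, shared_cM=round(cm, 1)))
            truth_rel[mid] = cls
        hidden = _hide_individual(doc, target)
        truth = TruthManifest(target_id=target, true_relationships=truth_rel,
                              true_exit=(famc, 1))
        return GGPSCase(document=hidden, full_document=doc, matches=matches, truth=truth)

    raise CaseGenerationError(
        f"no target with {n_matches} branch-diverse relatives; "
        "increase founders/generations/mean_children")


def _hide_individual(doc: GedcomDocument, target: str) -> GedcomDocument:
    records = []
    for rec in doc.records:
        if rec.xref_id == target:
            continue
        clone = rec.copy()
        if clone.tag == "FAM":
            clone.children = [c for c in clone.children if c.value != target]
        records.append(clone)
    return normalize(GedcomDocument(records=records, source_dialect=doc.source_dialect,
                                    encoding=doc.encoding))
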