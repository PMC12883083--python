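"""Placement hypothesis engine for an unknown individual given cM matches.

For every DNA match, every relationship class whose posterior at the match's
shared cM clears ``p_min`` defines a move string ``U^g_up D^g_down`` (read
from the match toward the unknown). The verified portion of that string is
walked through recorded edges in half-generation steps, emitting an exit
event at every node reached — the point where known tree data could end and
hypothetical individuals begin. Matches converging on the same exit node
``v`` with the same count of unconsumed half-generation edges ``r`` jointly
support one testable hypothesis, ranked by a lower-is-better score

    (W_eff + alpha) / (P_combined * P_t * Q_factor)

with ``W_eff`` the hypothetical-node workload (1.0 per individual, 0.5 per
family node), ``P_t = qa^up * qd^down`` over the unbuilt suffix,
``P_combined`` the geometric mean of per-match probabilities, and
``Q_factor`` the consistency reward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

from ._util import natural_key
from .cm_model import (CalibrationTable, RelationshipClass, combined_probability,
                       default_classes, default_table, equivalent_keys,
                       prob_relationship, quality_factor)
from .pedigree_graph import Match, PedigreeGraph

__all__ = [
    "GGPSConfig",
    "ExitEvent",
    "Hypothesis",
    "enumerate_exit_events",
    "intersect_events",
    "workload",
    "transition_probability",
    "score_hypotheses",
    "apply_filters",
    "run_ggps",
]


@dataclass(frozen=True)
class GGPSConfig:
    qa: float = 0.9                      # per-ascending-generation success probability
    qd: float = 0.8                      # per-descending-generation success probability
    alpha: float = 1.0                   # workload smoothing constant
    p_min: float = 0.05                  # minimum per-relationship posterior
    age_tolerance_years: int = 25
    years_per_generation: float = 28.0
    max_depth: int = 10
    min_converging_matches: int = 2
    include_nonbiological: bool = False
    trace_descent: bool = True           # walk the D-part through verified descendants
    expand_equivalents: bool = True      # trace every class sharing a passing distribution
    include_identity_hypotheses: bool = False  # keep r=0 "unknown is this person" groups

    def __post_init__(self):
        if not (0 < self.qa <= 1 and 0 < self.qd <= 1):
            raise ValueError("qa and qd must be in (0, 1]")
        if self.alpha < 0 or self.p_min < 0 or self.age_tolerance_years < 0:
            raise ValueError("alpha, p_min and age_tolerance_years must be non-negative")
        if self.years_per_generation <= 0 or self.min_converging_matches < 1:
            raise ValueError("bad years_per_generation or min_converging_matches")


@dataclass(frozen=True)
class ExitEvent:
    match_id: str
    rel_class: RelationshipClass
    node_v: str
    remaining_moves_r: int     # half-generation edge units
    consumed_up: int           # fully completed ascending moves
    remaining_up: int          # ascending moves not yet complete (partial counts)
    remaining_down: int
    p_rel: float


@dataclass
class Hypothesis:
    node_v: str
    remaining_moves_r: int
    events: list[ExitEvent] = field(default_factory=list)
    W_eff: float = 0.0
    P_t: float = 1.0
    P_combined: float = 1.0
    Q_factor: float = 1.0
    score: float = float("inf")

    @property
    def match_ids(self) -> list[str]:
        return sorted({e.match_id for e in self.events}, key=natural_key)

    def representative(self) -> ExitEvent:
        """Highest-probability event, ties broken by smallest match id."""
        return sorted(self.events, key=lambda e: (-e.p_rel, natural_key(e.match_id)))[0]


def _class_instances(rep: RelationshipClass, table: CalibrationTable,
                     expand: bool) -> list[RelationshipClass]:
    """Concrete (g_up, g_down, half) orientations to trace for one
    passing class (optionally every class sharing its distribution)."""
    keys = equivalent_keys(rep, table) if expand else [rep.key]
    seen = set()
    out = []
    for lo, hi, half in keys:
        for up, down in {(lo, hi), (hi, lo)}:
            if (up, down, half) not in seen:
                seen.add((up, down, half))
                out.append(RelationshipClass(g_up=up, g_down=down, half=half))
    out.sort(key=lambda c: (c.g_up, c.g_down, c.half))
    return out


def enumerate_exit_events(g: PedigreeGraph, match: Match, config: GGPSConfig,
                          table: Optional[CalibrationTable] = None) -> list[ExitEvent]:
    """Trace verified prefixes of each plausible move string from a match."""
    table = table or default_table()
    if match.individual_id not in g.individuals:
        raise KeyError(f"match {match.individual_id} not in graph")
    result = prob_relationship(match.shared_cM, default_classes(table), table)
    events: dict[tuple, ExitEvent] = {}
    for rep, p in sorted(result.posterior.items(), key=lambda kv: kv[0].key):
        if p < config.p_min:
            continue
        for cls in _class_instances(rep, table, config.expand_equivalents):
            if cls.g_up > config.max_depth or cls.g_down > config.max_depth:
                continue
            _trace(g, match, cls, p, config, events)
    out = list(events.values())
    out.sort(key=lambda e: (-e.remaining_moves_r, natural_key(e.node_v),
                            e.rel_class.g_up, e.rel_class.g_down, e.rel_class.half))
    return out


def _trace(g: PedigreeGraph, match: Match, cls: RelationshipClass, p_rel: float,
           config: GGPSConfig, events: dict) -> None:
    total_half = 2 * (cls.g_up + cls.g_down)
    up_half = 2 * cls.g_up

    def emit(node: str, consumed: int) -> None:
        # a partially consumed move still counts as remaining, which yields
        # r = 2*ru + 2*rd - 1 exactly when the exit lands on a FAM mid-move
        r = total_half - consumed
        cu = min(consumed, up_half) // 2
        ru = cls.g_up - cu
        rd = cls.g_down - max(0, consumed - up_half) // 2
        key = (match.individual_id, node, r, cls.g_up, cls.g_down, cls.half)
        prev = events.get(key)
        if prev is None or p_rel > prev.p_rel:
            events[key] = ExitEvent(
                match_id=match.individual_id, rel_class=cls, node_v=node,
                remaining_moves_r=r, consumed_up=cu, remaining_up=ru,
                remaining_down=rd, p_rel=p_rel)

    def ascend(node: str, consumed: int, visited: frozenset, via_fam: Optional[str]) -> None:
        emit(node, consumed)
        if consumed == up_half:
            if config.trace_descent and cls.g_down > 0:
                descend_from_apex(node, consumed, visited, via_fam)
            return
        if consumed % 2 == 0:  # at an individual: step into a child-of family
            for fid in g._birth_families(node, config.include_nonbiological):
                if fid not in visited:
                    ascend(fid, consumed + 1, visited | {fid}, via_fam)
        else:  # at a family: step to a partner
            for p in g.families[node].partner_ids:
                if p not in visited:
                    ascend(p, consumed + 1, visited | {p}, node)

    def descend_from_apex(apex: str, consumed: int, visited: frozenset,
                          ascent_fam: Optional[str]) -> None:
        # full classes turn around inside the ascent family (shared couple);
        # half classes must leave through a different family of the apex
        for fid in g.partner_in.get(apex, []):
            if cls.half:
                if fid == ascent_fam:
                    continue
            elif ascent_fam is not None and fid != ascent_fam:
                continue
            descend(fid, consumed + 1, visited | {fid})

    def descend(node: str, consumed: int, visited: frozenset) -> None:
        emit(node, consumed)
        if consumed == total_half:
            return
        if node in g.families:
            fam = g.families[node]
            for c in fam.child_ids:
                if c not in visited:
                    descend(c, consumed + 1, visited | {c})
        else:
            for fid in g.partner_in.get(node, []):
                if fid not in visited:
                    descend(fid, consumed + 1, visited | {fid})

    start = match.individual_id
    if cls.g_up > 0:
        ascend(start, 0, frozenset({start}), None)
    else:
        emit(start, 0)
        if config.trace_descent and cls.g_down > 0:
            for fid in g.partner_in.get(start, []):
                descend(fid, 1, frozenset({start, fid}))


def intersect_events(events_by_match: dict[str, list[ExitEvent]],
                     config: GGPSConfig) -> list[Hypothesis]:
    """Group events on (node_v, r); keep groups backed by enough matches."""
    groups: dict[tuple[str, int], dict[str, ExitEvent]] = {}
    for mid, events in events_by_match.items():
        for e in events:
            best = groups.setdefault((e.node_v, e.remaining_moves_r), {})
            prev = best.get(mid)
            if prev is None or e.p_rel > prev.p_rel:
                best[mid] = e
    out = []
    for (node_v, r), per_match in groups.items():
        if len(per_match) < config.min_converging_matches:
            continue
        if r == 0 and not config.include_identity_hypotheses:
            continue  # nothing to build: the unknown would be a recorded person
        events = [per_match[mid] for mid in sorted(per_match, key=natural_key)]
        out.append(Hypothesis(node_v=node_v, remaining_moves_r=r, events=events))
    out.sort(key=lambda h: (h.remaining_moves_r, natural_key(h.node_v)))
    return out


def workload(h: Hypothesis, g: PedigreeGraph) -> float:
    """Hypothetical-node workload of the unbuilt suffix: the r half-edges
    beyond v alternate FAM/INDI, shared by every converging match."""
    v_is_fam = g.is_family(h.node_v)
    w = 0.0
    for i in range(1, h.remaining_moves_r + 1):
        node_is_fam = (i % 2 == 1) != v_is_fam  # alternates away from v's type
        w += 0.5 if node_is_fam else 1.0
    return w


def transition_probability(remaining_up: int, remaining_down: int,
                           config: GGPSConfig) -> float:
    if remaining_up < 0 or remaining_down < 0:
        raise ValueError("generation counts must be non-negative")
    return config.qa ** remaining_up * config.qd ** remaining_down


def score_hypotheses(hyps: list[Hypothesis], g: PedigreeGraph, config: GGPSConfig,
                     table: Optional[CalibrationTable] = None) -> list[Hypothesis]:
    """Fill evidence terms and sort ascending by the unified score."""
    scored = []
    for h in hyps:
        rep = h.representative()
        probs = [e.p_rel for e in h.events]
        h.W_eff = workload(h, g)
        h.P_t = transition_probability(rep.remaining_up, rep.remaining_down, config)
        h.P_combined = combined_probability(probs)
        h.Q_factor = quality_factor(probs)
        h.score = (h.W_eff + config.alpha) / (h.P_combined * h.P_t * h.Q_factor)
        scored.append(h)
    scored.sort(key=lambda h: (h.score, h.remaining_moves_r, natural_key(h.node_v)))
    return scored


def _node_year(g: PedigreeGraph, node_id: str,
               years_per_generation: float) -> Optional[float]:
    if g.is_individual(node_id):
        y = g.individuals[node_id].birth_year
        return float(y) if y is not None else None
    fam = g.families[node_id]
    partner_years = [g.individuals[p].birth_year for p in fam.partner_ids
                     if g.individuals[p].birth_year is not None]
    if partner_years:
        return sum(partner_years) / len(partner_years)
    child_years = [g.individuals[c].birth_year for c in fam.child_ids
                   if g.individuals[c].birth_year is not None]
    if child_years:
        return sum(child_years) / len(child_years) - years_per_generation
    return None


def apply_filters(hyps: list[Hypothesis], g: PedigreeGraph, config: GGPSConfig,
                  target_birth_year: Optional[int] = None) -> list[Hypothesis]:
    """Age-range filter on the implied target birth year; p_min was already
    enforced per event."""
    if target_birth_year is None:
        warnings.warn("no target birth-year estimate: age filter skipped",
                      stacklevel=2)
        return list(hyps)
    out = []
    for h in hyps:
        base = _node_year(g, h.node_v, config.years_per_generation)
        if base is None:
            out.append(h)  # cannot evaluate: keep
            continue
        rep = h.representative()
        offset = rep.remaining_down - rep.remaining_up
        implied = base + offset * config.years_per_generation
        if abs(implied - target_birth_year) <= config.age_tolerance_years:
            out.append(h)
    return out


def run_ggps(g: PedigreeGraph, matches: list[Match],
             config: Optional[GGPSConfig] = None,
             table: Optional[CalibrationTable] = None,
             target_birth_year: Optional[int] = None) -> list[Hypothesis]:
    """End-to-end pipeline: trace, intersect, score, filter, rank."""
    config = config or GGPSConfig()
    table = table or default_table()
    events_by_match = {m.individual_id: enumerate_exit_events(g, m, config, table)
                       for m in matches}
    hyps = intersect_events(events_by_match, config)
    hyps = score_hypotheses(hyps, g, config, table)
    if target_birth_year is not None:
        hyps = apply_filters(hyps, g, config, target_birth_year)
    return hyps
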