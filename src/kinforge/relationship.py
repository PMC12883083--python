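"""Relationship calculator: common ancestors, exhaustive up-then-down path
enumeration (endogamy-aware), kinship naming, and MRCA path subgraphs.

A relationship path ascends ``g_up`` generations from A to an apex — either a
shared couple (reported as the family node, ``half=False``) or a single shared
individual (``half=True``) — and descends ``g_down`` generations to B. Affinal
zig-zag chains through marriages are deliberately not relationships here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from ._util import natural_key
from .pedigree_graph import PedigreeGraph

__all__ = [
    "RelationshipPath",
    "RelationshipName",
    "MrcaResult",
    "common_ancestors",
    "ancestor_depths",
    "relationship_paths",
    "name_relationship",
    "mrca_subgraph",
    "to_dot",
    "DEFAULT_MAX_DEPTH",
]

DEFAULT_MAX_DEPTH = 10


@dataclass(frozen=True)
class RelationshipPath:
    nodes: tuple[str, ...]
    g_up: int
    g_down: int
    half: bool
    apex: str

    @property
    def total_generations(self) -> int:
        return self.g_up + self.g_down


@dataclass(frozen=True)
class RelationshipName:
    label: str
    degree: int
    removal: int


def ancestor_depths(g: PedigreeGraph, start: str, max_depth: int,
                    include_nonbiological: bool = False) -> dict[str, int]:
    """Minimal U-move depth to every ancestor (self included at depth 0)."""
    depths = {start: 0}
    frontier = [start]
    for d in range(1, max_depth + 1):
        nxt = []
        for node in frontier:
            for p in g.parents(node, include_nonbiological):
                if p not in depths:
                    depths[p] = d
                    nxt.append(p)
        frontier = nxt
        if not frontier:
            break
    return depths


def common_ancestors(g: PedigreeGraph, a: str, b: str, max_depth: int = DEFAULT_MAX_DEPTH,
                     include_nonbiological: bool = False) -> list[tuple[str, int, int]]:
    """Shared ancestors with minimal depths, sorted by total depth then id."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    da = ancestor_depths(g, a, max_depth, include_nonbiological)
    db = ancestor_depths(g, b, max_depth, include_nonbiological)
    out = [(anc, da[anc], db[anc]) for anc in da.keys() & db.keys()]
    out.sort(key=lambda t: (t[1] + t[2], natural_key(t[0])))
    return out


def _ascent_chains(g: PedigreeGraph, start: str, max_up: int,
                   include_nonbiological: bool) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All ascent chains (indis, fams): indis[0] = start, fams[i] links
    indis[i] as child to indis[i+1] as partner. Includes the length-0 chain."""
    chains = [((start,), ())]
    frontier = chains[:]
    for _ in range(max_up):
        nxt = []
        for indis, fams in frontier:
            top = indis[-1]
            for fid in g._birth_families(top, include_nonbiological):
                if fid in fams:
                    continue
                for p in g.families[fid].partner_ids:
                    if p in indis:
                        continue
                    nxt.append((indis + (p,), fams + (fid,)))
        chains.extend(nxt)
        frontier = nxt
        if not frontier:
            break
    return chains


def relationship_paths(g: PedigreeGraph, a: str, b: str,
                       max_depth: int = DEFAULT_MAX_DEPTH,
                       include_nonbiological: bool = False) -> list[RelationshipPath]:
    """Every valid up-then-down kinship path between a and b, shortest first."""
    if a == b:
        raise ValueError("a and b must differ")
    chains_a = _ascent_chains(g, a, max_depth, include_nonbiological)
    chains_b = _ascent_chains(g, b, max_depth, include_nonbiological)
    paths: dict[tuple[str, ...], RelationshipPath] = {}

    def interleave_up(indis, fams):  # A, f1, i1, f2, i2, ...
        seq = [indis[0]]
        for f, i in zip(fams, indis[1:]):
            seq += [f, i]
        return seq

    # direct line: one side's chain tops out at the other individual
    for chains, g_up_side in ((chains_a, True), (chains_b, False)):
        other = b if g_up_side else a
        for indis, fams in chains:
            if len(fams) >= 1 and indis[-1] == other:
                seq = interleave_up(indis, fams)
                if not g_up_side:
                    seq = seq[::-1]
                u = len(fams) if g_up_side else 0
                d = 0 if g_up_side else len(fams)
                _add(paths, seq, u, d, half=False, apex=other if g_up_side else a)

    # collateral: join chain pairs at a shared apex family (full) or apex
    # individual reached through two different families (half)
    by_top_fam: dict[str, list] = {}
    by_top_ind: dict[str, list] = {}
    for indis, fams in chains_b:
        if fams:
            by_top_fam.setdefault(fams[-1], []).append((indis, fams))
            by_top_ind.setdefault(indis[-1], []).append((indis, fams))
    for indis_a, fams_a in chains_a:
        if not fams_a:
            continue
        u = len(fams_a)
        # full: the child below A's top ancestor shares its family with B's side
        for indis_b, fams_b in by_top_fam.get(fams_a[-1], ()):
            d = len(fams_b)
            if indis_a[-2] == indis_b[-2]:
                continue  # same child: degenerates to a shorter path
            seq = (interleave_up(indis_a[:-1], fams_a[:-1]) + [fams_a[-1]]
                   + interleave_up(indis_b[:-1], fams_b[:-1])[::-1])
            if len(set(seq)) != len(seq):
                continue
            _add(paths, seq, u, d, half=False, apex=fams_a[-1])
        # half: same top individual reached through different families
        for indis_b, fams_b in by_top_ind.get(indis_a[-1], ()):
            d = len(fams_b)
            if fams_a[-1] == fams_b[-1]:
                continue
            seq = (interleave_up(indis_a, fams_a)
                   + interleave_up(indis_b, fams_b)[::-1][1:])
            if len(set(seq)) != len(seq):
                continue
            _add(paths, seq, u, d, half=True, apex=indis_a[-1])

    out = list(paths.values())
    out.sort(key=lambda p: (p.total_generations, p.g_up, p.half,
                            len(p.nodes), tuple(natural_key(n) for n in p.nodes)))
    return out


def _add(paths, seq, g_up, g_down, half, apex):
    key = tuple(seq)
    if key not in paths:
        paths[key] = RelationshipPath(nodes=key, g_up=g_up, g_down=g_down,
                                      half=half, apex=apex)


_ORDINALS = ["", "first", "second", "third", "fourth", "fifth", "sixth",
             "seventh", "eighth", "ninth", "tenth", "eleventh", "twelfth"]


def _ordinal(n: int) -> str:
    if n < len(_ORDINALS):
        return _ORDINALS[n]
    suffix = {1: "st", 2: "nd", 3: "rd"}.get(n % 10 if n % 100 not in (11, 12, 13) else 0, "th")
    return f"{n}{suffix}"


def name_relationship(g_up: int, g_down: int, half: bool = False) -> RelationshipName:
    """Canonical English kinship term for an up/down generation count."""
    if g_up < 0 or g_down < 0:
        raise ValueError("generation counts must be non-negative")
    if g_up == 0 and g_down == 0:
        raise ValueError("(0, 0) is the same person, not a relationship")
    lo, hi = min(g_up, g_down), max(g_up, g_down)
    prefix = "half " if half else ""

    if lo == 0:
        up = g_up > 0
        if hi == 1:
            label = "parent" if up else "child"
        elif hi == 2:
            label = "grandparent" if up else "grandchild"
        else:
            label = "great-" * (hi - 2) + ("grandparent" if up else "grandchild")
        return RelationshipName(prefix + label, 0, 0)
    if g_up == 1 and g_down == 1:
        return RelationshipName(prefix + "sibling", 0, 0)
    if lo == 1:
        removal = hi - lo
        base = "aunt/uncle" if g_up > g_down else "niece/nephew"
        if removal >= 2:
            stem = "grandaunt/granduncle" if g_up > g_down else "grandniece/grandnephew"
            base = "great-" * (removal - 2) + stem
        return RelationshipName(prefix + base, 0, removal)
    degree = lo - 1
    removal = hi - lo
    label = f"{_ordinal(degree)} cousin"
    if removal == 1:
        label += " once removed"
    elif removal == 2:
        label += " twice removed"
    elif removal > 2:
        label += f" {removal} times removed"
    return RelationshipName(prefix + label, degree, removal)


@dataclass
class MrcaResult:
    status: str  # "ok" | "no_mrca_within_depth"
    subgraph: PedigreeGraph
    apexes: list[str] = field(default_factory=list)
    targets: list[str] = field(default_factory=list)

    @property
    def node_ids(self) -> set[str]:
        return set(self.subgraph.individuals) | set(self.subgraph.families)


def mrca_subgraph(g: PedigreeGraph, targets: list[str],
                  max_depth: int = DEFAULT_MAX_DEPTH,
                  include_nonbiological: bool = False) -> MrcaResult:
    """Union of ascent paths from each target to the minimal-total-depth
    ancestors shared by all targets."""
    if len(targets) < 2:
        raise ValueError("need at least two targets")
    depth_maps = [ancestor_depths(g, t, max_depth, include_nonbiological) for t in targets]
    shared = set(depth_maps[0])
    for dm in depth_maps[1:]:
        shared &= set(dm)
    shared -= set(targets)
    if not shared:
        return MrcaResult(status="no_mrca_within_depth", subgraph=PedigreeGraph(),
                          targets=list(targets))
    best_total = min(sum(dm[anc] for dm in depth_maps) for anc in shared)
    apexes = sorted((anc for anc in shared
                     if sum(dm[anc] for dm in depth_maps) == best_total),
                    key=natural_key)

    node_ids: set[str] = set(targets) | set(apexes)
    for t in targets:
        for indis, fams in _ascent_chains(g, t, max_depth, include_nonbiological):
            if indis[-1] in apexes:
                node_ids |= set(indis) | set(fams)

    sub = PedigreeGraph()
    for iid in node_ids:
        if iid in g.individuals:
            sub.individuals[iid] = g.individuals[iid]
    for fid in node_ids:
        fam = g.families.get(fid)
        if fam is None:
            continue
        kept_partners = [p for p in fam.partner_ids if p in sub.individuals]
        kept_children = [c for c in fam.child_ids if c in sub.individuals]
        sub.families[fid] = type(fam)(
            id=fid, partner_ids=kept_partners, child_ids=kept_children,
            child_link_types={c: l for c, l in fam.child_link_types.items()
                              if c in sub.individuals})
        for p in kept_partners:
            sub.partner_in.setdefault(p, []).append(fid)
        for c in kept_children:
            sub.child_of.setdefault(c, []).append(fid)
    return MrcaResult(status="ok", subgraph=sub, apexes=apexes, targets=list(targets))


def to_dot(g: PedigreeGraph, highlight: Optional[list[str]] = None,
           display_name=None) -> str:
    """Graph description (DOT) for the pedigree; families drawn as points."""
    highlight = set(highlight or [])
    if display_name is None:
        def display_name(ind):
            return f"{ind.given} {ind.surname}".strip() or ind.id
    lines = ["digraph pedigree {", "  rankdir=TB;", "  node [fontname=Helvetica];"]
    for iid in sorted(g.individuals, key=natural_key):
        ind = g.individuals[iid]
        label = display_name(ind).replace('"', r'\"')
        style = ', style=filled, fillcolor="#ffe28a"' if iid in highlight else ""
        lines.append(f'  "{iid}" [shape=box, label="{label}"{style}];')
    for fid in sorted(g.families, key=natural_key):
        lines.append(f'  "{fid}" [shape=point, width=0.1];')
        fam = g.families[fid]
        for p in fam.partner_ids:
            lines.append(f'  "{p}" -> "{fid}" [arrowhead=none];')
        for c in fam.child_ids:
            lines.append(f'  "{fid}" -> "{c}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
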