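"""Deterministic hierarchical layout with force refinement, plus tile
aggregation for the global view.

Pipeline: connected components are laid out independently (largest first) and
packed left to right. Within a component, generation layers come from
longest-ancestor-path depth so parents always sit strictly above children;
components above the large-component threshold get a two-phase treatment
where family nodes are first anchored on a widely spaced grid (600 px
horizontal, 2000 px vertical) and individuals are then placed around their
anchors. A fixed-iteration seeded force simulation (collision, springs,
centering) refines x positions while y stays clamped to per-layer bands, so
the generational hierarchy survives refinement and the result is fully
deterministic given (graph, seed, params).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._util import natural_key
from .pedigree_graph import PedigreeGraph, components as graph_components

__all__ = [
    "LayoutParams",
    "LayoutResult",
    "Tile",
    "ViewResult",
    "layout",
    "aggregate_tiles",
    "render_svg",
    "GLOBAL_VIEW_THRESHOLD",
    "LARGE_COMPONENT_THRESHOLD",
]

GLOBAL_VIEW_THRESHOLD = 500     # nodes in view beyond which tiles activate
LARGE_COMPONENT_THRESHOLD = 150


@dataclass(frozen=True)
class LayoutParams:
    h_spacing: float = 120.0          # default horizontal slot width
    v_spacing: float = 160.0          # pixels per full generation layer
    anchor_h_spacing: float = 600.0   # phase-1 family-grid spacing (large comps)
    anchor_v_spacing: float = 2000.0
    collision_radius: float = 40.0
    spring_length: float = 90.0
    iterations: int = 150
    step_size: float = 0.08
    band_halfwidth_frac: float = 0.12  # y freedom inside a layer band
    component_gutter: float = 400.0


@dataclass
class LayoutResult:
    positions: dict[str, tuple[float, float]]
    layers: dict[str, float]
    component_of: dict[str, int]
    seed: int
    anchors: Optional[dict[str, tuple[float, float]]] = None  # phase-1 FAM grid
    kinds: dict[str, str] = field(default_factory=dict)       # node id -> INDI|FAM


@dataclass(frozen=True)
class Tile:
    grid_x: int
    grid_y: int
    individual_count: int
    family_count: int
    total_entities: int
    center: tuple[float, float]
    sample_node: str


@dataclass
class ViewResult:
    status: str                      # "detail" | "global"
    nodes: list[str] = field(default_factory=list)
    tiles: list[Tile] = field(default_factory=list)


def _layers(g: PedigreeGraph, comp: set[str]) -> dict[str, float]:
    """Longest-path generation index; families sit half a layer below the
    latest of their partners."""
    indis = sorted((n for n in comp if n in g.individuals), key=natural_key)
    depth: dict[str, float] = {}

    def resolve(iid: str) -> float:
        if iid in depth:
            return depth[iid]
        depth[iid] = 0.0  # provisional; graph is acyclic so this only guards reentry
        best = 0.0
        for p in g.parents(iid, include_nonbiological=True):
            best = max(best, resolve(p) + 1.0)
        depth[iid] = best
        return best

    for iid in indis:
        resolve(iid)
    out = dict(depth)
    for fid in (n for n in comp if n in g.families):
        fam = g.families[fid]
        if fam.partner_ids:
            out[fid] = max(depth.get(p, 0.0) for p in fam.partner_ids) + 0.5
        elif fam.child_ids:
            out[fid] = min(depth.get(c, 1.0) for c in fam.child_ids) - 0.5
        else:
            out[fid] = 0.5
    # fixed point: families half a layer below their partners, children a
    # further half-layer down (late-generation marriages can push this deep)
    changed = True
    guard = 0
    while changed and guard < 50:
        changed = False
        guard += 1
        for fid in (n for n in comp if n in g.families):
            for c in g.families[fid].child_ids:
                if out.get(c, 0.0) < out[fid] + 0.5:
                    out[c] = out[fid] + 0.5
                    changed = True
        for fid in (n for n in comp if n in g.families):
            fam = g.families[fid]
            if fam.partner_ids:
                want = max(out[p] for p in fam.partner_ids) + 0.5
                if out[fid] < want:
                    out[fid] = want
                    changed = True
    return out


def _component_layout(g: PedigreeGraph, comp: set[str], params: LayoutParams,
                      rng: np.random.Generator
                      ) -> tuple[dict[str, tuple[float, float]], dict[str, float],
                                 Optional[dict[str, tuple[float, float]]]]:
    layers = _layers(g, comp)
    large = len(comp) > LARGE_COMPONENT_THRESHOLD
    vs = params.anchor_v_spacing / 2.0 if large else params.v_spacing
    pos: dict[str, list[float]] = {}
    anchors: Optional[dict[str, tuple[float, float]]] = None

    if large:
        # phase 1: family anchors on a massively spaced grid
        anchors = {}
        fams_by_layer: dict[float, list[str]] = {}
        for n in comp:
            if n in g.families:
                fams_by_layer.setdefault(layers[n], []).append(n)
        for layer, fams in sorted(fams_by_layer.items()):
            for i, fid in enumerate(sorted(fams, key=natural_key)):
                anchors[fid] = (i * params.anchor_h_spacing, layer * 2 * vs)
        for fid, (x, y) in anchors.items():
            pos[fid] = [x, y]
        # phase 2: individuals around their family anchor points
        for iid in sorted((n for n in comp if n in g.individuals), key=natural_key):
            fams = g.partner_in.get(iid, []) + g.child_of.get(iid, [])
            xs = [anchors[f][0] for f in fams if f in anchors]
            x = float(np.mean(xs)) if xs else 0.0
            pos[iid] = [x + float(rng.uniform(-40, 40)), layers[iid] * 2 * vs]
    else:
        by_layer: dict[float, list[str]] = {}
        for n in comp:
            by_layer.setdefault(layers[n], []).append(n)
        for layer, nodes in sorted(by_layer.items()):
            nodes.sort(key=natural_key)
            width = (len(nodes) - 1) * params.h_spacing
            for i, n in enumerate(nodes):
                pos[n] = [i * params.h_spacing - width / 2.0, layer * vs]

    _refine(g, comp, pos, layers, params, vs, rng)
    _enforce_collisions(g, comp, pos, layers, params)
    return {n: (p[0], p[1]) for n, p in pos.items()}, layers, anchors


def _refine(g, comp, pos, layers, params, vs, rng):
    nodes = sorted(comp, key=natural_key)
    index = {n: i for i, n in enumerate(nodes)}
    xy = np.array([pos[n] for n in nodes], dtype=float)
    xy[:, 0] += rng.uniform(-1e-3, 1e-3, len(nodes))  # seeded symmetry breaking
    band_c = np.array([layers[n] * vs for n in nodes])
    band_hw = params.band_halfwidth_frac * vs

    edges = []
    for fid in (n for n in comp if n in g.families):
        fam = g.families[fid]
        for p in fam.partner_ids:
            edges.append((index[p], index[fid]))
        for c in fam.child_ids:
            edges.append((index[fid], index[c]))
    e = np.array(edges, dtype=int) if edges else np.zeros((0, 2), dtype=int)
    min_dist = 2.0 * params.collision_radius

    for _ in range(params.iterations):
        force = np.zeros_like(xy)
        if len(e):
            delta = xy[e[:, 1]] - xy[e[:, 0]]
            dist = np.hypot(delta[:, 0], delta[:, 1]) + 1e-9
            stretch = (dist - params.spring_length) / dist
            pull = delta * stretch[:, None]
            np.add.at(force, e[:, 0], pull)
            np.add.at(force, e[:, 1], -pull)
        # pairwise collision repulsion (components stay small enough for n^2)
        diff = xy[:, None, :] - xy[None, :, :]
        d = np.hypot(diff[..., 0], diff[..., 1]) + np.eye(len(xy)) * 1e9
        overlap = np.clip(min_dist - d, 0.0, None)
        push = diff / (d[..., None]) * overlap[..., None]
        force += push.sum(axis=1) * 0.5
        # centering on the component mean x
        force[:, 0] -= 0.01 * (xy[:, 0] - xy[:, 0].mean())
        xy += params.step_size * force
        xy[:, 1] = np.clip(xy[:, 1], band_c - band_hw, band_c + band_hw)

    for n, i in index.items():
        pos[n] = [float(xy[i, 0]), float(xy[i, 1])]


def _enforce_collisions(g, comp, pos, layers, params):
    """Guarantee the collision invariant for individuals inside each band."""
    by_layer: dict[float, list[str]] = {}
    for n in comp:
        if n in g.individuals:
            by_layer.setdefault(layers[n], []).append(n)
    min_dist = params.collision_radius
    for nodes in by_layer.values():
        nodes.sort(key=lambda n: (pos[n][0], natural_key(n)))
        for a, b in zip(nodes, nodes[1:]):
            gap = pos[b][0] - pos[a][0]
            if gap < min_dist:
                pos[b][0] = pos[a][0] + min_dist


def layout(g: PedigreeGraph, seed: int = 0,
           params: Optional[LayoutParams] = None) -> LayoutResult:
    """Deterministic layout of the whole graph."""
    params = params or LayoutParams()
    comps = graph_components(g)
    positions: dict[str, tuple[float, float]] = {}
    all_layers: dict[str, float] = {}
    component_of: dict[str, int] = {}
    anchors_all: dict[str, tuple[float, float]] = {}
    x_cursor = 0.0
    for ci, comp in enumerate(comps):
        rng = np.random.default_rng([seed, ci])
        cpos, clayers, anchors = _component_layout(g, comp, params, rng)
        xs = [p[0] for p in cpos.values()]
        shift = x_cursor - (min(xs) if xs else 0.0)
        for n, (x, y) in cpos.items():
            positions[n] = (x + shift, y)
            component_of[n] = ci
            all_layers[n] = clayers[n]
        if anchors:
            for fid, (x, y) in anchors.items():
                anchors_all[fid] = (x + shift, y)
        x_cursor = (max(p[0] for p in positions.values() if positions) + params.component_gutter
                    if positions else 0.0)
    kinds = {n: ("INDI" if n in g.individuals else "FAM") for n in positions}
    return LayoutResult(positions=positions, layers=all_layers,
                        component_of=component_of, seed=seed,
                        anchors=anchors_all or None, kinds=kinds)


def aggregate_tiles(result: LayoutResult, viewport: tuple[float, float, float, float],
                    tile_size: float) -> ViewResult:
    """Grid-tile aggregation; activates only above the global-view threshold.

    Tiles are half-open [lo, hi) squares aligned to the global origin, so the
    same coordinate system serves every zoom level.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    vx, vy, vw, vh = viewport
    if vw <= 0 or vh <= 0:
        raise ValueError("degenerate viewport")
    visible = [n for n, (x, y) in result.positions.items()
               if vx <= x < vx + vw and vy <= y < vy + vh]
    visible.sort(key=natural_key)
    if len(visible) <= GLOBAL_VIEW_THRESHOLD:
        return ViewResult(status="detail", nodes=visible)

    buckets: dict[tuple[int, int], list[str]] = {}
    for n in visible:
        x, y = result.positions[n]
        buckets.setdefault((int(np.floor(x / tile_size)), int(np.floor(y / tile_size))), []).append(n)
    tiles = []
    for (gx, gy), nodes in sorted(buckets.items()):
        pts = np.array([result.positions[n] for n in nodes])
        center = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
        d2 = ((pts - np.array(center)) ** 2).sum(axis=1)
        sample = nodes[int(np.argmin(d2))]
        n_ind = sum(1 for n in nodes if result.kinds.get(n, "INDI") == "INDI")
        tiles.append(Tile(grid_x=gx, grid_y=gy,
                          individual_count=n_ind,
                          family_count=len(nodes) - n_ind,
                          total_entities=len(nodes),
                          center=center, sample_node=sample))
    return ViewResult(status="global", tiles=tiles)


def render_svg(g: PedigreeGraph, result: LayoutResult,
               display_name=None, node_radius: float = 18.0) -> str:
    """Minimal standalone SVG rendering of a laid-out pedigree."""
    if display_name is None:
        def display_name(ind):
            return f"{ind.given} {ind.surname}".strip() or ind.id
    if not result.positions:
        return '<svg xmlns="http://www.w3.org/2000/svg" width="10" height="10"/>'
    xs = [p[0] for p in result.positions.values()]
    ys = [p[1] for p in result.positions.values()]
    pad = 60.0
    ox, oy = min(xs) - pad, min(ys) - pad
    w, h = max(xs) - min(xs) + 2 * pad, max(ys) - min(ys) + 2 * pad
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" height="{h:.0f}" '
             f'viewBox="0 0 {w:.0f} {h:.0f}">',
             '<style>text{font:12px sans-serif;text-anchor:middle}</style>']

    def pt(n):
        x, y = result.positions[n]
        return x - ox, y - oy

    for fid, fam in g.families.items():
        if fid not in result.positions:
            continue
        fx, fy = pt(fid)
        for other in fam.partner_ids + fam.child_ids:
            if other in result.positions:
                x2, y2 = pt(other)
                parts.append(f'<line x1="{fx:.1f}" y1="{fy:.1f}" x2="{x2:.1f}" '
                             f'y2="{y2:.1f}" stroke="#888"/>')
    for fid in g.families:
        if fid in result.positions:
            fx, fy = pt(fid)
            parts.append(f'<circle cx="{fx:.1f}" cy="{fy:.1f}" r="4" fill="#444"/>')
    for iid, ind in g.individuals.items():
        if iid not in result.positions:
            continue
        x, y = pt(iid)
        parts.append(f'<rect x="{x - 45:.1f}" y="{y - node_radius:.1f}" width="90" '
                     f'height="{2 * node_radius:.1f}" rx="6" fill="#eef" stroke="#446"/>')
        label = display_name(ind).replace("&", "&amp;").replace("<", "&lt;")
        parts.append(f'<text x="{x:.1f}" y="{y + 4:.1f}">{label}</text>')
    parts.append("</svg>")
    return "\n".join(parts)
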