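"""Typed line segments linking family members.

For every mating (a co-parent pair) the geometry is: a horizontal spouse
segment at the partners' row, a vertical drop from the spouse midpoint down
to the sibship bar (``barOffset`` units above the child row), a horizontal
sibship bar spanning the children, and one vertical stub per child from the
bar to the child's symbol.  Twin pairs replace their stubs with diagonals
converging to a shared apex on the bar; monozygotic pairs additionally get a
tie joining the diagonals at mid-height.  Segments that would pass through an
unrelated symbol are swapped for quadratic-Bezier arcs.

All geometry is computed from the layout tables with simple array/sort
passes — no per-individual recursion — so large pedigrees route quickly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .layout import LayoutResult, mating_id
from .ped_model import PedigreeTable, Zygosity

BAR_OFFSET = 0.35
NODE_CLEARANCE = 0.25
CURVE_OFFSET = 0.3

Point = Tuple[float, float]


@dataclass
class Segment:
    kind: str  # spouse | drop | sibbar | stub | twin_tie | arc
    frm: Point
    to: Point
    matingID: Optional[str] = None
    control: Optional[Point] = None
    members: List[str] = field(default_factory=list)
    #: for arcs, the kind of straight segment the arc replaced
    replaced: Optional[str] = None


@dataclass
class ConnectionSet:
    segments: List[Segment]
    matingMidpoints: Dict[str, Point] = field(default_factory=dict)

    def by_kind(self, kind: str) -> List[Segment]:
        return [s for s in self.segments if s.kind == kind]


def _cfg_value(cfg, path: str, default: float) -> float:
    if cfg is None:
        return default
    try:
        return float(cfg.get(path))
    except Exception:
        return default


def build_connections(layout: LayoutResult, ped: PedigreeTable,
                      cfg=None) -> ConnectionSet:
    """Spouse, drop, sibbar and stub segments for every mating.

    The appearance chosen for each partner is the (possibly duplicate) node
    recorded by the layout stage as serving that mating.  Raises ``KeyError``
    when a mating partner has no drawn node.
    """
    bar_offset = _cfg_value(cfg, "lines.barOffset", BAR_OFFSET)
    segments: List[Segment] = []
    midpoints: Dict[str, Point] = {}

    for (mom, dad), kids in sorted(ped.matings().items(),
                                   key=lambda kv: mating_id(*kv[0])):
        mid = mating_id(mom, dad)
        serving = layout.matingNodes.get(mid, {})
        pnodes = []
        for p in (mom, dad):
            if p is None:
                continue
            if p not in serving:
                raise KeyError(f"mating {mid}: partner {p!r} has no drawn node")
            pnodes.append(layout.node(serving[p]))

        if len(pnodes) == 2:
            a, b = sorted(pnodes, key=lambda n: n.x)
            if a.y == b.y:
                segments.append(Segment("spouse", (a.x, a.y), (b.x, b.y),
                                        matingID=mid, members=[mom, dad]))
            else:  # parent-child mating: rows differ, draw as arc
                cx = (a.x + b.x) / 2.0 + CURVE_OFFSET
                segments.append(Segment("arc", (a.x, a.y), (b.x, b.y),
                                        matingID=mid, control=(cx, (a.y + b.y) / 2),
                                        members=[mom, dad], replaced="spouse"))
            mx, my = (a.x + b.x) / 2.0, max(a.y, b.y)
        else:
            mx, my = pnodes[0].x, pnodes[0].y
        midpoints[mid] = (mx, my)

        kid_nodes = [layout.primary(k) for k in kids if k in layout._by_person]
        if not kid_nodes:
            continue
        child_y = min(n.y for n in kid_nodes)
        bar_y = child_y - bar_offset
        members = [p for p in (mom, dad) if p is not None] + kids
        segments.append(Segment("drop", (mx, my), (mx, bar_y),
                                matingID=mid, members=members))
        kid_x = [n.x for n in kid_nodes]
        lo, hi = min(kid_x + [mx]), max(kid_x + [mx])
        if len(kid_nodes) >= 2 or abs(kid_x[0] - mx) > 1e-9:
            segments.append(Segment("sibbar", (lo, bar_y), (hi, bar_y),
                                    matingID=mid, members=kids))
        for n in sorted(kid_nodes, key=lambda n: (n.x, n.personID)):
            segments.append(Segment("stub", (n.x, bar_y), (n.x, n.y),
                                    matingID=mid, members=[n.personID]))
    return ConnectionSet(segments=segments, matingMidpoints=midpoints)


def add_twin_geometry(conn: ConnectionSet, ped: PedigreeTable,
                      layout: LayoutResult) -> ConnectionSet:
    """Replace co-twins' stubs by diagonals to a shared apex on the sibbar.

    Monozygotic pairs get an additional ``twin_tie`` joining the diagonals at
    mid-height; dizygotic pairs get the diagonals only.  A twin group whose
    members do not share both parents is left as ordinary siblings with a
    warning.
    """
    groups: Dict[str, List[str]] = {}
    for ind in ped:
        if ind.twinID is not None:
            groups.setdefault(ind.twinID, []).append(ind.personID)

    segments = list(conn.segments)
    for tid in sorted(groups):
        members = sorted(groups[tid])
        if len(members) < 2:
            continue
        parents = {(ped.get(m).momID, ped.get(m).dadID) for m in members}
        if len(parents) > 1:
            warnings.warn(f"twin group {tid!r} has mismatched parents; "
                          "drawn as ordinary siblings")
            continue
        nodes = [layout.primary(m) for m in members if m in layout._by_person]
        if len(nodes) < 2:
            continue
        stubs = [s for s in segments if s.kind == "stub"
                 and s.members and s.members[0] in members]
        if len(stubs) < 2:
            continue
        bar_y = stubs[0].frm[1]
        apex_x = sum(n.x for n in nodes) / len(nodes)
        mid = stubs[0].matingID
        diagonals = []
        for s, n in zip(sorted(stubs, key=lambda s: s.frm[0]),
                        sorted(nodes, key=lambda n: n.x)):
            segments.remove(s)
            d = Segment("stub", (apex_x, bar_y), (n.x, n.y),
                        matingID=mid, members=[n.personID])
            segments.append(d)
            diagonals.append(d)
        zyg = ped.get(members[0]).zygosity
        if zyg is Zygosity.MZ and len(diagonals) >= 2:
            p1 = _seg_midpoint(diagonals[0])
            p2 = _seg_midpoint(diagonals[-1])
            segments.append(Segment("twin_tie", p1, p2, matingID=mid,
                                    members=members))
    return ConnectionSet(segments=segments, matingMidpoints=dict(conn.matingMidpoints))


def _seg_midpoint(s: Segment) -> Point:
    return ((s.frm[0] + s.to[0]) / 2.0, (s.frm[1] + s.to[1]) / 2.0)


def _point_segment_distance(px, py, ax, ay, bx, by) -> float:
    dx, dy = bx - ax, by - ay
    L2 = dx * dx + dy * dy
    if L2 == 0:
        return ((px - ax) ** 2 + (py - ay) ** 2) ** 0.5
    t = max(0.0, min(1.0, ((px - ax) * dx + (py - ay) * dy) / L2))
    cx, cy = ax + t * dx, ay + t * dy
    return ((px - cx) ** 2 + (py - cy) ** 2) ** 0.5


def resolve_overlaps(conn: ConnectionSet, layout: LayoutResult,
                     cfg=None) -> ConnectionSet:
    """Swap obstructed spouse/drop segments for quadratic arcs.

    A segment is obstructed when a node not among its members lies within
    ``nodeClearance`` of it, or when an earlier drop (ordered by matingID)
    already occupies the same vertical corridor.  The arc's control point
    sits ``curveOffset`` units to the side with more free space; ties bow
    left (drops) or above the row (spouse segments).
    """
    clearance = _cfg_value(cfg, "lines.nodeClearance", NODE_CLEARANCE)
    offset = _cfg_value(cfg, "lines.curveOffset", CURVE_OFFSET)

    node_pos = [(n.personID, n.x, n.y) for n in layout.nodes]
    out: List[Segment] = []
    seen_drop_corridors: List[Tuple[float, float, float]] = []  # x, y_lo, y_hi

    def obstructors(seg: Segment):
        hits = []
        for pid, x, y in node_pos:
            if pid in seg.members:
                continue
            if _point_segment_distance(x, y, *seg.frm, *seg.to) < clearance:
                hits.append((x, y))
        return hits

    order = sorted(range(len(conn.segments)),
                   key=lambda i: (conn.segments[i].kind,
                                  conn.segments[i].matingID or "",
                                  conn.segments[i].frm))
    arced: Dict[int, Segment] = {}
    for i in order:
        seg = conn.segments[i]
        if seg.kind not in ("spouse", "drop"):
            continue
        hits = obstructors(seg)
        corridor_clash = False
        if seg.kind == "drop":
            x = seg.frm[0]
            y_lo, y_hi = sorted((seg.frm[1], seg.to[1]))
            for cx, c_lo, c_hi in seen_drop_corridors:
                if abs(cx - x) < 1e-9 and y_lo < c_hi and c_lo < y_hi:
                    corridor_clash = True
                    break
            if not corridor_clash:
                seen_drop_corridors.append((x, y_lo, y_hi))
        if not hits and not corridor_clash:
            continue
        mx, my = _seg_midpoint(seg)
        if seg.kind == "spouse":
            control = (mx, my - offset)  # bow above the row
        else:
            side = _freer_side(mx, my, node_pos, seg.members)
            control = (mx + side * offset, my)
        arced[i] = Segment("arc", seg.frm, seg.to, matingID=seg.matingID,
                           control=control, members=list(seg.members),
                           replaced=seg.kind)

    for i, seg in enumerate(conn.segments):
        out.append(arced.get(i, seg))
    return ConnectionSet(segments=out, matingMidpoints=dict(conn.matingMidpoints))


def _freer_side(mx: float, my: float, node_pos, members) -> int:
    """-1 to bow left, +1 to bow right; ties go left."""
    left = min((mx - x for pid, x, y in node_pos
                if x < mx and abs(y - my) < 0.75 and pid not in members),
               default=float("inf"))
    right = min((x - mx for pid, x, y in node_pos
                 if x > mx and abs(y - my) < 0.75 and pid not in members),
                default=float("inf"))
    return -1 if left >= right else 1


def build_all(layout: LayoutResult, ped: PedigreeTable, cfg=None) -> ConnectionSet:
    """Full routing pipeline: base segments, twin geometry, overlap arcs."""
    conn = build_connections(layout, ped, cfg)
    conn = add_twin_geometry(conn, ped, layout)
    return resolve_overlaps(conn, layout, cfg)
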