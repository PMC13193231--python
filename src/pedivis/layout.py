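"""Drawing-coordinate calculation for pedigrees.

A layered (Sugiyama-style) pipeline:

1. :func:`assign_generations` — longest-path leveling from the founders,
   then mating-pair equalization iterated to a fixpoint, so that both
   partners of a mating sit on one row and every child hangs one row below.
2. :func:`order_within_generations` — sibships kept contiguous and spouses
   pulled adjacent, then barycenter crossing-minimisation sweeps (a down
   pass plus an up pass per sweep, at most four sweeps, stopping early when
   the crossing count stops improving).  Ties break by ascending personID,
   so the result is deterministic.
3. :func:`break_loops` — a person with several matings that cannot all be
   adjacent keeps a primary symbol beside one mating and gains dashed
   duplicate symbols beside the others.
4. :func:`assign_coordinates` — unit x slots per generation, one bottom-up
   pass centering each mating pair over its sibship where spacing allows,
   then per-family normalisation and horizontal tiling of families.

Coordinates are abstract: one unit is one symbol slot, y equals the
generation index and increases downward.  Renderers own all scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .ped_model import PedigreeTable, assign_families, parent_graph

MAX_SWEEPS = 4
FAMILY_GUTTER = 2.0


@dataclass
class LayoutNode:
    nodeID: str
    personID: str
    famID: str
    x: float
    y: float
    generation: int
    duplicateIndex: int = 0


@dataclass
class LayoutResult:
    nodes: List[LayoutNode]
    familyBounds: Dict[str, Tuple[float, float, float, float]]
    crossingCount: int
    # matingID -> {personID: nodeID} appearance serving that mating
    matingNodes: Dict[str, Dict[str, str]] = field(default_factory=dict)

    def node(self, nodeID: str) -> LayoutNode:
        return self._by_id[nodeID]

    def primary(self, personID: str) -> LayoutNode:
        return self._by_person[personID]

    def __post_init__(self) -> None:
        self._by_id = {n.nodeID: n for n in self.nodes}
        self._by_person = {n.personID: n for n in self.nodes if n.duplicateIndex == 0}


def mating_id(momID: Optional[str], dadID: Optional[str]) -> str:
    return f"{momID}+{dadID}"


def _fam_of(ped: PedigreeTable, pid: str) -> str:
    return ped.get(pid).famID or "1"


def assign_generations(ped: PedigreeTable) -> Dict[str, int]:
    """Generation (row) index per person.

    Founders seed at 0; each child sits one below its deepest parent; mating
    partners are lifted to a common row.  Partner equalization is skipped
    when one partner is an ancestor of the other (a parent-child mating
    cannot share a row without contradicting the child rule); such pairs
    keep their leveling rows and their spouse segment is drawn slanted-free
    via the duplicate machinery downstream.  Rows are normalised to start at
    0 within each family.
    """
    gen: Dict[str, int] = {pid: 0 for pid in ped.ids}
    g = parent_graph(ped)
    # ancestor test for the equalization guard
    desc: Dict[str, set] = {pid: nx.descendants(g, pid) for pid in ped.ids}

    pairs = set()
    for (mom, dad) in ped.matings():
        if mom is not None and dad is not None and mom in ped and dad in ped:
            pairs.add((mom, dad))

    n = len(ped)
    for _ in range(3 * n + 10):
        changed = False
        for ind in ped:
            parents = [p for p in (ind.momID, ind.dadID) if p is not None and p in ped]
            if parents:
                want = 1 + max(gen[p] for p in parents)
                if gen[ind.personID] < want:
                    gen[ind.personID] = want
                    changed = True
        for mom, dad in pairs:
            if dad in desc[mom] or mom in desc[dad]:
                continue
            hi = max(gen[mom], gen[dad])
            for p in (mom, dad):
                if gen[p] < hi:
                    gen[p] = hi
                    changed = True
        if not changed:
            break
    else:
        raise RuntimeError("generation leveling did not converge")

    fams: Dict[str, List[str]] = {}
    for pid in ped.ids:
        fams.setdefault(_fam_of(ped, pid), []).append(pid)
    for members in fams.values():
        lo = min(gen[p] for p in members)
        for p in members:
            gen[p] -= lo
    return gen


# orders: famID -> {generation -> [personID, ...]}
Orders = Dict[str, Dict[int, List[str]]]


def _sibship_key(ped: PedigreeTable, pid: str) -> Tuple[Optional[str], Optional[str]]:
    ind = ped.get(pid)
    return (ind.momID, ind.dadID)


def _initial_order(ped: PedigreeTable, gens: Dict[str, int], fam: str,
                   members: List[str]) -> Dict[int, List[str]]:
    by_gen: Dict[int, List[str]] = {}
    for pid in sorted(members):
        by_gen.setdefault(gens[pid], []).append(pid)
    layers: Dict[int, List[str]] = {}
    for g in sorted(by_gen):
        # sibships contiguous; blocks ordered by parents' mean position above
        blocks: Dict[Tuple, List[str]] = {}
        for pid in by_gen[g]:
            blocks.setdefault(_sibship_key(ped, pid), []).append(pid)
        above = {pid: i for i, pid in enumerate(layers.get(g - 1, []))}

        def block_key(item):
            (mom, dad), kids = item
            pos = [above[p] for p in (mom, dad) if p in above]
            bary = float(np.mean(pos)) if pos else float("inf")
            return (bary, min(kids))

        seq: List[str] = []
        for _, kids in sorted(blocks.items(), key=block_key):
            seq.extend(sorted(kids))
        layers[g] = seq
    _pull_spouses_adjacent(ped, layers)
    return layers


def _pull_spouses_adjacent(ped: PedigreeTable, layers: Dict[int, List[str]]) -> None:
    """Best-effort pass moving married-in partners next to their spouse."""
    pos_gen = {pid: g for g, seq in layers.items() for pid in seq}
    n_matings: Dict[str, int] = {}
    for (mom, dad) in ped.matings():
        for p in (mom, dad):
            if p is not None:
                n_matings[p] = n_matings.get(p, 0) + 1
    for (mom, dad), kids in sorted(ped.matings().items(),
                                   key=lambda kv: mating_id(*kv[0])):
        if mom is None or dad is None or mom not in pos_gen or dad not in pos_gen:
            continue
        if pos_gen[mom] != pos_gen[dad]:
            continue
        if n_matings.get(mom, 0) > 1 and n_matings.get(dad, 0) > 1:
            continue  # multi-marriage chains handled by duplicates later
        seq = layers[pos_gen[mom]]
        i, j = seq.index(mom), seq.index(dad)
        if abs(i - j) == 1:
            continue
        # move the partner with fewer matings beside the other
        mover, anchor = (mom, dad) if n_matings.get(mom, 0) <= n_matings.get(dad, 0) \
            else (dad, mom)
        seq.remove(mover)
        k = seq.index(anchor)
        seq.insert(k + 1, mover)


def _layer_edges(ped: PedigreeTable, upper: Sequence[str], lower: Sequence[str]
                 ) -> List[Tuple[int, int]]:
    up = {pid: i for i, pid in enumerate(upper)}
    lo = {pid: i for i, pid in enumerate(lower)}
    edges = []
    for pid in lower:
        ind = ped.get(pid)
        for par in (ind.momID, ind.dadID):
            if par in up:
                edges.append((up[par], lo[pid]))
    return edges


def _count_crossings_layers(edges: List[Tuple[int, int]]) -> int:
    if len(edges) < 2:
        return 0
    e = np.array(edges)
    u, v = e[:, 0], e[:, 1]
    lt_u = u[:, None] < u[None, :]
    gt_v = v[:, None] > v[None, :]
    return int(np.sum(lt_u & gt_v))


def count_crossings(ped: PedigreeTable, orders: Orders) -> int:
    total = 0
    for layers in orders.values():
        gs = sorted(layers)
        for g in gs[:-1]:
            if g + 1 in layers:
                total += _count_crossings_layers(
                    _layer_edges(ped, layers[g], layers[g + 1]))
    return total


def _barycenter_pass(ped: PedigreeTable, layers: Dict[int, List[str]],
                     downward: bool) -> None:
    children: Dict[str, List[str]] = {pid: [] for pid in
                                      (p for seq in layers.values() for p in seq)}
    for ind in ped:
        for par in (ind.momID, ind.dadID):
            if par in children:
                children[par].append(ind.personID)
    gs = sorted(layers)
    seq_gs = gs[1:] if downward else list(reversed(gs[:-1]))
    for g in seq_gs:
        ref = layers.get(g - 1 if downward else g + 1, [])
        refpos = {pid: i for i, pid in enumerate(ref)}
        cur = layers[g]
        keys = {}
        for i, pid in enumerate(cur):
            if downward:
                ind = ped.get(pid)
                nb = [refpos[p] for p in (ind.momID, ind.dadID) if p in refpos]
            else:
                nb = [refpos[c] for c in children.get(pid, []) if c in refpos]
            keys[pid] = (float(np.mean(nb)) if nb else float(i), pid)
        cur.sort(key=lambda pid: keys[pid])


def order_within_generations(ped: PedigreeTable, gens: Dict[str, int]) -> Orders:
    """Deterministic per-generation ordering with barycenter sweeps.

    A sweep is one down pass plus one up pass; at most ``MAX_SWEEPS`` sweeps
    run, and a sweep that fails to reduce the crossing count is rolled back,
    so the count is non-increasing over sweeps.
    """
    fams: Dict[str, List[str]] = {}
    for pid in ped.ids:
        fams.setdefault(_fam_of(ped, pid), []).append(pid)

    orders: Orders = {}
    for fam in sorted(fams):
        orders[fam] = _initial_order(ped, gens, fam, fams[fam])

    best = count_crossings(ped, orders)
    for _ in range(MAX_SWEEPS):
        snapshot = {f: {g: list(seq) for g, seq in layers.items()}
                    for f, layers in orders.items()}
        for layers in orders.values():
            _barycenter_pass(ped, layers, downward=True)
            _barycenter_pass(ped, layers, downward=False)
            _pull_spouses_adjacent(ped, layers)
        now = count_crossings(ped, orders)
        if now >= best:
            orders = snapshot
            break
        best = now
    return orders


# drawn slots: famID -> {generation -> [(personID, duplicateIndex), ...]}
Slots = Dict[str, Dict[int, List[Tuple[str, int]]]]


def break_loops(ped: PedigreeTable, orders: Orders
                ) -> Tuple[Slots, Dict[str, Dict[str, str]]]:
    """Insert duplicate appearances for multiply-married individuals.

    The primary symbol stays beside the mating holding the person's
    first-drawn child sibship; every other mating whose partner is not
    already adjacent gets a dashed duplicate inserted beside that partner.
    Returns the drawn slot lists and, per mating, the node id serving each
    partner.
    """
    slots: Slots = {fam: {g: [(pid, 0) for pid in seq]
                          for g, seq in layers.items()}
                    for fam, layers in orders.items()}
    serving: Dict[str, Dict[str, str]] = {}
    dup_count: Dict[str, int] = {}

    matings = ped.matings()
    person_matings: Dict[str, List[Tuple[str, str]]] = {}
    for (mom, dad), kids in matings.items():
        mid = mating_id(mom, dad)
        serving[mid] = {}
        for p in (mom, dad):
            if p is not None and p in ped:
                person_matings.setdefault(p, []).append((mid, (mom, dad)))
                serving[mid][p] = p  # primary node id == personID

    pos = {}
    for fam, layers in slots.items():
        for g, seq in layers.items():
            for i, (pid, d) in enumerate(seq):
                pos[pid] = (fam, g, i)

    def slot_seq(pid):
        fam, g, _ = pos[pid]
        return slots[fam][g]

    def index_of(seq, node):
        return next(i for i, s in enumerate(seq) if s == node)

    for person in sorted(person_matings):
        mlist = person_matings[person]
        if len(mlist) < 2:
            continue

        def mating_rank(entry):
            mid, (mom, dad) = entry
            kid_keys = []
            for k in matings[(mom, dad)]:
                if k in pos:
                    fam, g, i = pos[k]
                    kid_keys.append((g, i, k))
            return (min(kid_keys) if kid_keys else (10**9,), mid)

        mlist = sorted(mlist, key=mating_rank)
        seq = slot_seq(person)
        for mid, (mom, dad) in mlist[1:]:
            partner = dad if person == mom else mom
            if partner is None or partner not in pos:
                continue
            my_i = index_of(seq, (person, 0))
            pseq = slot_seq(partner)
            partner_node = (partner, 0)
            if pseq is seq:
                pj = index_of(pseq, partner_node)
                if abs(pj - my_i) == 1:
                    continue  # already adjacent; primary node can serve
            # insert duplicate right after the partner's symbol
            dup_count[person] = dup_count.get(person, 0) + 1
            d = dup_count[person]
            node = (person, d)
            pj = index_of(pseq, partner_node)
            pseq.insert(pj + 1, node)
            serving[mid][person] = f"{person}#dup{d}"
    return slots, serving


def assign_coordinates(ped: PedigreeTable, slots: Slots, gens: Dict[str, int],
                       serving: Dict[str, Dict[str, str]],
                       crossing_count: int = 0,
                       gutter: float = FAMILY_GUTTER) -> LayoutResult:
    """Unit-slot x positions, one bottom-up centering pass, family tiling."""
    nodes: List[LayoutNode] = []
    bounds: Dict[str, Tuple[float, float, float, float]] = {}
    matings = ped.matings()
    x_offset = 0.0

    for fam in sorted(slots):
        layers = slots[fam]
        xs: Dict[Tuple[str, int], float] = {}
        for g, seq in layers.items():
            for i, node in enumerate(seq):
                xs[node] = float(i)

        node_id = {node: (node[0] if node[1] == 0 else f"{node[0]}#dup{node[1]}")
                   for seq in layers.values() for node in seq}
        id_node = {v: k for k, v in node_id.items()}

        # bottom-up centering of mating pairs over their sibships
        for g in sorted(layers, reverse=True):
            seq = layers[g]
            pairs = []
            for (mom, dad), kids in matings.items():
                mid = mating_id(mom, dad)
                srv = serving.get(mid, {})
                if mom not in srv or dad not in srv:
                    continue
                if srv[mom] not in id_node or srv[dad] not in id_node:
                    continue  # mating belongs to another family
                a, b = id_node[srv[mom]], id_node[srv[dad]]
                if a not in xs or b not in xs:
                    continue
                if gens.get(mom) != g or gens.get(dad) != g:
                    continue
                if a not in seq or b not in seq:
                    continue
                kid_nodes = [(k, 0) for k in kids if (k, 0) in xs]
                if not kid_nodes:
                    continue
                pairs.append((min(xs[a], xs[b]), a, b, kid_nodes))
            pairs.sort()
            locked: set = set()
            for _, a, b, kid_nodes in pairs:
                if a in locked or b in locked:
                    continue  # shared spouse already centered with another pair
                ia, ib = seq.index(a), seq.index(b)
                if abs(ia - ib) != 1:
                    continue  # only adjacent pairs slide as a unit
                kid_x = [xs[k] for k in kid_nodes]
                center = (min(kid_x) + max(kid_x)) / 2.0
                mid_x = (xs[a] + xs[b]) / 2.0
                delta = center - mid_x
                lo_i, hi_i = min(ia, ib), max(ia, ib)
                left_lim = -np.inf if lo_i == 0 else xs[seq[lo_i - 1]] + 1.0 - xs[seq[lo_i]]
                right_lim = np.inf if hi_i == len(seq) - 1 else xs[seq[hi_i + 1]] - 1.0 - xs[seq[hi_i]]
                delta = float(np.clip(delta, left_lim, right_lim))
                xs[seq[lo_i]] += delta
                xs[seq[hi_i]] += delta
                locked.update((a, b))

        fam_min = min(xs.values()) if xs else 0.0
        fam_nodes = []
        for g, seq in layers.items():
            for node in seq:
                x = xs[node] - fam_min + x_offset
                fam_nodes.append(LayoutNode(
                    nodeID=node_id[node], personID=node[0], famID=fam,
                    x=x, y=float(g), generation=g, duplicateIndex=node[1]))
        nodes.extend(fam_nodes)
        if fam_nodes:
            xmin = min(n.x for n in fam_nodes)
            xmax = max(n.x for n in fam_nodes)
            ymin = min(n.y for n in fam_nodes)
            ymax = max(n.y for n in fam_nodes)
            bounds[fam] = (xmin, ymin, xmax, ymax)
            x_offset = xmax + gutter

    return LayoutResult(nodes=nodes, familyBounds=bounds,
                        crossingCount=crossing_count, matingNodes=serving)


def compute_layout(ped: PedigreeTable, gutter: float = FAMILY_GUTTER) -> LayoutResult:
    """Full pipeline: leveling, ordering, loop breaking, coordinates.

    Assigns famIDs first when any are missing.  Pure function of the table:
    identical inputs give identical outputs.
    """
    if any(ind.famID is None for ind in ped):
        ped = assign_families(ped)
    gens = assign_generations(ped)
    orders = order_within_generations(ped, gens)
    crossings = count_crossings(ped, orders)
    slots, serving = break_loops(ped, orders)
    return assign_coordinates(ped, slots, gens, serving,
                              crossing_count=crossings, gutter=gutter)
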