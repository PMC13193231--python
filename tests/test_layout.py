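"""Layered layout: leveling, ordering, loop breaking, coordinates."""

import pytest

import pedivis as pv
from conftest import layout_corpus
from pedivis.layout import (
    assign_generations,
    break_loops,
    count_crossings,
    order_within_generations,
)
from pedivis.ped_model import Individual, PedigreeTable, Sex


class TestAssignGenerations:
    def test_trio(self, trio):
        gens = assign_generations(pv.assign_families(trio))
        assert gens == {"F1": 0, "F2": 0, "C1": 1}

    def test_three_generation_chain(self):
        ped = pv.assign_families(PedigreeTable([
            Individual("G", sex=Sex.FEMALE),
            Individual("P", momID="G", sex=Sex.FEMALE),
            Individual("C", momID="P"),
        ]))
        gens = assign_generations(ped)
        assert (gens["G"], gens["P"], gens["C"]) == (0, 1, 2)

    def test_founder_lifted_by_spouse_equalization(self):
        # S is a founder but marries a generation-2 member: lifted 0 -> 2
        ped = pv.assign_families(PedigreeTable([
            Individual("G1", sex=Sex.FEMALE), Individual("G2", sex=Sex.MALE),
            Individual("P", momID="G1", dadID="G2", sex=Sex.FEMALE),
            Individual("D", sex=Sex.MALE),
            Individual("X", momID="P", dadID="D", sex=Sex.FEMALE),
            Individual("S", sex=Sex.MALE),
            Individual("K", momID="X", dadID="S"),
        ]))
        gens = assign_generations(ped)
        assert gens["X"] == 2 and gens["S"] == 2
        assert gens["K"] == 3

    def test_partners_equalized_in_corpus(self):
        for ped in layout_corpus(10, seed0=6000):
            ped = pv.assign_families(ped)
            gens = assign_generations(ped)
            for (mom, dad) in ped.matings():
                if mom and dad:
                    assert gens[mom] == gens[dad]


class TestOrdering:
    def test_trio_order(self, trio):
        ped = pv.assign_families(trio)
        orders = order_within_generations(ped, assign_generations(ped))
        assert orders["1"][0] == ["F1", "F2"]
        assert orders["1"][1] == ["C1"]

    def test_deterministic_rerun(self, wizard):
        ped = pv.assign_families(wizard)
        gens = assign_generations(ped)
        assert order_within_generations(ped, gens) == \
            order_within_generations(ped, gens)

    def test_crossing_count_non_negative_and_reported(self, wizard):
        ped = pv.assign_families(wizard)
        gens = assign_generations(ped)
        orders = order_within_generations(ped, gens)
        assert count_crossings(ped, orders) >= 0


class TestBreakLoops:
    def test_single_mating_no_duplicates(self, trio):
        ped = pv.assign_families(trio)
        gens = assign_generations(ped)
        orders = order_within_generations(ped, gens)
        slots, serving = break_loops(ped, orders)
        assert all(d == 0 for seq in slots["1"].values() for _, d in seq)

    def test_cousin_marriage_closes_without_duplicates(self, cousin_marriage):
        layout = pv.compute_layout(pv.assign_families(cousin_marriage))
        assert all(n.duplicateIndex == 0 for n in layout.nodes)

    def test_two_marriage_partners_both_adjacent(self, two_marriages):
        """H sits between his two wives, so both matings are served without
        duplicates and each serving pair is horizontally adjacent."""
        ped = pv.assign_families(two_marriages)
        layout = pv.compute_layout(ped)
        for mid, srv in layout.matingNodes.items():
            nodes = [layout.node(n) for n in srv.values()]
            if len(nodes) == 2 and nodes[0].y == nodes[1].y:
                assert abs(nodes[0].x - nodes[1].x) <= 1.5

    def test_distant_second_mating_creates_one_duplicate(self):
        # two wide sibships; one man fathers children with a woman from each
        # flank, and the sibships are anchored apart by their own parents
        inds = [Individual("A1", sex=Sex.FEMALE), Individual("A2", sex=Sex.MALE),
                Individual("B1", sex=Sex.FEMALE), Individual("B2", sex=Sex.MALE)]
        for i in range(1, 5):
            inds.append(Individual(f"a{i}", momID="A1", dadID="A2",
                                   sex=Sex.FEMALE))
            inds.append(Individual(f"b{i}", momID="B1", dadID="B2",
                                   sex=Sex.MALE))
        inds += [
            Individual("H", sex=Sex.MALE),
            Individual("k1", momID="a1", dadID="H"),
            Individual("k2", momID="a4", dadID="b1"),
            Individual("k3", momID="a3", dadID="H"),
        ]
        ped = pv.assign_families(PedigreeTable(inds))
        layout = pv.compute_layout(ped)
        dups = [n for n in layout.nodes if n.duplicateIndex > 0]
        # H's matings cannot all be adjacent; at most one duplicate per extra
        # mating, and every person keeps exactly one primary node
        assert len(dups) <= 1
        primaries = [n.personID for n in layout.nodes if n.duplicateIndex == 0]
        assert sorted(primaries) == sorted(ped.ids)
        for mid, srv in layout.matingNodes.items():
            for pid, node_id in srv.items():
                assert layout.node(node_id).personID == pid


class TestCoordinates:
    def test_trio_exact(self, trio):
        layout = pv.compute_layout(pv.assign_families(trio))
        pos = {n.personID: (n.x, n.y) for n in layout.nodes}
        assert pos == {"F1": (0.0, 0.0), "F2": (1.0, 0.0), "C1": (0.5, 1.0)}

    def test_single_individual_origin(self):
        layout = pv.compute_layout(pv.assign_families(
            PedigreeTable([Individual("A")])))
        assert (layout.nodes[0].x, layout.nodes[0].y) == (0.0, 0.0)

    def test_y_equals_generation(self, wizard):
        layout = pv.compute_layout(pv.assign_families(wizard))
        assert all(n.y == n.generation for n in layout.nodes)

    def test_family_tiling_separates_bounds(self):
        inds = [
            Individual("A1", sex=Sex.FEMALE), Individual("A2", sex=Sex.MALE),
            Individual("A3", momID="A1", dadID="A2"),
            Individual("B1", sex=Sex.FEMALE), Individual("B2", sex=Sex.MALE),
            Individual("B3", momID="B1", dadID="B2"),
        ]
        layout = pv.compute_layout(pv.assign_families(PedigreeTable(inds)))
        (x0, _, x1, _) = layout.familyBounds["1"]
        (x2, _, x3, _) = layout.familyBounds["2"]
        assert x2 >= x1 + 2.0  # default gutter


@pytest.fixture(scope="module")
def corpus():
    return [pv.assign_families(pv.pad_founders(p))
            for p in layout_corpus(25, seed0=7000)]


class TestLayoutInvariants:

    def test_unique_coordinates_and_spacing(self, corpus):
        for ped in corpus:
            layout = pv.compute_layout(ped)
            seen = set()
            rows = {}
            for n in layout.nodes:
                key = (n.famID, round(n.x, 9), round(n.y, 9))
                assert key not in seen
                seen.add(key)
                rows.setdefault((n.famID, n.generation), []).append(n.x)
            for xs in rows.values():
                xs = sorted(xs)
                assert all(b - a >= 1.0 - 1e-9 for a, b in zip(xs, xs[1:]))

    def test_children_hang_one_row_below_their_mating(self, corpus):
        for ped in corpus:
            layout = pv.compute_layout(ped)
            gens = {n.personID: n.generation for n in layout.nodes
                    if n.duplicateIndex == 0}
            for (mom, dad), kids in ped.matings().items():
                if mom and dad and gens.get(mom) == gens.get(dad):
                    for k in kids:
                        assert gens[k] == gens[mom] + 1

    def test_layout_is_pure_function(self, corpus):
        ped = corpus[0]
        a = pv.compute_layout(ped)
        b = pv.compute_layout(ped)
        assert [(n.nodeID, n.x, n.y) for n in a.nodes] == \
            [(n.nodeID, n.x, n.y) for n in b.nodes]

    def test_every_person_has_exactly_one_primary_node(self, corpus):
        for ped in corpus:
            layout = pv.compute_layout(ped)
            primaries = [n.personID for n in layout.nodes
                         if n.duplicateIndex == 0]
            assert sorted(primaries) == sorted(ped.ids)


def test_large_pedigree_layout_smoke():
    """A >=1,000-person pedigree lays out quickly with valid coordinates."""
    import time
    params = pv.SimParams(nGenerations=6, foundingCouples=6,
                          meanOffspring=2.6, seed=99)
    ped = pv.simulate_pedigree(params)
    assert len(ped) >= 1000
    t0 = time.time()
    layout = pv.compute_layout(pv.assign_families(pv.pad_founders(ped)))
    assert len({(n.famID, n.x, n.y) for n in layout.nodes}) == len(layout.nodes)
    assert time.time() - t0 < 60
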