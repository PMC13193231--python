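"""Kinship recursion, additive and mitochondrial matrices, highlighting.

Exact coefficients below are classical hand-derivable values: a founder's
self-kinship is 1/2; parent-offspring kinship is 1/4 (additive 0.5); full
sibs 1/4; half sibs 1/8; first cousins 1/16; the child of first cousins has
inbreeding F = 1/16 and self-additive 1 + F = 1.0625.
"""

import numpy as np
import pytest

import pedivis as pv
from conftest import random_pedigree
from pedivis.ped_model import Individual, PedigreeTable, Sex


def half_sib_pedigree():
    return PedigreeTable([
        Individual("M1", sex=Sex.FEMALE), Individual("M2", sex=Sex.FEMALE),
        Individual("D", sex=Sex.MALE),
        Individual("H1", momID="M1", dadID="D"),
        Individual("H2", momID="M2", dadID="D"),
    ])


def first_cousin_pedigree():
    return pv.fixture("cousin_marriage")


class TestKinship:
    def test_founder_self_kinship(self, trio):
        k = pv.kinship_matrix(trio)
        assert k.loc("F1", "F1") == 0.5

    def test_trio_parent_offspring(self, trio):
        assert pv.kinship_matrix(trio).loc("C1", "F1") == 0.25

    def test_founders_mutually_unrelated(self, trio):
        assert pv.kinship_matrix(trio).loc("F1", "F2") == 0.0

    def test_full_sib_mating_child_inbreeding(self):
        ped = PedigreeTable([
            Individual("M", sex=Sex.FEMALE), Individual("D", sex=Sex.MALE),
            Individual("S1", momID="M", dadID="D", sex=Sex.MALE),
            Individual("S2", momID="M", dadID="D", sex=Sex.FEMALE),
            Individual("K", momID="S2", dadID="S1"),
        ])
        k = pv.kinship_matrix(ped)
        # parents are full sibs: phi = 1/4, so F(K) = 1/4, phi(K,K) = 5/8
        assert k.loc("K", "K") == pytest.approx(0.625)

    def test_cycle_raises(self):
        ped = PedigreeTable([
            Individual("A", momID="B", sex=Sex.FEMALE),
            Individual("B", momID="A", sex=Sex.FEMALE),
        ])
        with pytest.raises(ValueError, match="cycle"):
            pv.kinship_matrix(ped)

    def test_gene_drop_oracle_agreement(self):
        """Recursion matches a Monte-Carlo gene-dropping estimate."""
        for seed in (2001, 2002, 2003):
            ped = random_pedigree(seed)
            ids, phi, se = pv.gene_drop_kinship(ped, 40_000, seed=20240101)
            exact = pv.kinship_matrix(ped).values
            dev = np.abs(exact - phi)
            assert (dev <= 4.0 * se + 1e-12).all()


class TestAdditive:
    def test_parent_offspring(self, trio):
        assert pv.additive_matrix(trio).loc("C1", "F1") == 0.5

    def test_non_inbred_diagonal(self, trio):
        assert pv.additive_matrix(trio).loc("C1", "C1") == 1.0

    def test_full_sibs(self):
        ped = PedigreeTable([
            Individual("M", sex=Sex.FEMALE), Individual("D", sex=Sex.MALE),
            Individual("S1", momID="M", dadID="D"),
            Individual("S2", momID="M", dadID="D"),
        ])
        assert pv.additive_matrix(ped).loc("S1", "S2") == 0.5

    def test_half_sibs(self):
        assert pv.additive_matrix(half_sib_pedigree()).loc("H1", "H2") == 0.25

    def test_first_cousins_and_inbred_child(self):
        a = pv.additive_matrix(first_cousin_pedigree())
        assert a.loc("X", "Y") == 0.125
        assert a.loc("Z", "Z") == 1.0625

    def test_twice_kinship_exactly(self):
        for seed in (11, 12):
            ped = random_pedigree(seed)
            k = pv.kinship_matrix(ped)
            a = pv.additive_matrix(ped)
            np.testing.assert_array_equal(a.values, 2.0 * k.values)

    def test_kind_tag(self, trio):
        assert pv.additive_matrix(trio).kind == "additive"


class TestMitochondrial:
    def test_trio_matriline_entries(self, trio):
        m = pv.mitochondrial_matrix(trio)
        assert m.loc("C1", "F1") == 1.0
        assert m.loc("C1", "F2") == 0.0
        assert m.loc("C1", "C1") == 1.0

    def test_two_founders_unrelated(self, trio):
        assert pv.mitochondrial_matrix(trio).loc("F1", "F2") == 0.0

    def test_equivalence_relation(self):
        for seed in range(20, 26):
            ped = random_pedigree(seed, max_n=20)
            v = pv.mitochondrial_matrix(ped).values
            n = len(v)
            assert (np.diag(v) == 1).all()
            assert (v == v.T).all()
            # transitivity, exhaustively
            for i in range(n):
                for j in range(n):
                    if v[i, j] == 1:
                        assert (v[j] >= v[i]).all() and (v[i] >= v[j]).all()

    def test_matches_maternal_lineage(self, wizard):
        m = pv.mitochondrial_matrix(wizard)
        for pid in wizard.ids:
            assert pv.highlight_set(m, pid, 1.0) == \
                pv.extract_lineage(wizard, pid, "maternal")


class TestHighlightAndSubmatrix:
    def test_threshold_zero_selects_everyone(self, trio):
        m = pv.additive_matrix(trio)
        assert pv.highlight_set(m, "C1", 0.0) == set(trio.ids)

    def test_additive_trio_first_degree(self, trio):
        m = pv.additive_matrix(trio)
        assert pv.highlight_set(m, "C1", 0.5) == {"F1", "F2", "C1"}

    def test_unknown_focal_raises(self, trio):
        with pytest.raises(KeyError):
            pv.highlight_set(pv.additive_matrix(trio), "nobody", 0.5)

    def test_submatrix_identity_and_singleton(self, trio):
        m = pv.additive_matrix(trio)
        same = pv.submatrix(m, m.ids)
        np.testing.assert_array_equal(same.values, m.values)
        single = pv.submatrix(m, ["C1"])
        assert single.values.shape == (1, 1)
        assert single.values[0, 0] == m.loc("C1", "C1")
        assert single.kind == "additive"

    def test_submatrix_reversal_flips_both_axes(self, cousin_marriage):
        m = pv.additive_matrix(cousin_marriage)
        rev = pv.submatrix(m, list(reversed(m.ids)))
        np.testing.assert_array_equal(rev.values, m.values[::-1, ::-1])

    def test_submatrix_unknown_id_raises(self, trio):
        with pytest.raises(KeyError):
            pv.submatrix(pv.additive_matrix(trio), ["F1", "ghost"])


class TestStructuralInvariants:
    def test_unrelated_singleton_leaves_entries_unchanged(self, cousin_marriage):
        base = pv.additive_matrix(cousin_marriage)
        bigger = PedigreeTable(list(cousin_marriage) + [Individual("LONER")])
        grown = pv.additive_matrix(bigger)
        sub = pv.submatrix(grown, base.ids)
        np.testing.assert_array_equal(sub.values, base.values)

    def test_row_permutation_permutes_matrix(self):
        ped = random_pedigree(31)
        perm = list(reversed(range(len(ped))))
        shuffled = PedigreeTable([ped.individuals[i] for i in perm])
        a = pv.additive_matrix(ped)
        b = pv.additive_matrix(shuffled)
        aligned = pv.submatrix(b, a.ids)
        np.testing.assert_allclose(aligned.values, a.values, atol=0)

    def test_matrix_symmetry_and_range(self):
        for seed in (41, 42):
            a = pv.additive_matrix(random_pedigree(seed))
            assert (a.values == a.values.T).all()
            assert (a.values >= 0).all() and (a.values <= 2).all()
            assert (np.diag(a.values) >= 1).all()
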