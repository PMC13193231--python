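"""Synthetic pedigrees, simulated phenotypes, and embedded test fixtures.

The generator grows a population forward in time: a configurable number of
founding couples, Poisson-distributed sibship sizes, fair-coin sex, mating
either with a new immigrant founder or (with probability ``pCousinMarriage``)
with another member of the pedigree's same generation — which creates the
consanguineous loops the layout stage must handle — and occasional twin
pairs.  Phenotypes follow the standard additive polygenic model: a breeding
value transmitted as the parental midpoint plus Mendelian-segregation noise,
plus an independent environmental deviation, scaled so the population
phenotypic variance is ~1 and the narrow-sense heritability is ``h2``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .ped_model import Individual, PedigreeTable, Sex, Zygosity
from .relatedness import kinship_matrix


@dataclass
class SimParams:
    nGenerations: int = 4
    foundingCouples: int = 3
    meanOffspring: float = 2.5
    pMate: float = 0.8
    pCousinMarriage: float = 0.05
    twinRate: float = 0.02
    pMZ: float = 0.4
    h2: float = 0.6
    seed: int = 20240101

    def __post_init__(self) -> None:
        if self.nGenerations < 1:
            raise ValueError("nGenerations must be >= 1")
        if self.foundingCouples < 1:
            raise ValueError("foundingCouples must be >= 1")
        if self.meanOffspring < 0:
            raise ValueError("meanOffspring must be non-negative")
        for name in ("pMate", "pCousinMarriage", "twinRate", "pMZ", "h2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def simulate_pedigree(p: SimParams) -> PedigreeTable:
    """Grow a pedigree from ``foundingCouples`` couples over ``nGenerations``.

    Pure function of the parameters: the same seed always yields the same
    table.  The output passes validation with zero errors.
    """
    rng = np.random.default_rng(p.seed)
    counter = itertools.count(1)

    def new_person(sex: Sex, mom=None, dad=None) -> Individual:
        return Individual(f"I{next(counter):05d}", momID=mom, dadID=dad, sex=sex)

    individuals: List[Individual] = []
    couples: List[tuple] = []
    for _ in range(p.foundingCouples):
        mom = new_person(Sex.FEMALE)
        dad = new_person(Sex.MALE)
        individuals.extend([mom, dad])
        couples.append((mom.personID, dad.personID))

    twin_counter = itertools.count(1)
    for _gen in range(1, p.nGenerations):
        offspring: List[Individual] = []
        for mom_id, dad_id in couples:
            n_kids = int(rng.poisson(p.meanOffspring))
            sibship: List[Individual] = []
            for _ in range(n_kids):
                sex = Sex.FEMALE if rng.random() < 0.5 else Sex.MALE
                sibship.append(new_person(sex, mom=mom_id, dad=dad_id))
            if len(sibship) >= 2 and rng.random() < p.twinRate:
                tid = f"T{next(twin_counter)}"
                a, b = sibship[0], sibship[1]
                if rng.random() < p.pMZ:
                    a.zygosity = b.zygosity = Zygosity.MZ
                    b.sex = a.sex
                else:
                    a.zygosity = b.zygosity = Zygosity.DZ
                a.twinID = b.twinID = tid
            offspring.extend(sibship)
        individuals.extend(offspring)

        # pair off the new generation
        couples = []
        unmated = [ind for ind in offspring if rng.random() < p.pMate]
        females = [i for i in unmated if i.sex is Sex.FEMALE]
        males = [i for i in unmated if i.sex is Sex.MALE]
        for person in females + males:
            if person.personID in {c for pair in couples for c in pair}:
                continue
            want = males if person.sex is Sex.FEMALE else females
            partner: Optional[Individual] = None
            if rng.random() < p.pCousinMarriage:
                taken = {c for pair in couples for c in pair}
                pool = [q for q in want
                        if q.personID not in taken
                        and (q.momID, q.dadID) != (person.momID, person.dadID)]
                if pool:
                    partner = pool[int(rng.integers(0, len(pool)))]
            if partner is None:
                sex = Sex.MALE if person.sex is Sex.FEMALE else Sex.FEMALE
                partner = new_person(sex)
                individuals.append(partner)
            mom, dad = ((person, partner) if person.sex is Sex.FEMALE
                        else (partner, person))
            couples.append((mom.personID, dad.personID))
    return PedigreeTable(individuals)


def simulate_phenotype(ped: PedigreeTable, h2: float, seed: int,
                       name: str = "trait") -> pd.Series:
    """Additive polygenic phenotype with narrow-sense heritability ``h2``.

    Founders draw breeding values from N(0, h2); a child's breeding value is
    the parental midpoint plus segregation noise with variance
    ``h2/2 * (1 - (F_mom + F_dad)/2)`` — inbred parents transmit less
    segregation variance — and the phenotype adds N(0, 1 - h2) environment.
    Returns a Series indexed by personID.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must lie in [0, 1], got {h2}")
    rng = np.random.default_rng(seed)
    kin = kinship_matrix(ped)
    F = {pid: 2.0 * kin.values[i, i] - 1.0 for i, pid in enumerate(kin.ids)}

    # parents-first order
    from .relatedness import _topological_ids
    order = _topological_ids(ped)
    bv: Dict[str, float] = {}
    for pid in order:
        ind = ped.get(pid)
        parents = [q for q in (ind.momID, ind.dadID) if q in bv]
        if not parents and (ind.momID is None and ind.dadID is None):
            bv[pid] = rng.normal(0.0, np.sqrt(h2))
        else:
            mid_par = float(np.mean([bv.get(q, 0.0) for q in
                                     (ind.momID, ind.dadID) if q is not None]))
            f_m = F.get(ind.momID, 0.0) if ind.momID else 0.0
            f_d = F.get(ind.dadID, 0.0) if ind.dadID else 0.0
            seg_var = (h2 / 2.0) * (1.0 - (f_m + f_d) / 2.0)
            bv[pid] = mid_par + rng.normal(0.0, np.sqrt(max(seg_var, 0.0)))
    env_sd = np.sqrt(1.0 - h2)
    values = {pid: bv[pid] + rng.normal(0.0, env_sd) for pid in ped.ids}
    return pd.Series(values, name=name)


def attach_phenotype(ped: PedigreeTable, h2: float, seed: int,
                     name: str = "trait") -> PedigreeTable:
    """Copy of the pedigree with a simulated phenotype column attached."""
    values = simulate_phenotype(ped, h2, seed, name=name)
    out = ped.copy()
    for pid, v in values.items():
        out.get(pid).phenotypes[name] = float(v)
    return out


# -- hand-curated fixtures ---------------------------------------------------

def _ind(pid, mom=None, dad=None, sex="unknown", **kw) -> Individual:
    return Individual(pid, momID=mom, dadID=dad, sex=Sex(sex), **kw)


def fixture(name: str) -> PedigreeTable:
    """Small pedigrees with known layouts and matrices.

    ``trio`` — mother F1, father F2, child C1.
    ``cousin_marriage`` — 10 people; Z is the child of first cousins
    (inbreeding F = 1/16, self-additive 1.0625).
    ``two_marriages`` — 12 people; one man with children by two wives.
    ``multi_family_wizard`` — three interlinked nuclear families in the
    style of a wizarding-families example pedigree.
    ``mz_dz_twins`` — one MZ pair and one DZ pair with distinct twinIDs.
    """
    builders = {
        "trio": _fixture_trio,
        "cousin_marriage": _fixture_cousin_marriage,
        "two_marriages": _fixture_two_marriages,
        "multi_family_wizard": _fixture_wizard,
        "mz_dz_twins": _fixture_twins,
    }
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; valid names: "
                       f"{sorted(builders)}")
    return builders[name]()


def _fixture_trio() -> PedigreeTable:
    return PedigreeTable([
        _ind("F1", sex="female"),
        _ind("F2", sex="male"),
        _ind("C1", mom="F1", dad="F2", sex="female"),
    ])


def _fixture_cousin_marriage() -> PedigreeTable:
    # G1 x G2 -> P1, P2 (sibs); spouses S1, S2; X, W (sibs) and Y are the
    # grandchildren; first cousins X and Y marry and have Z.
    return PedigreeTable([
        _ind("G1", sex="female"),
        _ind("G2", sex="male"),
        _ind("P1", mom="G1", dad="G2", sex="female"),
        _ind("P2", mom="G1", dad="G2", sex="male"),
        _ind("S1", sex="male"),
        _ind("S2", sex="female"),
        _ind("X", mom="P1", dad="S1", sex="male"),
        _ind("W", mom="P1", dad="S1", sex="female"),
        _ind("Y", mom="S2", dad="P2", sex="female"),
        _ind("Z", mom="Y", dad="X", sex="male"),
    ])


def _fixture_two_marriages() -> PedigreeTable:
    # H has children with W1 and with W2; both wives have parents drawn in.
    return PedigreeTable([
        _ind("A1", sex="female"),
        _ind("A2", sex="male"),
        _ind("B1", sex="female"),
        _ind("B2", sex="male"),
        _ind("H", sex="male"),
        _ind("W1", mom="A1", dad="A2", sex="female"),
        _ind("W2", mom="B1", dad="B2", sex="female"),
        _ind("K1", mom="W1", dad="H", sex="male"),
        _ind("K2", mom="W1", dad="H", sex="female"),
        _ind("K3", mom="W2", dad="H", sex="male"),
        _ind("K4", mom="W2", dad="H", sex="female"),
        _ind("K5", mom="W2", dad="H", sex="male"),
    ])


def _fixture_wizard() -> PedigreeTable:
    # three founding couples; one granddaughter marries into family 2 style
    # structure, all connected through the marriage generation
    return PedigreeTable([
        _ind("d1", sex="male"), _ind("d2", sex="female"),
        _ind("e1", sex="male"), _ind("e2", sex="female"),
        _ind("w1", sex="male"), _ind("w2", sex="female"),
        _ind("d3", mom="d2", dad="d1", sex="male"),
        _ind("e3", mom="e2", dad="e1", sex="female"),
        _ind("e4", mom="e2", dad="e1", sex="female"),
        _ind("w3", mom="w2", dad="w1", sex="male"),
        _ind("w4", mom="w2", dad="w1", sex="female"),
        _ind("d4", mom="e3", dad="d3", sex="male"),
        _ind("p1", mom="e4", dad="w3", sex="male"),
        _ind("p2", mom="e4", dad="w3", sex="female"),
        _ind("g1", mom="p2", dad="d4", sex="female"),
    ])


def _fixture_twins() -> PedigreeTable:
    return PedigreeTable([
        _ind("M1", sex="female"), _ind("D1", sex="male"),
        _ind("M2", sex="female"), _ind("D2", sex="male"),
        _ind("T1a", mom="M1", dad="D1", sex="female",
             twinID="TW1", zygosity=Zygosity.MZ),
        _ind("T1b", mom="M1", dad="D1", sex="female",
             twinID="TW1", zygosity=Zygosity.MZ),
        _ind("T2a", mom="M2", dad="D2", sex="male",
             twinID="TW2", zygosity=Zygosity.DZ),
        _ind("T2b", mom="M2", dad="D2", sex="female",
             twinID="TW2", zygosity=Zygosity.DZ),
    ])
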