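import numpy as np
import pytest

import pedivis as pv
from pedivis.ped_model import Individual, PedigreeTable


@pytest.fixture
def trio():
    return pv.fixture("trio")


@pytest.fixture
def cousin_marriage():
    return pv.fixture("cousin_marriage")


@pytest.fixture
def two_marriages():
    return pv.fixture("two_marriages")


@pytest.fixture
def wizard():
    return pv.fixture("multi_family_wizard")


@pytest.fixture
def twins():
    return pv.fixture("mz_dz_twins")


def random_pedigree(seed: int, max_n: int = 15) -> PedigreeTable:
    """Small random pedigree for property corpora, truncated to ``max_n``.

    Truncation cuts dangling parent links so the table stays valid.
    """
    rng = np.random.default_rng(seed)
    params = pv.SimParams(
        nGenerations=int(rng.integers(2, 4)),
        foundingCouples=int(rng.integers(1, 3)),
        meanOffspring=float(rng.uniform(1.0, 2.5)),
        pMate=0.7,
        pCousinMarriage=0.15,
        twinRate=0.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ped = pv.simulate_pedigree(params)
    if len(ped) > max_n:
        keep = ped.ids[:max_n]
        ks = set(keep)
        inds = []
        for pid in keep:
            ind = ped.get(pid)
            inds.append(Individual(
                pid,
                momID=ind.momID if ind.momID in ks else None,
                dadID=ind.dadID if ind.dadID in ks else None,
                sex=ind.sex,
            ))
        ped = PedigreeTable(inds)
    return ped


def layout_corpus(n: int, seed0: int = 5000):
    """Random synthetic pedigrees exercising loops and twins."""
    rng = np.random.default_rng(seed0)
    peds = []
    for _ in range(n):
        params = pv.SimParams(
            nGenerations=int(rng.integers(2, 5)),
            foundingCouples=int(rng.integers(1, 4)),
            meanOffspring=float(rng.uniform(1.0, 3.0)),
            pMate=0.75,
            pCousinMarriage=float(rng.uniform(0.0, 0.2)),
            twinRate=0.1,
            pMZ=0.5,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        peds.append(pv.simulate_pedigree(params))
    return peds
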