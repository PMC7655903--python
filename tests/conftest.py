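"""Shared fixtures: simulated populations reused across test modules."""

import numpy as np
import pytest

import popgs
from popgs import synthetic_data as sd


@pytest.fixture(scope="session")
def study_design():
    return sd.study_population_design()


@pytest.fixture(scope="session")
def small_design(study_design):
    """Study design with family sizes scaled to ~30% (~300 offspring)."""
    crosses = [(s, d, max(2, int(round(n * 0.3))))
               for s, d, n in study_design.crosses]
    return sd.MatingDesign(sires=study_design.sires, dams=study_design.dams,
                           crosses=crosses)


@pytest.fixture(scope="session")
def popdata(small_design):
    """One simulated population shared by read-only tests."""
    ped = sd.simulate_pedigree(small_design, seed=1)
    founders = sd.simulate_founders(
        len(small_design.sires), len(small_design.dams), 800,
        n_chromosomes=5, seed=1, sire_ids=small_design.sires,
        dam_ids=small_design.dams)
    geno = sd.drop_genes(ped, founders, seed=2)
    A = popgs.a_matrix(ped)
    return {"design": small_design, "ped": ped, "founders": founders,
            "geno": geno, "A": A}


@pytest.fixture(scope="session")
def trio_pedigree():
    """Sire, dam, one offspring; plus a full-sib pair."""
    return popgs.Pedigree([
        ("s1", "0", "0"), ("d1", "0", "0"),
        ("o1", "s1", "d1"), ("o2", "s1", "d1"),
    ])


def rng(seed=0):
    return np.random.default_rng(seed)
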