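"""Shared fixtures: small canonical pedigrees and simulated studies."""

import numpy as np
import pytest

from linkgeo.pedio import Individual, Pedigree
from linkgeo.linkage import FamilyEngine
from linkgeo.synthdata import marker_panel, primary_design, simulate_pedigrees


@pytest.fixture(scope="session")
def sib_pair_pedigree():
    members = [
        Individual("f", "FAM", None, None, "male", "unaffected"),
        Individual("m", "FAM", None, None, "female", "unaffected"),
        Individual("c1", "FAM", "f", "m", "male", "affected"),
        Individual("c2", "FAM", "f", "m", "female", "affected"),
    ]
    return Pedigree("FAM", members)


@pytest.fixture(scope="session")
def sib_pair_engine(sib_pair_pedigree):
    return FamilyEngine(sib_pair_pedigree)


@pytest.fixture(scope="session")
def trio_pedigree():
    """Three-member family: typed child, partially typed parents."""
    members = [
        Individual("f", "TRIO", None, None, "male", "unaffected"),
        Individual("m", "TRIO", None, None, "female", "unaffected"),
        Individual("c", "TRIO", "f", "m", "male", "affected"),
    ]
    return Pedigree("TRIO", members)


@pytest.fixture(scope="session")
def primary_study():
    """Structures + marker panel of the primary design (no genotypes)."""
    cfg = primary_design()
    peds, religions = simulate_pedigrees(cfg, seed=11)
    mmap, freqs = marker_panel(cfg, seed=12)
    return cfg, peds, religions, mmap, freqs


def uniform_freqs(k):
    return {a: 1.0 / k for a in range(1, k + 1)}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
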