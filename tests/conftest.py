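import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from kinpred.simdata import (
    Pedigree,
    SimulationConfig,
    UNKNOWN,
    generate_pedigree,
    simulate_genotypes,
    unrelated_pedigree,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def _ped(rows) -> Pedigree:
    return Pedigree(pd.DataFrame(rows, columns=list(Pedigree.COLUMNS)))


@pytest.fixture(scope="session")
def toy_pedigrees() -> dict[str, Pedigree]:
    """Small named pedigrees (every one <= 20 members) covering trios, full
    sibs, half sibs, an inbred mating, and a three-generation family with
    cousins."""
    trio = _ped([
        ("P1", UNKNOWN, UNKNOWN, "M", "T", 0),
        ("P2", UNKNOWN, UNKNOWN, "F", "T", 0),
        ("C1", "P1", "P2", "M", "T", 1),
    ])
    nuclear = _ped([
        ("P1", UNKNOWN, UNKNOWN, "M", "N", 0),
        ("P2", UNKNOWN, UNKNOWN, "F", "N", 0),
        ("S1", "P1", "P2", "M", "N", 1),
        ("S2", "P1", "P2", "F", "N", 1),
        ("S3", "P1", "P2", "M", "N", 1),
    ])
    half_sibs = _ped([
        ("SIRE", UNKNOWN, UNKNOWN, "M", "H", 0),
        ("DAM1", UNKNOWN, UNKNOWN, "F", "H", 0),
        ("DAM2", UNKNOWN, UNKNOWN, "F", "H", 0),
        ("K1", "SIRE", "DAM1", "M", "H", 1),
        ("K2", "SIRE", "DAM2", "F", "H", 1),
    ])
    # D is the offspring of a sire x daughter mating: F(D) = 0.25
    inbred = _ped([
        ("A", UNKNOWN, UNKNOWN, "M", "I", 0),
        ("B", UNKNOWN, UNKNOWN, "F", "I", 0),
        ("C", "A", "B", "F", "I", 1),
        ("D", "A", "C", "M", "I", 2),
    ])
    cousins = generate_pedigree(
        SimulationConfig(n_families=1, sibship_size=2, n_generations=3, seed=0)
    )
    return {
        "trio": trio,
        "nuclear": nuclear,
        "half_sibs": half_sibs,
        "inbred": inbred,
        "cousins": cousins,
    }


@pytest.fixture(scope="session")
def small_dataset():
    """120 unrelated founders x 400 SNPs with genotypes — shared by tests
    that only need a modest polymorphic genotype matrix."""
    ped = unrelated_pedigree(120)
    cfg = SimulationConfig(n_families=1, n_snps=400, h2=0.5, seed=42)
    geno = simulate_genotypes(ped, cfg)
    return ped, cfg, geno


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
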