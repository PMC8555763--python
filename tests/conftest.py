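import numpy as np
import pytest

from forenpop.io_formats import GenotypeTable, LocusSpec
from forenpop.synthetic_data import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One shared default synthetic cohort (seeded)."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture
def small_panel():
    return [
        LocusSpec("D1", "A-STR"),
        LocusSpec("DYS1", "Y-STR"),
        LocusSpec("DYS385a-b", "Y-STR", copy_number=2),
        LocusSpec("X1", "X-STR"),
        LocusSpec("rs1", "IISNP"),
    ]


@pytest.fixture
def small_table(small_panel):
    cells = {
        ("s1", "D1"): ("14", "15"),
        ("s2", "D1"): ("14", "14"),
        ("s1", "DYS1"): ("17",),
        ("s2", "DYS1"): ("18",),
        ("s1", "DYS385a-b"): ("11", "14"),
        ("s2", "DYS385a-b"): ("12", "12"),
        ("s1", "X1"): ("9",),
        ("s2", "X1"): None,
        ("s1", "rs1"): ("A", "G"),
        ("s2", "rs1"): ("G", "G"),
    }
    return GenotypeTable(
        samples=["s1", "s2"],
        populations=["p1", "p1"],
        loci=small_panel,
        cells=cells,
    )


def random_genotype_table(seed: int) -> GenotypeTable:
    """A small random valid table exercising all cell arities."""
    rng = np.random.default_rng(seed)
    loci = [
        LocusSpec("AS1", "A-STR"),
        LocusSpec("YS1", "Y-STR"),
        LocusSpec("YM1", "Y-STR", copy_number=2),
        LocusSpec("SNP1", "IISNP"),
    ]
    n = int(rng.integers(2, 8))
    samples = [f"s{i}" for i in range(n)]
    cells = {}
    for s in samples:
        if rng.random() < 0.15:
            cells[(s, "AS1")] = None
        else:
            cells[(s, "AS1")] = tuple(
                sorted(str(rng.integers(10, 15)) for _ in range(2))
            )
        cells[(s, "YS1")] = (str(rng.integers(15, 20)),)
        cells[(s, "YM1")] = tuple(
            sorted(str(rng.integers(10, 14)) for _ in range(2))
        )
        cells[(s, "SNP1")] = tuple(sorted(rng.choice(list("AG"), size=2)))
    return GenotypeTable(
        samples=samples,
        populations=["p1"] * n,
        loci=loci,
        cells=cells,
    )
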