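import numpy as np
import pytest

from promoterpop.coalescent import RecombMap
from promoterpop.core import (
    GenotypeMatrix,
    HaplotypeSet,
    HaplotypeSource,
    Marker,
    Phenotype,
    VarClass,
)
from promoterpop.simulate import SimConfig, simulate_haplotypes


@pytest.fixture
def small_markers() -> list[Marker]:
    return [
        Marker(id="m1", position=-2315, var_class=VarClass.SNP,
               alleles=("A", "G"), rsid="rs1"),
        Marker(id="m2", position=-68, var_class=VarClass.SNP,
               alleles=("T", "A")),
        Marker(id="m3", position=1531, var_class=VarClass.SSLP,
               alleles=("6", "7", "8")),
    ]


@pytest.fixture
def small_calls(small_markers) -> GenotypeMatrix:
    return GenotypeMatrix(
        subjects=["s1", "s2", "s3"],
        marker_ids=[m.id for m in small_markers],
        calls=[
            [("A", "A"), ("T", "A"), ("6", "7")],
            [("A", "G"), ("T", "T"), ("7", "7")],
            [None, ("A", "A"), ("6", "8")],
        ],
        phenotype={"s1": Phenotype.CASE, "s2": Phenotype.CONTROL,
                   "s3": Phenotype.CONTROL},
    )


def make_haps(vectors, marker_ids=None, source=HaplotypeSource.INPUT):
    """Haplotype set from a list of allele tuples (pairs -> subjects)."""
    n = len(vectors)
    assert n % 2 == 0
    m = len(vectors[0])
    return HaplotypeSet(
        haplotypes=[tuple(v) for v in vectors],
        subject_of=[f"S{i // 2 + 1}" for i in range(n)],
        marker_ids=marker_ids or [f"m{j}" for j in range(m)],
        source=source,
    )


@pytest.fixture(scope="session")
def neutral_cohort():
    """One deterministic 60-chromosome SNP-only cohort, no recombination."""
    cfg = SimConfig(
        n_chromosomes=60,
        theta_per_kb=1.0,
        recomb_map=RecombMap(18_000, 0.0),
        class_mix={VarClass.SNP: 1.0},
        seed=42,
    )
    return simulate_haplotypes(cfg)


@pytest.fixture(scope="session")
def mixed_cohort():
    """60 chromosomes, all six variant classes, mild recombination."""
    cfg = SimConfig(
        n_chromosomes=60,
        theta_per_kb=1.5,
        recomb_map=RecombMap(18_000, 0.3, ((9_000, 2_000, 8.0),)),
        seed=7,
    )
    return simulate_haplotypes(cfg)
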