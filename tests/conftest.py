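"""Shared fixtures and dataset builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from ssrpopgen import GenotypeMatrix


def build_matrix(pops: dict[str, list[list[tuple[int, int]]]],
                 loci: list[str] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {pop: [individual, ...]} where each
    individual is a list of (allele1, allele2) pairs, one per locus."""
    n_loci = len(next(iter(pops.values()))[0])
    if loci is None:
        loci = [f"L{j + 1}" for j in range(n_loci)]
    individuals, pop_of, rows = [], {}, []
    for pop, inds in pops.items():
        for k, genotype in enumerate(inds):
            name = f"{pop}_i{k + 1}"
            individuals.append(name)
            pop_of[name] = pop
            rows.append(genotype)
    calls = np.array(rows, dtype=np.int64)
    return GenotypeMatrix(individuals, loci, pop_of, calls)


def random_matrix(rng: np.random.Generator,
                  max_pops: int = 5, max_loci: int = 6, max_inds: int = 10,
                  missing_rate: float = 0.1) -> GenotypeMatrix:
    """Small random dataset for property tests (alleles from a 4-label pool)."""
    n_pops = int(rng.integers(1, max_pops + 1))
    n_loci = int(rng.integers(1, max_loci + 1))
    pool = np.array([100, 102, 104, 106])
    pops: dict[str, list[list[tuple[int, int]]]] = {}
    for p in range(n_pops):
        n_ind = int(rng.integers(1, max_inds + 1))
        inds = []
        for _ in range(n_ind):
            genotype = []
            for _ in range(n_loci):
                if rng.random() < missing_rate:
                    genotype.append((0, 0))
                else:
                    genotype.append(tuple(rng.choice(pool, size=2)))
            inds.append(genotype)
        pops[f"P{p + 1}"] = inds
    return build_matrix(pops)


@pytest.fixture
def two_pop_one_locus() -> GenotypeMatrix:
    """Pop A = one heterozygote 150/154, Pop B = one homozygote 150/150."""
    return build_matrix({"A": [[(150, 154)]], "B": [[(150, 150)]]})


@pytest.fixture
def worked_two_locus() -> GenotypeMatrix:
    """The worked 2-population, 2-individual, 2-locus table used for the
    frozen Nei-distance golden value."""
    return build_matrix(
        {
            "A": [[(150, 150), (200, 202)], [(150, 154), (200, 200)]],
            "B": [[(154, 154), (202, 202)], [(150, 154), (202, 200)]],
        }
    )
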