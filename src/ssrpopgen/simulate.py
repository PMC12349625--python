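"""Synthetic multipopulation SSR genotype generator.

Population allele frequencies follow the Balding–Nichols model: for
each locus an ancestral frequency vector is drawn from a symmetric
Dirichlet(1), and each population's vector from a Dirichlet with that
mean and concentration ``(1 - theta) / theta``, so ``theta`` is
directly interpretable as the expected Fst among populations.

Within a population, diploid genotypes are drawn with inbreeding
coefficient ``f``:

* ``f >= 0``: ``P(hom i) = p_i^2 + f p_i (1 - p_i)``,
  ``P(het ij) = 2 p_i p_j (1 - f)`` (sums to 1 exactly);
* ``f < 0`` (heterozygote excess, as in outcrossing populations):
  heterozygote probabilities are inflated by ``(1 - f)`` over the
  Hardy–Weinberg homozygote terms and the vector renormalized.

Allele identities are abstract integer labels (offset to look like
fragment sizes); no stepwise mutation model is imposed because the
downstream statistics use identity-in-state only.  Calls are masked
missing independently at ``missing_rate``.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "SimConfig",
    "simulate",
    "make_single_individual_fixture",
    "make_gorge_scenario",
    "GORGE_POP_SIZES",
    "GORGE_GROUPS",
]

#: population sizes of the emulated field study (54 individuals, 11 populations)
GORGE_POP_SIZES = (3, 18, 1, 6, 5, 1, 3, 6, 3, 4, 4)

#: population index groups per gorge: 4 + 3 + 4 populations
GORGE_GROUPS = (
    ("Pop1", "Pop2", "Pop3", "Pop4"),        # Bolshoy Aksu
    ("Pop8", "Pop9", "Pop10"),               # Turgen
    ("Pop5", "Pop6", "Pop7", "Pop11"),       # Bolshoy Kyrgyzsay
)

_ALLELE_OFFSET = 100  # abstract labels rendered as plausible fragment sizes


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset.

    ``theta`` is the Balding–Nichols differentiation parameter (target
    Fst, in (0, 1)); ``f_within`` the within-population inbreeding
    coefficient in [-1, 1] (negative = heterozygote excess);
    ``missing_rate`` the independent per-call missingness probability.
    """

    n_pops: int = 11
    pop_sizes: tuple[int, ...] = GORGE_POP_SIZES
    n_loci: int = 13
    alleles_per_locus: int = 6
    theta: float = 0.22
    f_within: float = -0.3
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError(
                f"pop_sizes has {len(self.pop_sizes)} entries for n_pops={self.n_pops}"
            )
        if any(s < 1 for s in self.pop_sizes):
            raise ValueError("every population size must be >= 1")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.alleles_per_locus < 2:
            raise ValueError("alleles_per_locus must be >= 2")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must be in (0, 1)")
        if not -1.0 <= self.f_within <= 1.0:
            raise ValueError("f_within must be in [-1, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


def _genotype_distribution(p: np.ndarray, f: float) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Unordered-genotype support and probabilities for frequencies ``p``, inbreeding ``f``."""
    k = p.size
    genotypes: list[tuple[int, int]] = []
    probs: list[float] = []
    for i in range(k):
        for j in range(i, k):
            if i == j:
                if f >= 0.0:
                    pr = p[i] ** 2 + f * p[i] * (1.0 - p[i])
                else:
                    pr = p[i] ** 2
            else:
                pr = 2.0 * p[i] * p[j] * (1.0 - f)
            genotypes.append((i, j))
            probs.append(pr)
    arr = np.asarray(probs)
    arr = np.clip(arr, 0.0, None)
    total = arr.sum()
    if total <= 0.0:  # single-allele degenerate case with f = 1 noise
        arr = np.zeros_like(arr)
        arr[0] = 1.0
        total = 1.0
    return genotypes, arr / total


def _population_frequencies(rng: np.random.Generator, ancestral: np.ndarray, theta: float) -> np.ndarray:
    """Balding–Nichols draw: Dirichlet with mean ``ancestral``, concentration (1-theta)/theta."""
    conc = (1.0 - theta) / theta
    alpha = np.clip(ancestral * conc, 1e-9, None)
    return rng.dirichlet(alpha)


def simulate(config: SimConfig) -> GenotypeMatrix:
    """Draw one multipopulation diploid SSR dataset under the configured model."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_total = sum(config.pop_sizes)
    calls = np.zeros((n_total, config.n_loci, 2), dtype=np.int64)

    pop_labels = [f"Pop{i + 1}" for i in range(config.n_pops)]
    individuals: list[str] = []
    pop_of: dict[str, str] = {}
    for p, (label, size) in enumerate(zip(pop_labels, config.pop_sizes)):
        for s in range(size):
            ind = f"{label}_ind{s + 1}"
            individuals.append(ind)
            pop_of[ind] = label

    for locus in range(config.n_loci):
        ancestral = rng.dirichlet(np.ones(config.alleles_per_locus))
        row = 0
        for size in config.pop_sizes:
            p = _population_frequencies(rng, ancestral, config.theta)
            genotypes, probs = _genotype_distribution(p, config.f_within)
            draws = rng.choice(len(genotypes), size=size, p=probs)
            for d in draws:
                i, j = genotypes[d]
                calls[row, locus] = (
                    _ALLELE_OFFSET + 2 * i,
                    _ALLELE_OFFSET + 2 * j,
                )
                row += 1

    if config.missing_rate > 0.0:
        mask = rng.random((n_total, config.n_loci)) < config.missing_rate
        calls[mask] = MISSING

    loci = [f"Locus{j + 1}" for j in range(config.n_loci)]
    return GenotypeMatrix(individuals, loci, pop_of, calls)


def make_single_individual_fixture(n_loci: int, n_het: int) -> GenotypeMatrix:
    """One population of one individual, heterozygous at exactly ``n_het`` loci.

    This is the exact configuration implied by a published summary row
    with N = 1: every index is then a closed-form function of the
    heterozygous-locus count (e.g. mean Ho = n_het / n_loci and mean
    Shannon I = n_het * ln(2) / n_loci).
    """
    if not 0 <= n_het <= n_loci:
        raise ValueError(f"n_het must be in [0, {n_loci}], got {n_het}")
    calls = np.zeros((1, n_loci, 2), dtype=np.int64)
    for j in range(n_loci):
        if j < n_het:
            calls[0, j] = (150, 154)
        else:
            calls[0, j] = (150, 150)
    loci = [f"Locus{j + 1}" for j in range(n_loci)]
    return GenotypeMatrix(["ind1"], loci, {"ind1": "Pop1"}, calls)


def make_gorge_scenario(seed: int) -> GenotypeMatrix:
    """Hierarchically structured dataset emulating the three-gorge study design.

    Eleven populations with the study's sizes (54 individuals total) in
    three geographic groups; gorge-level frequency vectors diverge from
    the ancestral pool at theta = 0.25 and populations within a gorge
    diverge from their gorge pool at theta = 0.05, so between-gorge
    differentiation dominates and a 3-cluster cut of the UPGMA tree
    should recover the groups.  13 loci, 6 alleles each, f = -0.3
    (heterozygote excess as observed in outcrossing wild stands).
    """
    theta_between = 0.25
    theta_within = 0.05
    n_loci = 13
    alleles_per_locus = 6
    f_within = -0.3

    rng = np.random.default_rng(seed)
    pop_labels = [f"Pop{i + 1}" for i in range(len(GORGE_POP_SIZES))]
    gorge_of = {pop: gi for gi, group in enumerate(GORGE_GROUPS) for pop in group}

    n_total = sum(GORGE_POP_SIZES)
    calls = np.zeros((n_total, n_loci, 2), dtype=np.int64)
    individuals: list[str] = []
    pop_of: dict[str, str] = {}
    for label, size in zip(pop_labels, GORGE_POP_SIZES):
        for s in range(size):
            ind = f"{label}_ind{s + 1}"
            individuals.append(ind)
            pop_of[ind] = label

    for locus in range(n_loci):
        ancestral = rng.dirichlet(np.ones(alleles_per_locus))
        gorge_freqs = [
            _population_frequencies(rng, ancestral, theta_between)
            for _ in GORGE_GROUPS
        ]
        row = 0
        for label, size in zip(pop_labels, GORGE_POP_SIZES):
            p = _population_frequencies(rng, gorge_freqs[gorge_of[label]], theta_within)
            genotypes, probs = _genotype_distribution(p, f_within)
            draws = rng.choice(len(genotypes), size=size, p=probs)
            for d in draws:
                i, j = genotypes[d]
                calls[row, locus] = (_ALLELE_OFFSET + 2 * i, _ALLELE_OFFSET + 2 * j)
                row += 1

    loci = [f"Locus{j + 1}" for j in range(n_loci)]
    return GenotypeMatrix(individuals, loci, pop_of, calls)
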