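"""Per-(population, locus) diversity indices and population summaries.

For allele frequencies :math:`p_i` estimated from the :math:`N_l`
non-missing calls of one population at one locus:

* ``Na`` — number of distinct alleles observed;
* ``Ne = 1 / sum(p_i^2)`` — effective number of alleles;
* ``I = -sum(p_i ln p_i)`` — Shannon information index (natural log);
* ``Ho`` — fraction of heterozygous individuals;
* ``He = 1 - sum(p_i^2)`` — expected heterozygosity under random mating;
* ``uHe = (2 N_l / (2 N_l - 1)) He`` — small-sample-corrected He;
* ``F = (He - Ho) / He`` — fixation index; undefined at fixed loci
  (``He = 0``), where it is 0/0.

Per-locus realized sample sizes ``N_l`` (not the nominal population
size) enter ``Ho`` and ``uHe``, as unbiased estimators require.  The
percentage of polymorphic loci counts loci with at least two observed
alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .genotypes import GenotypeMatrix, NoDataError, allele_frequencies

__all__ = ["LocusPopStats", "PopSummary", "locus_stats", "population_summary", "grand_means"]


@dataclass(frozen=True)
class LocusPopStats:
    """Diversity indices for one population at one locus.

    ``f`` is ``None`` when the locus is fixed in the population
    (``he == 0``), where the fixation index is indeterminate.
    """

    population: str
    locus: str
    n: int
    na: int
    ne: float
    i: float
    ho: float
    he: float
    uhe: float
    f: float | None


@dataclass(frozen=True)
class PopSummary:
    """Unweighted means of the per-locus indices for one population.

    ``f`` averages only loci where the fixation index is defined; it is
    ``None`` if no locus has ``he > 0``.  ``pct_polymorphic`` is the
    percentage of loci (out of all ``n_loci``) with at least two
    observed alleles.
    """

    population: str
    n: float
    na: float
    ne: float
    i: float
    ho: float
    he: float
    uhe: float
    f: float | None
    pct_polymorphic: float
    n_loci: int


def locus_stats(g: GenotypeMatrix, population: str, locus: str) -> LocusPopStats:
    """Compute all per-cell diversity indices; raises :class:`NoDataError` if N_l = 0."""
    freqs = allele_frequencies(g, population, locus)  # raises NoDataError
    pairs = g.calls_at(population, locus)
    n_l = pairs.shape[0]

    p = list(freqs.values())
    sum_p2 = sum(x * x for x in p)
    na = len(p)
    ne = 1.0 / sum_p2
    shannon = -sum(x * math.log(x) for x in p if x > 0.0)
    ho = float((pairs[:, 0] != pairs[:, 1]).sum()) / n_l
    he = 1.0 - sum_p2
    uhe = (2.0 * n_l / (2.0 * n_l - 1.0)) * he
    f = (he - ho) / he if he > 0.0 else None
    return LocusPopStats(str(population), str(locus), n_l, na, ne, shannon, ho, he, uhe, f)


def population_summary(g: GenotypeMatrix, population: str) -> PopSummary:
    """Unweighted means across loci for one population (the per-row summary).

    Loci with no data in this population are skipped in the means and
    count as non-polymorphic; loci where ``F`` is undefined (fixed) are
    excluded from the mean fixation index rather than treated as zero.
    """
    view = g.population_view(population)
    cells: list[LocusPopStats] = []
    for locus in g.loci:
        try:
            cells.append(locus_stats(g, population, locus))
        except NoDataError:
            continue
    if not cells:
        raise NoDataError(str(population), "<all loci>")

    def mean(values: list[float]) -> float:
        return sum(values) / len(values)

    f_defined = [c.f for c in cells if c.f is not None]
    n_poly = sum(1 for c in cells if c.na >= 2)
    return PopSummary(
        population=str(population),
        n=float(view.n_total),
        na=mean([float(c.na) for c in cells]),
        ne=mean([c.ne for c in cells]),
        i=mean([c.i for c in cells]),
        ho=mean([c.ho for c in cells]),
        he=mean([c.he for c in cells]),
        uhe=mean([c.uhe for c in cells]),
        f=mean(f_defined) if f_defined else None,
        pct_polymorphic=100.0 * n_poly / g.n_loci,
        n_loci=len(cells),
    )


def grand_means(summaries: list[PopSummary]) -> PopSummary:
    """Unweighted mean of per-population means (the table's bottom row).

    ``n`` becomes the mean sample size.  The mean fixation index
    averages the populations where it is defined.
    """
    if not summaries:
        raise ValueError("need at least one population summary")

    def mean(values: list[float]) -> float:
        return sum(values) / len(values)

    f_defined = [s.f for s in summaries if s.f is not None]
    return PopSummary(
        population="Mean",
        n=mean([s.n for s in summaries]),
        na=mean([s.na for s in summaries]),
        ne=mean([s.ne for s in summaries]),
        i=mean([s.i for s in summaries]),
        ho=mean([s.ho for s in summaries]),
        he=mean([s.he for s in summaries]),
        uhe=mean([s.uhe for s in summaries]),
        f=mean(f_defined) if f_defined else None,
        pct_polymorphic=mean([s.pct_polymorphic for s in summaries]),
        n_loci=max(s.n_loci for s in summaries),
    )
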