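"""Hierarchical F-statistics (Fis, Fit, Fst) and gene-flow estimates per locus.

Gene-diversity formulation with UNWEIGHTED population means (the
convention of GenAlEx and Nei's 1977 treatment), not the
Weir–Cockerham variance-components estimator:

* ``Hi`` — mean observed heterozygosity across populations;
* ``Hs`` — mean within-population expected heterozygosity;
* ``Ht = 1 - sum(pbar_i^2)`` with ``pbar`` the unweighted mean of the
  per-population allele-frequency vectors;
* ``Fis = (Hs - Hi)/Hs``, ``Fit = (Ht - Hi)/Ht``, ``Fst = (Ht - Hs)/Ht``.

These satisfy the partition identity ``(1 - Fit) = (1 - Fis)(1 - Fst)``
exactly, and ``Ht >= Hs`` by concavity of ``1 - sum(p^2)`` under
frequency averaging, so ``Fst`` lies in ``[0, 1]``.  Gene flow is the
island-model estimate ``Nm = (1 - Fst) / (4 Fst)``.  No small-sample
correction is applied to Hs or Ht.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix, NoDataError, allele_frequencies
from .diversity import locus_stats

logger = logging.getLogger(__name__)

__all__ = [
    "FStatRow",
    "FStatTable",
    "fstats_locus",
    "nm_from_fst",
    "fstats_table",
    "column_mean_se",
]


@dataclass(frozen=True)
class FStatRow:
    """Per-locus F-statistics across populations.

    ``fis`` is ``None`` when ``Hs = 0`` and all three are ``None`` when
    the locus is monomorphic overall (``Ht = 0``).  ``nm`` is ``None``
    when ``Fst = 0`` (no differentiation: the island-model estimate
    diverges).  ``n_pops`` counts the populations with data that
    entered the means.
    """

    locus: str
    hi: float
    hs: float
    ht: float
    fis: float | None
    fit: float | None
    fst: float | None
    nm: float | None
    n_pops: int


@dataclass(frozen=True)
class FStatTable:
    """Per-locus rows plus unweighted column means and standard errors."""

    rows: list[FStatRow]
    mean: dict[str, float | None]
    se: dict[str, float | None]


def nm_from_fst(fst: float) -> float:
    """Island-model migrants per generation, ``(1 - Fst) / (4 Fst)``; needs Fst > 0."""
    if not fst > 0.0:
        raise ValueError(f"Nm requires Fst > 0, got {fst}")
    return (1.0 - fst) / (4.0 * fst)


def fstats_locus(g: GenotypeMatrix, locus: str) -> FStatRow:
    """F-statistics at one locus over all populations with data there."""
    pops = []
    for pop in g.populations:
        try:
            stats = locus_stats(g, pop, locus)
        except NoDataError:
            continue
        pops.append((pop, stats))
    if len(pops) < 2:
        raise NoDataError("<2 populations>", str(locus))

    hi = float(np.mean([s.ho for _, s in pops]))
    hs = float(np.mean([s.he for _, s in pops]))

    # unweighted mean of per-population frequency vectors over the allele union
    freq_maps = [allele_frequencies(g, pop, locus) for pop, _ in pops]
    alleles = sorted({a for fm in freq_maps for a in fm})
    pbar = np.array([np.mean([fm.get(a, 0.0) for fm in freq_maps]) for a in alleles])
    ht = float(1.0 - np.sum(pbar**2))

    fis = (hs - hi) / hs if hs > 0.0 else None
    if ht > 0.0:
        fit = (ht - hi) / ht
        fst = (ht - hs) / ht
        fst = max(fst, 0.0)  # guard against rounding at Ht ~= Hs
    else:
        fit = fst = None
        fis = None
    nm = nm_from_fst(fst) if fst is not None and fst > 0.0 else None
    return FStatRow(str(locus), hi, hs, ht, fis, fit, fst, nm, len(pops))


_COLUMNS = ("fis", "fit", "fst", "nm")


def fstats_table(g: GenotypeMatrix) -> FStatTable:
    """Per-locus F-statistic rows plus column means and standard errors.

    The mean is the unweighted mean of the defined per-locus values and
    the SE is the sample standard deviation over sqrt(number of defined
    values); undefined cells are excluded with a logged warning.  With a
    single defined value the SE is 0 by convention.
    """
    if len(g.populations) < 2:
        raise ValueError("F-statistics need at least two populations")
    rows = []
    for locus in g.loci:
        try:
            rows.append(fstats_locus(g, locus))
        except NoDataError:
            logger.warning("locus %r skipped: fewer than two populations with data", locus)
    if not rows:
        raise ValueError("no locus has data in two or more populations")

    mean: dict[str, float | None] = {}
    se: dict[str, float | None] = {}
    for col in _COLUMNS:
        values = [getattr(r, col) for r in rows]
        defined = [v for v in values if v is not None]
        if len(defined) < len(values):
            logger.warning(
                "column %s: %d undefined cell(s) excluded from mean/SE",
                col, len(values) - len(defined),
            )
        if not defined:
            mean[col] = se[col] = None
            continue
        mean[col] = float(np.mean(defined))
        se[col] = (
            float(np.std(defined, ddof=1) / math.sqrt(len(defined)))
            if len(defined) > 1
            else 0.0
        )
    return FStatTable(rows, mean, se)


def column_mean_se(values: list[float]) -> tuple[float, float]:
    """Mean and standard error (sample SD / sqrt(n)) of a statistic column."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty column")
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))
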