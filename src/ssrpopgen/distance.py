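"""Nei's (1978) unbiased genetic distance between populations.

For populations A and B with per-locus allele frequencies ``x`` and
``y`` estimated from ``N_A`` and ``N_B`` diploid individuals:

* between-population gene identity ``J_AB = sum(x_i y_i)``;
* unbiased within-population identity
  ``Jhat = (2N sum(p_i^2) - 1) / (2N - 1)``;
* distance ``D = -ln( Jbar_AB / sqrt(Jbar_A Jbar_B) )``, where the bars
  denote arithmetic means over the loci both populations were typed at.

Loci missing in either population are excluded pairwise, not listwise.
The unbiased correction can make D slightly negative by sampling noise;
such values are clamped to 0 with a warning.  If the populations share
no allele at any locus (``Jbar_AB = 0``) the distance is infinite;
``math.inf`` is preserved in the matrix, and a finite sentinel
(10 x the largest finite entry) is substituted only when clustering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix, allele_frequencies

logger = logging.getLogger(__name__)

__all__ = ["DistanceMatrix", "nei_unbiased_distance", "distance_matrix"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric population-by-population distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("diagonal is not zero")
        finite = v[np.isfinite(v)]
        if finite.size and finite.min() < 0.0:
            raise ValueError("negative distances")
        object.__setattr__(self, "values", v)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def with_inf_sentinel(self) -> "DistanceMatrix":
        """Replace infinite entries by 10 x the largest finite off-diagonal entry."""
        v = self.values.copy()
        if np.isinf(v).any():
            finite = v[np.isfinite(v)]
            sentinel = 10.0 * (finite.max() if finite.size else 1.0)
            if sentinel <= 0.0:
                sentinel = 1.0
            v[np.isinf(v)] = sentinel
            logger.warning("infinite distances replaced by sentinel %.6g for clustering", sentinel)
        return DistanceMatrix(self.labels, v)


def _unbiased_identity(freqs: dict[int, float], n: int) -> float:
    """Nei's unbiased within-population gene identity (2N sum p^2 - 1)/(2N - 1)."""
    sum_p2 = sum(p * p for p in freqs.values())
    return (2.0 * n * sum_p2 - 1.0) / (2.0 * n - 1.0) if n > 0 else float("nan")


def nei_unbiased_distance(g: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Nei's unbiased distance between two populations over their shared loci."""
    jab, ja, jb = [], [], []
    for locus in g.loci:
        pairs_a = g.calls_at(pop_a, locus)
        pairs_b = g.calls_at(pop_b, locus)
        if pairs_a.shape[0] == 0 or pairs_b.shape[0] == 0:
            continue
        x = allele_frequencies(g, pop_a, locus)
        y = allele_frequencies(g, pop_b, locus)
        jab.append(sum(px * y.get(a, 0.0) for a, px in x.items()))
        ja.append(_unbiased_identity(x, pairs_a.shape[0]))
        jb.append(_unbiased_identity(y, pairs_b.shape[0]))
    if not jab:
        raise ValueError(f"populations {pop_a!r} and {pop_b!r} share no typed locus")
    jab_bar = float(np.mean(jab))
    ja_bar = float(np.mean(ja))
    jb_bar = float(np.mean(jb))
    if ja_bar <= 0.0 or jb_bar <= 0.0:
        raise ValueError(
            f"non-positive mean unbiased identity for pair ({pop_a!r}, {pop_b!r}); "
            f"single all-heterozygous individuals cannot anchor the unbiased estimator"
        )
    if jab_bar <= 0.0:
        return math.inf
    d = -math.log(jab_bar / math.sqrt(ja_bar * jb_bar))
    if d < 0.0:
        logger.warning(
            "negative distance %.6g for pair (%s, %s) clamped to 0 "
            "(unbiased-correction sampling noise)", d, pop_a, pop_b,
        )
        d = 0.0
    return d


def distance_matrix(g: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs Nei unbiased distances in population order of first appearance."""
    pops = g.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    n = len(pops)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = nei_unbiased_distance(g, pops[i], pops[j])
            except ValueError as exc:
                raise ValueError(f"pair ({pops[i]!r}, {pops[j]!r}): {exc}") from exc
            v[i, j] = v[j, i] = d
    return DistanceMatrix(tuple(pops), v)
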