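"""Independent brute-force oracles.

These deliberately re-derive every quantity from first principles with
naive loops over raw calls (no shared code with the package internals),
so that agreement with the implementation is a genuine two-route check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def tally_frequencies(g, population, locus):
    """Allele frequencies by direct tally over all calls."""
    counts: Counter = Counter()
    j = list(g.loci).index(locus)
    for i, ind in enumerate(g.individuals):
        if g.pop_of[ind] != population:
            continue
        a, b = int(g.calls[i, j, 0]), int(g.calls[i, j, 1])
        if a == 0 and b == 0:
            continue
        counts[a] += 1
        counts[b] += 1
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()}, total // 2


def diversity_oracle(g, population, locus):
    """All per-cell diversity indices evaluated literally from the formulas."""
    freqs, n = tally_frequencies(g, population, locus)
    p = list(freqs.values())
    j = list(g.loci).index(locus)
    het = sum(
        1
        for i, ind in enumerate(g.individuals)
        if g.pop_of[ind] == population
        and g.calls[i, j, 0] != 0
        and g.calls[i, j, 0] != g.calls[i, j, 1]
    )
    he = 1 - sum(x * x for x in p)
    return {
        "n": n,
        "na": len(p),
        "ne": 1 / sum(x * x for x in p),
        "i": -sum(x * math.log(x) for x in p),
        "ho": het / n,
        "he": he,
        "uhe": (2 * n / (2 * n - 1)) * he,
        "f": (he - het / n) / he if he > 0 else None,
    }


def fstats_oracle(g, locus):
    """Gene-diversity F-statistics evaluated literally from the definitions."""
    per_pop = []
    for pop in g.populations:
        freqs, n = tally_frequencies(g, pop, locus)
        if n == 0:
            continue
        d = diversity_oracle(g, pop, locus)
        per_pop.append((freqs, d["ho"], d["he"]))
    hi = sum(ho for _, ho, _ in per_pop) / len(per_pop)
    hs = sum(he for _, _, he in per_pop) / len(per_pop)
    alleles = sorted({a for f, _, _ in per_pop for a in f})
    pbar = {a: sum(f.get(a, 0.0) for f, _, _ in per_pop) / len(per_pop) for a in alleles}
    ht = 1 - sum(x * x for x in pbar.values())
    out = {"hi": hi, "hs": hs, "ht": ht}
    out["fis"] = (hs - hi) / hs if hs > 0 else None
    out["fit"] = (ht - hi) / ht if ht > 0 else None
    out["fst"] = (ht - hs) / ht if ht > 0 else None
    return out


def nei_oracle(g, pop_a, pop_b):
    """Nei-1978 unbiased distance evaluated literally, pairwise over shared loci."""
    jab, ja, jb = [], [], []
    for locus in g.loci:
        x, na = tally_frequencies(g, pop_a, locus)
        y, nb = tally_frequencies(g, pop_b, locus)
        if na == 0 or nb == 0:
            continue
        jab.append(sum(x[a] * y.get(a, 0.0) for a in x))
        ja.append((2 * na * sum(p * p for p in x.values()) - 1) / (2 * na - 1))
        jb.append((2 * nb * sum(p * p for p in y.values()) - 1) / (2 * nb - 1))
    jab_bar = sum(jab) / len(jab)
    ja_bar = sum(ja) / len(ja)
    jb_bar = sum(jb) / len(jb)
    if jab_bar <= 0:
        return math.inf
    return max(0.0, -math.log(jab_bar / math.sqrt(ja_bar * jb_bar)))


def upgma_naive(labels, matrix):
    """O(n^3) agglomeration recomputing every cluster distance from scratch
    as the mean of the original inter-leaf distances (the definitional form
    of average linkage, not the incremental update)."""
    matrix = np.asarray(matrix, dtype=float)
    clusters = [frozenset([i]) for i in range(len(labels))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = float(
                    np.mean([matrix[i, j] for i in clusters[a] for j in clusters[b]])
                )
                rep = tuple(sorted((min(labels[i] for i in clusters[a]),
                                    min(labels[j] for j in clusters[b]))))
                key = (d, rep)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (dmin, _), a, b = best
        merges.append((clusters[a], clusters[b], dmin / 2.0))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges
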