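"""Per-cell diversity indices, population summaries and grand means."""

import math

import numpy as np
import pytest

from ssrpopgen import (
    NoDataError,
    grand_means,
    locus_stats,
    make_single_individual_fixture,
    population_summary,
    round_half_away,
)
from ssrpopgen.diversity import PopSummary

from conftest import build_matrix, random_matrix
from oracles import diversity_oracle


class TestLocusStats:
    def test_single_heterozygote(self):
        g = build_matrix({"A": [[(150, 154)]]})
        s = locus_stats(g, "A", "L1")
        assert s.na == 2
        assert s.ne == pytest.approx(2.0)
        assert s.i == pytest.approx(math.log(2))
        assert s.ho == 1.0
        assert s.he == pytest.approx(0.5)
        assert s.uhe == pytest.approx(1.0)  # (2N/(2N-1)) He = 2 * 0.5 at N = 1
        assert s.f == pytest.approx(-1.0)

    def test_monomorphic_locus(self):
        g = build_matrix({"A": [[(150, 150)], [(150, 150)]]})
        s = locus_stats(g, "A", "L1")
        assert (s.na, s.ne, s.i, s.ho, s.he, s.uhe) == (1, 1.0, 0.0, 0.0, 0.0, 0.0)
        assert s.f is None  # fixation index is 0/0 at a fixed locus

    def test_two_individual_example(self):
        g = build_matrix({"A": [[(150, 150)], [(150, 154)]]})
        s = locus_stats(g, "A", "L1")
        assert s.he == pytest.approx(0.375)
        assert s.ho == pytest.approx(0.5)
        assert s.ne == pytest.approx(1.6)
        assert s.i == pytest.approx(0.5623, abs=5e-5)
        assert s.uhe == pytest.approx(0.5)  # (4/3) * 0.375

    def test_no_data_raises(self):
        g = build_matrix({"A": [[(0, 0), (150, 150)]]})
        with pytest.raises(NoDataError):
            locus_stats(g, "A", "L1")

    def test_agrees_with_literal_formula_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            g = random_matrix(rng, missing_rate=0.0)
            for pop in g.populations:
                for locus in g.loci:
                    want = diversity_oracle(g, pop, locus)
                    got = locus_stats(g, pop, locus)
                    for key in ("na", "ne", "i", "ho", "he", "uhe"):
                        assert getattr(got, key) == pytest.approx(want[key]), (pop, locus, key)


class TestPopulationSummary:
    def test_single_individual_11_of_13_heterozygous(self):
        """A one-individual population heterozygous at 11 of 13 loci has every
        index in closed form (the published Pop3 row: 1.846/1.846/0.587/
        0.846/0.423/0.846, 84.62% polymorphic)."""
        s = population_summary(make_single_individual_fixture(13, 11), "Pop1")
        assert round_half_away(s.na) == 1.846
        assert round_half_away(s.ne) == 1.846
        assert round_half_away(s.i) == 0.587
        assert round_half_away(s.ho) == 0.846
        assert round_half_away(s.he) == 0.423
        assert round_half_away(s.uhe) == 0.846
        assert round_half_away(s.pct_polymorphic, 2) == 84.62

    def test_single_individual_9_of_13_heterozygous(self):
        """The published Pop6 row: 1.692/0.480/0.692/0.346/0.692, 69.23%."""
        s = population_summary(make_single_individual_fixture(13, 9), "Pop1")
        assert round_half_away(s.na) == 1.692
        assert round_half_away(s.ne) == 1.692
        assert round_half_away(s.i) == 0.480
        assert round_half_away(s.ho) == 0.692
        assert round_half_away(s.he) == 0.346
        assert round_half_away(s.uhe) == 0.692
        assert round_half_away(s.pct_polymorphic, 2) == 69.23

    def test_all_monomorphic(self):
        s = population_summary(make_single_individual_fixture(5, 0), "Pop1")
        assert s.pct_polymorphic == 0.0
        assert s.f is None  # no locus with He > 0, mean F undefined

    def test_mean_f_excludes_fixed_loci(self):
        """Mean F averages only loci where F is defined, rather than
        counting fixed loci as zero."""
        g = build_matrix({"A": [[(150, 154), (200, 200)], [(150, 154), (200, 200)]]})
        s = population_summary(g, "A")
        assert s.f == pytest.approx(-1.0)  # only L1 enters; L2 is fixed

    def test_means_lie_within_per_locus_ranges(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            g = random_matrix(rng)
            for pop in g.populations:
                try:
                    s = population_summary(g, pop)
                except NoDataError:
                    continue
                cells = []
                for locus in g.loci:
                    try:
                        cells.append(locus_stats(g, pop, locus))
                    except NoDataError:
                        pass
                for key in ("na", "ne", "i", "ho", "he", "uhe"):
                    values = [float(getattr(c, key)) for c in cells]
                    assert min(values) - 1e-12 <= getattr(s, key) <= max(values) + 1e-12


class TestGrandMeans:
    def test_single_population_identity(self):
        s = population_summary(make_single_individual_fixture(13, 11), "Pop1")
        gm = grand_means([s])
        assert (gm.na, gm.ne, gm.i, gm.ho) == (s.na, s.ne, s.i, s.ho)

    def test_published_ho_and_uhe_columns(self):
        """The grand mean over the 11 published per-population Ho values is
        0.759 and over the uHe values 0.736."""
        ho = [0.615, 0.628, 0.846, 0.744, 0.769, 0.692, 0.769, 0.782, 0.872, 0.904, 0.731]
        uhe = [0.800, 0.616, 0.846, 0.772, 0.718, 0.692, 0.692, 0.709, 0.723, 0.777, 0.750]
        summaries = [
            PopSummary(population=f"Pop{k + 1}", n=1, na=0, ne=0, i=0,
                       ho=h, he=0, uhe=u, f=None, pct_polymorphic=0, n_loci=13)
            for k, (h, u) in enumerate(zip(ho, uhe))
        ]
        gm = grand_means(summaries)
        assert round_half_away(gm.ho) == 0.759
        assert round_half_away(gm.uhe) == 0.736


class TestInvariants:
    def test_hill_ordering(self):
        """Ne <= exp(I) <= Na in every cell (Hill-number ordering)."""
        rng = np.random.default_rng(31)
        for _ in range(50):
            g = random_matrix(rng)
            for pop in g.populations:
                for locus in g.loci:
                    try:
                        s = locus_stats(g, pop, locus)
                    except NoDataError:
                        continue
                    assert s.ne <= math.exp(s.i) + 1e-9 <= s.na + 2e-9

    def test_uhe_strictly_exceeds_he_when_polymorphic(self):
        rng = np.random.default_rng(37)
        for _ in range(30):
            g = random_matrix(rng)
            for pop in g.populations:
                for locus in g.loci:
                    try:
                        s = locus_stats(g, pop, locus)
                    except NoDataError:
                        continue
                    if s.he > 0:
                        assert s.uhe > s.he

    def test_pctp_invariant_under_relabeling_and_permutation(self):
        rng = np.random.default_rng(41)
        g = random_matrix(rng, missing_rate=0.0)
        # relabel alleles by an order-scrambling injective map
        relabel = {0: 0, 100: 888, 102: 4, 104: 500, 106: 62}
        calls2 = np.vectorize(relabel.get)(g.calls)
        perm = rng.permutation(g.n_individuals)
        from ssrpopgen import GenotypeMatrix

        g2 = GenotypeMatrix(
            [g.individuals[i] for i in perm], g.loci,
            g.pop_of, calls2[perm],
        )
        for pop in g.populations:
            a = population_summary(g, pop).pct_polymorphic
            b = population_summary(g2, pop).pct_polymorphic
            assert a == pytest.approx(b)
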