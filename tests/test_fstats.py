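"""Hierarchical F-statistics, gene flow and table aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ssrpopgen import (
    column_mean_se,
    fstats_locus,
    fstats_table,
    nm_from_fst,
    round_half_away,
)

from conftest import build_matrix, random_matrix
from oracles import fstats_oracle


class TestFstatsLocus:
    def test_complete_differentiation(self):
        g = build_matrix({"A": [[(150, 150)]], "B": [[(154, 154)]]})
        r = fstats_locus(g, "L1")
        assert r.hs == 0.0
        assert r.ht == pytest.approx(0.5)
        assert r.fst == pytest.approx(1.0)
        assert r.nm == pytest.approx(0.0)
        assert r.fis is None  # Hs = 0

    def test_identical_populations(self):
        g = build_matrix({"A": [[(150, 154)]], "B": [[(150, 154)]]})
        r = fstats_locus(g, "L1")
        assert r.ht == pytest.approx(r.hs)
        assert r.fst == pytest.approx(0.0, abs=1e-12)
        assert r.nm is None

    def test_hand_worked_two_population_example(self, two_pop_one_locus):
        """A = {150/154}, B = {150/150}: pbar = (0.75, 0.25), Hs = 0.25,
        Ht = 0.375, Hi = 0.5, Fst = 1/3, Fis = -1, Nm = 0.5."""
        r = fstats_locus(two_pop_one_locus, "L1")
        assert r.hi == pytest.approx(0.5)
        assert r.hs == pytest.approx(0.25)
        assert r.ht == pytest.approx(0.375)
        assert r.fst == pytest.approx(1 / 3)
        assert r.fis == pytest.approx(-1.0)
        assert r.nm == pytest.approx(0.5)

    def test_agrees_with_literal_definition_oracle(self):
        rng = np.random.default_rng(43)
        checked = 0
        while checked < 25:
            g = random_matrix(rng, missing_rate=0.0)
            if len(g.populations) < 2:
                continue
            for locus in g.loci:
                want = fstats_oracle(g, locus)
                got = fstats_locus(g, locus)
                assert got.hi == pytest.approx(want["hi"])
                assert got.hs == pytest.approx(want["hs"])
                assert got.ht == pytest.approx(want["ht"])
                for key in ("fis", "fit", "fst"):
                    if want[key] is None:
                        assert getattr(got, key) is None
                    else:
                        assert getattr(got, key) == pytest.approx(
                            max(want[key], 0.0) if key == "fst" else want[key]
                        )
            checked += 1

    def test_partition_identity(self):
        """(1 - Fit) = (1 - Fis)(1 - Fst) whenever all three are defined."""
        rng = np.random.default_rng(47)
        checked = 0
        while checked < 40:
            g = random_matrix(rng)
            if len(g.populations) < 2:
                continue
            for locus in g.loci:
                try:
                    r = fstats_locus(g, locus)
                except Exception:
                    continue
                if None in (r.fis, r.fit, r.fst):
                    continue
                assert (1 - r.fit) == pytest.approx((1 - r.fis) * (1 - r.fst), abs=1e-9)
                assert 0.0 <= r.fst <= 1.0
                assert r.ht >= r.hs - 1e-12
            checked += 1

    def test_fst_invariant_under_relabeling_and_pop_order(self):
        g1 = build_matrix(
            {"A": [[(150, 154)], [(150, 150)]], "B": [[(154, 154)], [(150, 154)]]}
        )
        g2 = build_matrix(  # alleles renamed, populations listed in other order
            {"B": [[(908, 908)], [(700, 908)]], "A": [[(700, 908)], [(700, 700)]]}
        )
        assert fstats_locus(g1, "L1").fst == pytest.approx(fstats_locus(g2, "L1").fst)


class TestNm:
    @pytest.mark.parametrize(
        "fst, expected, tol",
        [
            (0.222, 0.876, 5e-4),  # published Locus2 row
            (0.2, 1.0, 1e-12),
            (1.0, 0.0, 1e-12),
        ],
    )
    def test_values(self, fst, expected, tol):
        assert nm_from_fst(fst) == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("fst", [0.0, -0.1])
    def test_domain_error(self, fst):
        with pytest.raises(ValueError):
            nm_from_fst(fst)

    @given(st.floats(min_value=1e-6, max_value=1.0 - 1e-9))
    @settings(derandomize=True, max_examples=100)
    def test_strictly_decreasing(self, fst):
        eps = fst * 1e-6
        assert nm_from_fst(fst) > nm_from_fst(min(fst + max(eps, 1e-9), 1.0))


class TestFstatsTable:
    def test_single_locus_se_zero(self, two_pop_one_locus):
        tab = fstats_table(two_pop_one_locus)
        assert len(tab.rows) == 1
        assert tab.se["fst"] == 0.0
        assert tab.mean["fst"] == pytest.approx(1 / 3)

    def test_published_column_aggregation(self):
        """Mean and SE of the 13 published per-locus values: Fst 0.220 +/-
        0.015, Fis -0.274, Nm 0.961."""
        fst = [0.317, 0.222, 0.148, 0.247, 0.125, 0.243, 0.202,
               0.253, 0.235, 0.211, 0.298, 0.171, 0.188]
        fis = [-0.185, -0.387, -0.237, -0.275, -0.365, -0.166, -0.309,
               -0.294, -0.294, -0.129, -0.237, -0.269, -0.413]
        nm = [0.537, 0.876, 1.435, 0.762, 1.745, 0.780, 0.987,
              0.740, 0.816, 0.936, 0.589, 1.212, 1.079]
        mean_fst, se_fst = column_mean_se(fst)
        assert round_half_away(mean_fst) == 0.220
        assert round_half_away(se_fst) == 0.015
        assert round_half_away(column_mean_se(fis)[0]) == -0.274
        assert round_half_away(column_mean_se(nm)[0]) == 0.961

    def test_simulated_table_shape(self):
        from ssrpopgen import SimConfig, simulate

        g = simulate(SimConfig(seed=3))
        tab = fstats_table(g)
        assert len(tab.rows) == 13
        assert all(r.n_pops >= 2 for r in tab.rows)
        assert tab.mean["fst"] is not None and tab.se["fst"] is not None
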