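import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sp_stats

from poletrack import (central_fraction, length_variability_test,
                       pearson_definitional, pole_growth_rates,
                       relative_position, summarize_population)
from poletrack.analysis import asymmetry_stats
from poletrack.foci import Focus

from oracles import definitional_pearson, exact_rank_sum_p, two_pass_sd


class TestRelativePosition:
    @pytest.mark.parametrize("s,L,p,q", [
        (5.0, 10.0, 0.5, 0.5),
        (0.0, 7.0, 0.0, 0.0),
        (3.2, 8.0, 0.4, 0.4),
        (6.0, 8.0, 0.75, 0.25),
    ])
    def test_examples(self, s, L, p, q):
        got_p, got_q = relative_position(s, L)
        assert got_p == pytest.approx(p)
        assert got_q == pytest.approx(q)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            relative_position(1.0, 0.0)
        with pytest.raises(ValueError):
            relative_position(9.0, 8.0)

    @given(st.floats(0, 1, allow_nan=False), st.floats(0.1, 50))
    @settings(max_examples=50, deadline=None)
    def test_folded_position_bounded(self, frac, L):
        p, q = relative_position(frac * L, L)
        assert 0.0 <= p <= 1.0
        assert 0.0 <= q <= 0.5 + 1e-12


class TestCentralFraction:
    def test_all_central(self):
        assert central_fraction([0.5, 0.5, 0.5]) == 1.0

    def test_partial_with_boundary_excluded_value(self):
        # 0.3 is outside: |0.3 - 0.5| = 0.2 > 0.1
        assert central_fraction([0.3, 0.5, 0.55]) == pytest.approx(2 / 3)

    def test_boundary_inclusive(self):
        assert central_fraction([0.4, 0.6]) == 1.0

    def test_uniform_positions_approach_band_width(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(0, 1, 100_000)
        se = math.sqrt(0.2 * 0.8 / len(p))
        assert abs(central_fraction(p) - 0.2) < 3 * se

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            central_fraction([])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1,
                    max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_reflection_invariance(self, ps):
        assert central_fraction(ps) == pytest.approx(
            central_fraction([1 - p for p in ps]))


class TestPoleGrowthRates:
    def test_doubling_closed_form(self):
        rec = pole_growth_rates(0, 0.0, 100.0, 2.0, 2.0, 4.0, 4.0)
        assert rec.r_a == pytest.approx(math.log(2) / 100)
        assert rec.r_b == pytest.approx(math.log(2) / 100)
        assert rec.ratio == pytest.approx(1.0)
        assert rec.faster_on_shorter is False  # tie broken as False

    def test_fast_slow_ordering_and_ratio(self):
        rec = pole_growth_rates(0, 0.0, 160.0, 2.0, 3.0,
                                2.0 * math.exp(1.66e-4 * 160),
                                3.0 * math.exp(7.87e-5 * 160))
        assert rec.r_fast == pytest.approx(1.66e-4, rel=1e-10)
        assert rec.r_slow == pytest.approx(7.87e-5, rel=1e-10)
        assert rec.ratio == pytest.approx(1.66e-4 / 7.87e-5, rel=1e-9)
        assert rec.faster_on_shorter is True

    def test_noise_free_round_trip_to_float_tolerance(self):
        # generator-truth side growing at the reported fast rate for the
        # reported condensation-to-division delay
        r_true = 1.66e-4
        side0 = 2.0
        rec = pole_growth_rates(0, 0.0, 160.0, side0, 2.0,
                                side0 * math.exp(r_true * 160.0),
                                2.0 * math.exp(7.87e-5 * 160.0))
        assert rec.r_a == pytest.approx(r_true, rel=1e-12)

    def test_non_growing_side_flagged(self):
        rec = pole_growth_rates(0, 0.0, 100.0, 2.0, 2.0, 2.5, 1.9)
        assert rec.r_slow <= 0
        assert rec.ratio is None

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pole_growth_rates(0, 100.0, 50.0, 2, 2, 3, 3)
        with pytest.raises(ValueError):
            pole_growth_rates(0, 0.0, 50.0, 0.0, 2, 3, 3)


class TestPearson:
    def test_perfect_anticorrelation(self):
        r, p = pearson_definitional([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_perfect_correlation(self):
        r, _ = pearson_definitional([1, 2, 3], [1, 2, 3])
        assert r == pytest.approx(1.0)

    def test_matches_definitional_oracle_on_random_pairs(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=5)
        y = rng.normal(size=5)
        r, p = pearson_definitional(x, y)
        assert r == pytest.approx(definitional_pearson(x, y), rel=1e-12)
        r_sp, p_sp = sp_stats.pearsonr(x, y)
        assert r == pytest.approx(r_sp, rel=1e-10)
        assert p == pytest.approx(p_sp, rel=1e-8)

    def test_zero_variance_undefined(self):
        r, p = pearson_definitional([1, 1, 1], [1, 2, 3])
        assert math.isnan(r) and math.isnan(p)


class TestAsymmetryStats:
    def test_summary_fields(self):
        recs = [pole_growth_rates(i, 0.0, 160.0, 2.0 + 0.1 * i, 2.5,
                                  (2.0 + 0.1 * i)
                                  * math.exp((1.5e-4 + 1e-5 * i) * 160),
                                  2.5 * math.exp(8e-5 * 160))
                for i in range(5)]
        out = asymmetry_stats(recs)
        assert out["n_records"] == 5
        assert out["fraction_faster_on_shorter"] == 1.0
        expect_ratio = np.mean([(1.5e-4 + 1e-5 * i) / 8e-5 for i in range(5)])
        assert out["mean_ratio"] == pytest.approx(expect_ratio, rel=1e-9)
        assert -1.0 <= out["pearson_r"] <= 1.0

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_stats([])


class TestLengthVariability:
    def test_identical_samples_give_p_one(self):
        w, p = length_variability_test([4, 4, 4, 4], [4, 4, 4, 4])
        assert p == 1.0

    def test_extreme_separation_exact_minimal_p(self):
        # when one sample's deviations all strictly exceed the other's,
        # the rank statistic attains its extremum and the two-sided exact
        # p is 2 / C(10,5) (checked on the deviation scale; with an odd
        # sample the median deviation of each sample is zero, so the
        # public API can only approach this bound)
        from poletrack.analysis import _rank_sum_exact_p
        dev_a = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        dev_b = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        assert _rank_sum_exact_p(dev_a, dev_b) == pytest.approx(
            2 / math.comb(10, 5), rel=1e-9)

    def test_strong_separation_small_p_via_public_api(self):
        # even sample sizes avoid the zero middle deviation, so full
        # separation of the deviation sets is attainable end to end
        a = [0.0, 10.0, 90.0, 110.0, 190.0, 200.0]    # devs 10..100
        b = [50.0, 50.1, 49.9, 50.05, 49.95, 50.02]   # devs <= ~0.1
        _w, p = length_variability_test(a, b)
        assert p == pytest.approx(2 / math.comb(12, 6), rel=1e-9)

    def test_exact_matches_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        a = rng.normal(5, 2.0, 6)
        b = rng.normal(5, 0.5, 6)
        _w, p = length_variability_test(a, b)
        dev_a = np.abs(a - np.median(a))
        dev_b = np.abs(b - np.median(b))
        assert p == pytest.approx(exact_rank_sum_p(dev_a, dev_b), rel=1e-12)

    def test_exact_and_normal_approximation_agree(self):
        rng = np.random.default_rng(10)
        a = rng.normal(5, 2.0, 6)
        b = rng.normal(5, 0.6, 6)
        _w, p_exact = length_variability_test(a, b, exact_max_n=12)
        _w, p_norm = length_variability_test(a, b, exact_max_n=0)
        assert abs(p_exact - p_norm) < 0.02

    def test_matches_scipy_rank_sum_on_deviations(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 3.0, 8)
        b = rng.normal(0, 1.0, 9)
        dev_a = np.abs(a - np.median(a))
        dev_b = np.abs(b - np.median(b))
        _w, p = length_variability_test(a, b, exact_max_n=0)
        ref = sp_stats.mannwhitneyu(dev_a, dev_b, alternative="two-sided",
                                    method="asymptotic", use_continuity=True)
        assert p == pytest.approx(ref.pvalue, rel=1e-4, abs=1e-6)

    def test_detects_higher_mycobacterial_variability(self):
        rng = np.random.default_rng(13)
        smeg = rng.normal(4.8, 1.37, 40)
        cglut = rng.normal(3.46, 0.34, 40)
        _w, p = length_variability_test(smeg, cglut)
        assert p < 0.01

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            length_variability_test([1.0], [2.0, 3.0])


def _focus(cls, p):
    return Focus(frame_index=0, cell_label=0, pixel=(0, 0), intensity=1.0,
                 s_um=p * 5.0, p_norm=p, focus_class=cls)


class TestSummarizePopulation:
    def test_constant_lengths(self):
        stats = summarize_population([4.0, 4.0, 4.0])
        assert stats.mean_length == 4.0
        assert stats.sd_length == 0.0

    def test_sd_matches_two_pass_oracle(self):
        vals = [3.1, 4.2, 5.3, 4.4, 3.9, 4.8, 5.1, 2.9, 4.0, 4.6]
        stats = summarize_population(vals)
        assert stats.sd_length == pytest.approx(two_pass_sd(vals), rel=1e-12)

    def test_three_spot_restriction(self):
        foci = {
            1: [_focus("polar", 0.02), _focus("polar", 0.98),
                _focus("internal", 0.5)],
            2: [_focus("polar", 0.02), _focus("internal", 0.5),
                _focus("internal", 0.7)],
        }
        lengths = {1: 5.0, 2: 6.0}
        stats = summarize_population([5.0, 6.0], foci_by_cell=foci,
                                     lengths_by_cell=lengths)
        assert stats.n_three_spot == 1
        assert stats.lengths == [5.0]
        assert stats.central_frac == 1.0

    def test_no_three_spot_cells_flagged(self):
        foci = {1: [_focus("polar", 0.02)]}
        stats = summarize_population([5.0], foci_by_cell=foci,
                                     lengths_by_cell={1: 5.0})
        assert stats.central_frac is None
        assert "no three-spot" in stats.note

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_population([])
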