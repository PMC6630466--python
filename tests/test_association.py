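"""Latitude regression, paired signed-rank shift test, Fst distribution report."""

import numpy as np
import pytest

from oracles import oracle_hodges_lehmann, oracle_ols, oracle_signed_rank_exact_p

from mirvar import (
    PopulationGeoRecord,
    centroid_latitude,
    fit_latitude_model,
    fst_distribution_report,
    paired_shift_test,
)
from mirvar.errors import (
    DegenerateDesignError,
    InvalidInputError,
    UndefinedTestError,
)


class TestCentroid:
    @pytest.mark.parametrize(
        "points, expected",
        [
            ([(10, 0), (20, 0)], 15.0),
            ([(-30, 10)], 30.0),          # absolute value, single point
            ([(-10, 0), (10, 0)], 0.0),   # symmetric cancellation
        ],
    )
    def test_plate_carree_centroid(self, points, expected):
        assert centroid_latitude(points) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            centroid_latitude([])

    def test_geo_record_validates_latitude(self):
        with pytest.raises(InvalidInputError):
            PopulationGeoRecord("P", ((95.0, 0.0),))
        rec = PopulationGeoRecord("P", ((-30.0, 10.0), (-20.0, 20.0)))
        assert rec.effective_latitude == pytest.approx(25.0)


class TestLatitudeModel:
    def test_perfect_negative_line(self):
        records = [(lat, 0.9 - 0.01 * lat) for lat in (0.0, 10.0, 20.0, 40.0)]
        fit = fit_latitude_model(records)
        assert fit.slope == pytest.approx(-0.01)
        assert fit.r2_adjusted == pytest.approx(1.0)
        assert fit.p_value < 1e-6

    def test_constant_frequency_zero_slope(self):
        fit = fit_latitude_model([(0.0, 0.4), (10.0, 0.4), (30.0, 0.4)])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r2 == pytest.approx(0.0)

    def test_coefficients_match_normal_equations(self):
        lat = [3.0, 11.0, 25.0, 38.0, 52.0]
        freq = [0.81, 0.74, 0.66, 0.35, 0.28]
        fit = fit_latitude_model(list(zip(lat, freq)))
        slope, intercept, r2, r2_adj, p, _ = oracle_ols(lat, freq)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        assert fit.r2_adjusted == pytest.approx(r2_adj, abs=1e-12)
        assert fit.p_value == pytest.approx(p, abs=1e-12)

    def test_order_invariance_and_rescaling_equivariance(self):
        records = [(3.0, 0.8), (18.0, 0.7), (33.0, 0.5), (47.0, 0.4)]
        fit = fit_latitude_model(records)
        shuffled = fit_latitude_model(records[::-1])
        assert fit.slope == pytest.approx(shuffled.slope)
        scaled = fit_latitude_model([(lat * 2, f) for lat, f in records])
        assert scaled.slope == pytest.approx(fit.slope / 2)
        assert scaled.r2_adjusted == pytest.approx(fit.r2_adjusted)
        assert scaled.p_value == pytest.approx(fit.p_value)

    def test_degenerate_design_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_latitude_model([(5.0, 0.1), (5.0, 0.2), (5.0, 0.3)])
        with pytest.raises(InvalidInputError):
            fit_latitude_model([(5.0, 0.1), (6.0, 0.2)])

    def test_slope_recovery_under_noise(self):
        """Gradient recovery: slope within 3 SE of truth for >=95% of seeds."""
        hits = 0
        n_seeds = 60
        for s in range(n_seeds):
            rng = np.random.default_rng(1000 + s)
            lat = rng.uniform(0, 60, 20)
            freq = 0.8 - 0.01 * lat + rng.normal(0, 0.02, lat.size)
            fit = fit_latitude_model(list(zip(lat, freq)))
            x = list(lat)
            se = oracle_ols(x, list(freq))[5]
            hits += abs(fit.slope - (-0.01)) <= 3 * se
        assert hits / n_seeds >= 0.95


class TestPairedShiftTest:
    def test_known_differences_match_enumeration(self):
        a = [0.0] * 5
        b = [0.1, 0.2, 0.3, 0.4, 0.5]
        res = paired_shift_test(a, b)
        assert res.exact
        assert res.shift_median == pytest.approx(0.3)
        assert res.shift_median == pytest.approx(oracle_hodges_lehmann(b))
        assert res.p_value == pytest.approx(oracle_signed_rank_exact_p(b))

    def test_single_pair(self):
        res = paired_shift_test([0.0], [0.2])
        assert res.shift_median == pytest.approx(0.2)
        assert res.p_value == pytest.approx(1.0)
        assert res.ci95[0] <= res.shift_median <= res.ci95[1]

    def test_all_zero_differences_undefined(self):
        with pytest.raises(UndefinedTestError):
            paired_shift_test([0.1, 0.2], [0.1, 0.2])

    def test_zero_differences_dropped_and_counted(self):
        res = paired_shift_test([0.1, 0.2, 0.3], [0.1, 0.25, 0.45])
        assert res.n_pairs == 2
        assert res.n_zero_dropped == 1

    def test_swap_negates_shift_and_ci_keeps_p(self):
        rng = np.random.default_rng(9)
        a = rng.uniform(0, 1, 30)
        b = a + rng.normal(0.02, 0.05, 30)
        fwd = paired_shift_test(a, b)
        rev = paired_shift_test(b, a)
        assert rev.shift_median == pytest.approx(-fwd.shift_median)
        assert rev.ci95 == pytest.approx((-fwd.ci95[1], -fwd.ci95[0]))
        assert rev.p_value == pytest.approx(fwd.p_value)

    def test_shift_equivariance_under_constant_offset(self):
        rng = np.random.default_rng(10)
        a = rng.uniform(0, 1, 15)
        b = a + rng.normal(0, 0.05, 15)
        c = 0.123
        base = paired_shift_test(a, b)
        shifted = paired_shift_test(a, b + c)
        assert shifted.shift_median == pytest.approx(base.shift_median + c)
        assert shifted.ci95[0] == pytest.approx(base.ci95[0] + c)
        assert shifted.ci95[1] == pytest.approx(base.ci95[1] + c)

    def test_hl_of_symmetric_sample_equals_median(self):
        d = np.array([-0.3, -0.1, 0.0, 0.1, 0.3]) + 0.05
        res = paired_shift_test(np.zeros(5), d)
        assert res.shift_median == pytest.approx(float(np.median(d)))

    def test_exact_matches_enumeration_random_suite(self):
        """Exact p and HL equal brute force for random small samples."""
        rng = np.random.default_rng(4242)
        for _ in range(40):
            n = int(rng.integers(1, 11))
            d = rng.uniform(-0.5, 0.5, n)
            d = d[d != 0]
            if d.size == 0:
                continue
            res = paired_shift_test(np.zeros(d.size), d)
            assert res.exact
            assert res.p_value == pytest.approx(oracle_signed_rank_exact_p(d), abs=1e-12)
            assert res.shift_median == pytest.approx(oracle_hodges_lehmann(d), abs=1e-12)

    def test_large_sample_positive_shift_detected(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0.2, 0.8, 400)
        b = np.clip(a + rng.normal(0.01, 0.03, 400), 0, 1)
        res = paired_shift_test(a, b)
        assert not res.exact
        assert res.p_value < 0.01
        assert res.ci95[0] <= res.shift_median <= res.ci95[1]
        assert res.shift_median == pytest.approx(0.01, abs=0.006)

    def test_ci_has_nominal_coverage(self):
        """95% CI covers the true shift in roughly 95% of replicates."""
        rng = np.random.default_rng(12)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            d = rng.normal(0.05, 0.1, 40)
            res = paired_shift_test(np.zeros(40), d)
            covered += res.ci95[0] <= 0.05 <= res.ci95[1]
        assert 0.90 <= covered / n_rep <= 0.99

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InvalidInputError):
            paired_shift_test([0.1], [0.1, 0.2])


class TestFstDistributionReport:
    def test_count_and_fraction_inclusive_threshold(self):
        values = [0.31, 0.5, 0.3, 0.9, 0.45, 0.72, 0.38, 0.30] + [0.05] * 51
        report = fst_distribution_report(values, 0.3)
        assert report.n_total == 59
        assert report.n_at_or_above == 8
        assert report.fraction == pytest.approx(8 / 59)
        assert report.fraction == pytest.approx(0.1356, abs=5e-4)

    def test_threshold_zero_counts_all(self):
        report = fst_distribution_report([0.1, 0.2], 0.0)
        assert report.n_at_or_above == report.n_total == 2
        assert report.fraction == 1.0

    def test_all_below_threshold(self):
        report = fst_distribution_report([0.1, 0.2], 0.5)
        assert (report.n_at_or_above, report.fraction) == (0, 0.0)

    def test_negative_estimates_clamped_into_histogram(self):
        report = fst_distribution_report([-0.02, 0.4], 0.3, bins=10)
        assert sum(report.histogram_counts) == 2
        assert report.histogram_counts[0] == 1

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            fst_distribution_report([], 0.3)
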