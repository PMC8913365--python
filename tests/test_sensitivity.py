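import numpy as np
import pytest

from pwsfire import (
    GridDef,
    bin_annual_series,
    classify_hazard,
    equal_area_bins,
    make_truth,
    ols_slope,
    percent_change_sensitivity,
    sensitivity_curve,
    simulate_annual_vpd,
    simulate_fire,
)
from pwsfire.preprocess import AnnualFireSeries
from pwsfire.sensitivity import HAZARD_HIGH, HAZARD_INVALID, HAZARD_LOW, HAZARD_MEDIUM


class TestEqualAreaBins:
    def test_exact_partition_30_pixels_15_bins(self):
        pws = np.arange(30, dtype=float).reshape(5, 6)
        bins = equal_area_bins(pws, np.ones_like(pws, bool), 1.0, 15)
        assert (bins.counts == 2).all()
        assert bins.bin_area.max() - bins.bin_area.min() <= 1.0
        # bin order monotone in PWS
        assert (np.diff(bins.rep_pws) > 0).all()

    def test_single_bin(self):
        pws = np.random.default_rng(0).random((4, 4))
        bins = equal_area_bins(pws, np.ones_like(pws, bool), 2.0, 1)
        assert bins.counts[0] == 16 and bins.bin_area[0] == 32.0

    def test_ties_split_evenly(self):
        pws = np.full((3, 4), 1.3)
        bins = equal_area_bins(pws, np.ones_like(pws, bool), 1.0, 3)
        assert (bins.counts == 4).all()
        np.testing.assert_allclose(bins.rep_pws, 1.3)

    def test_balance_on_random_fields(self, rng):
        for _ in range(5):
            pws = rng.normal(size=(20, 20))
            veg = rng.random((20, 20)) < 0.8
            k = int(rng.integers(2, 16))
            bins = equal_area_bins(pws, veg, 16.0, k)
            assert bins.bin_area.max() - bins.bin_area.min() <= 16.0 + 1e-9

    def test_k_exceeding_pixels_errors(self):
        pws = np.ones((2, 2))
        with pytest.raises(ValueError, match="exceeds"):
            equal_area_bins(pws, np.ones_like(pws, bool), 1.0, 5)


class TestBinAnnualSeries:
    def grid_series(self):
        years = np.array([2001, 2002, 2003])
        ba = np.zeros((3, 1, 2))
        ba[:, 0, 0], ba[:, 0, 1] = 1.0, 2.0
        vpd = np.zeros((3, 1, 2))
        vpd[:, 0, 0], vpd[:, 0, 1] = 10.0, 20.0
        return AnnualFireSeries(years, ba, vpd, GridDef(1, 2, pixel_area=1.0))

    def test_additivity_and_area_weighted_vpd(self):
        fire = self.grid_series()
        bins = equal_area_bins(np.array([[0.5, 1.5]]), np.ones((1, 2), bool), 1.0, 1)
        _, ba, vpd = bin_annual_series(fire, bins, 1.0)
        assert np.allclose(ba, 3.0) and np.allclose(vpd, 15.0)

    def test_pixel_order_irrelevant(self, rng):
        pws = rng.random((6, 6))
        ba = rng.random((4, 6, 6))
        vpd = rng.random((4, 6, 6)) + 10
        fire = AnnualFireSeries(np.arange(4), ba, vpd, GridDef(6, 6, pixel_area=1.0))
        bins = equal_area_bins(pws, np.ones_like(pws, bool), 1.0, 3)
        _, ba1, vpd1 = bin_annual_series(fire, bins, 1.0)
        perm = rng.permutation(36)
        shape = (6, 6)
        fire2 = AnnualFireSeries(
            np.arange(4),
            ba.reshape(4, -1)[:, perm].reshape(4, *shape),
            vpd.reshape(4, -1)[:, perm].reshape(4, *shape),
            fire.grid,
        )
        bins2 = equal_area_bins(
            pws.ravel()[perm].reshape(shape), np.ones(shape, bool), 1.0, 3
        )
        _, ba2, vpd2 = bin_annual_series(fire2, bins2, 1.0)
        np.testing.assert_allclose(np.sort(ba1), np.sort(ba2))
        np.testing.assert_allclose(ba1, ba2)
        np.testing.assert_allclose(vpd1, vpd2, atol=1e-12)


class TestOlsSlope:
    def test_exact_line(self):
        x = np.arange(20, dtype=float)
        res = ols_slope(3 * x + 7, x)
        assert res.slope == pytest.approx(3.0) and res.stderr == pytest.approx(0.0, abs=1e-12)
        assert res.intercept == pytest.approx(7.0)

    def test_hand_computed_four_points(self):
        res = ols_slope([2, 1, 4, 3], [1, 2, 3, 4])
        assert res.slope == pytest.approx(0.6)

    def test_null_coverage(self):
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(100):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            res = ols_slope(y, x)
            hits += abs(res.slope) <= 2 * res.stderr
        assert hits >= 93

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ols_slope([1, 2], [1, 2])
        with pytest.raises(ValueError):
            ols_slope([1, 2, 3], [5, 5, 5])


class TestSensitivityCurve:
    def test_affine_slopes_give_r2_one(self):
        pws = np.linspace(0, 2, 30).reshape(5, 6)
        bins = equal_area_bins(pws, np.ones_like(pws, bool), 1.0, 10)
        slopes = [ols_slope([0, p * 5 + 1, 2 * (p * 5 + 1)], [0.0, 1.0, 2.0]) for p in bins.rep_pws]
        curve = sensitivity_curve(bins, slopes)
        assert curve.r2 == pytest.approx(1.0)
        assert curve.slope == pytest.approx(5.0)

    def test_slope_law_recovery_low_noise(self):
        grid = GridDef(40, 40, pixel_area=16.0)
        truth = make_truth(grid, seed=5, slope_a=350.0, slope_b=233.0)
        years, vpd = simulate_annual_vpd(grid, range(2001, 2021), seed=6)
        ba = simulate_fire(truth, years, vpd, seed=7, noise_sd=1.0)
        fire = AnnualFireSeries(years, ba, vpd, grid)
        bins = equal_area_bins(truth.pws, np.ones(grid.shape, bool), 16.0, 15)
        _, bab, vpdb = bin_annual_series(fire, bins, 16.0)
        slopes = [ols_slope(bab[:, b], vpdb[:, b]) for b in range(15)]
        curve = sensitivity_curve(bins, slopes)
        assert curve.slope == pytest.approx(233.0, rel=0.10)
        assert curve.intercept == pytest.approx(350.0, rel=0.15)

    def test_bin_count_robustness(self):
        grid = GridDef(40, 40, pixel_area=16.0)
        truth = make_truth(grid, seed=15)
        years, vpd = simulate_annual_vpd(grid, range(2001, 2021), seed=16)
        ba = simulate_fire(truth, years, vpd, seed=17, noise_sd=2.0)
        fire = AnnualFireSeries(years, vpd=vpd, burned=ba, grid=grid)
        curves = []
        for k in (10, 15):
            bins = equal_area_bins(truth.pws, np.ones(grid.shape, bool), 16.0, k)
            _, bab, vpdb = bin_annual_series(fire, bins, 16.0)
            slopes = [ols_slope(bab[:, b], vpdb[:, b]) for b in range(k)]
            curves.append(sensitivity_curve(bins, slopes))
        c10, c15 = curves
        # a bin's summed burned area scales with its vegetated area, so slopes
        # are normalised to a common (1/15 of domain) aggregation area first
        se = np.hypot(c10.stderr * 10 / 15, c15.stderr)
        assert abs(c10.slope * 10 / 15 - c15.slope) <= 2 * max(se, 1e-9)

    def test_too_few_bins_errors(self):
        pws = np.arange(9, dtype=float).reshape(3, 3)
        bins = equal_area_bins(pws, np.ones_like(pws, bool), 1.0, 2)
        with pytest.raises(ValueError):
            sensitivity_curve(bins, [None, None])


class TestHazard:
    @pytest.mark.parametrize(
        "pws,expected",
        [(0.5, HAZARD_LOW), (1.2, HAZARD_MEDIUM), (2.0, HAZARD_HIGH),
         (1.0, HAZARD_MEDIUM), (1.5, HAZARD_MEDIUM)],
    )
    def test_classes(self, pws, expected):
        assert classify_hazard(np.array([[pws]]))[0, 0] == expected

    def test_nodata_passthrough(self):
        out = classify_hazard(np.array([[np.nan, 0.2]]))
        assert out[0, 0] == HAZARD_INVALID and out[0, 1] == HAZARD_LOW


class TestPercentChange:
    def test_constant_burned_area_slope_zero(self):
        years = np.arange(2001, 2011)
        ba = np.full((10, 1), 40.0)
        vpd = np.linspace(10, 15, 10)[:, None]
        res = percent_change_sensitivity(years, ba, vpd)[0]
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_algebraic_construction_gives_10pct_per_hpa(self):
        years = np.arange(2001, 2021)
        rng = np.random.default_rng(3)
        vpd = (20 + rng.normal(0, 1.5, 20))[:, None]
        ba = 500.0 * (1 + 0.1 * (vpd - vpd[0]))
        res = percent_change_sensitivity(years, ba, vpd)[0]
        assert res.slope == pytest.approx(10.0, rel=1e-9)
        # scale invariance of relative change
        res2 = percent_change_sensitivity(years, 2 * ba, vpd)[0]
        assert res2.slope == pytest.approx(res.slope)

    def test_zero_baseline_errors(self):
        years = np.arange(2001, 2006)
        ba = np.zeros((5, 1))
        vpd = np.arange(5.0)[:, None] + 10
        with pytest.raises(ValueError, match="baseline"):
            percent_change_sensitivity(years, ba, vpd)
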