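import numpy as np
import pytest

from pwsfire import (
    confounder_screen,
    double_hazard,
    ndvi_precip_sensitivity,
    vpd_trend_map,
    wui_exposure,
)


class TestVpdTrend:
    def test_exact_on_linear_series(self):
        years = np.arange(1980, 2021)
        vpd = 10.0 + 0.05 * (years - 1980)
        tm = vpd_trend_map(np.tile(vpd[:, None, None], (1, 2, 2)), years)
        np.testing.assert_allclose(tm.trend, 0.05, rtol=1e-12)
        np.testing.assert_allclose(tm.relative_trend, 0.05 / tm.mean, rtol=1e-12)

    def test_constant_series_zero_trend(self):
        years = np.arange(1980, 2000)
        tm = vpd_trend_map(np.full((20, 1, 1), 12.0), years)
        assert tm.trend[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert tm.relative_trend[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_five_year_series(self):
        years = np.arange(2000, 2005)
        vpd = np.array([10.0, 11.0, 10.0, 12.0, 12.0])[:, None, None]
        tm = vpd_trend_map(vpd, years, min_years=5)
        assert tm.trend[0, 0] == pytest.approx(0.5)

    def test_matches_scipy_on_three_point_series(self, rng):
        from scipy.stats import linregress

        years = np.array([2000.0, 2001.0, 2002.0])
        for _ in range(20):
            v = rng.random(3) * 10
            tm = vpd_trend_map(v[:, None, None], years, min_years=3)
            assert tm.trend[0, 0] == pytest.approx(linregress(years, v).slope, abs=1e-10)

    def test_insufficient_years_masked(self):
        years = np.arange(1980, 1992)
        vpd = np.random.default_rng(1).random((12, 1, 2))
        vpd[3:, 0, 0] = np.nan  # only 3 valid years at pixel 0
        tm = vpd_trend_map(vpd, years, min_years=10)
        assert np.isnan(tm.trend[0, 0]) and np.isfinite(tm.trend[0, 1])


class TestDoubleHazard:
    def test_independent_fields_quarter_fraction(self):
        rng = np.random.default_rng(42)
        pws = rng.normal(1.0, 0.5, size=(250, 400))
        trend = rng.normal(0.05, 0.02, size=(250, 400))
        _, frac = double_hazard(pws, trend, "joint_median")
        assert frac == pytest.approx(0.25, abs=0.02)

    def test_comonotone_fields_half_fraction(self):
        rng = np.random.default_rng(7)
        pws = rng.normal(size=(100, 100))
        trend = np.exp(pws)  # perfectly rank-correlated
        _, frac = double_hazard(pws, trend, "joint_median")
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_high_pws_criterion_all_false_below_threshold(self):
        rng = np.random.default_rng(8)
        pws = rng.uniform(0, 1.4, size=(20, 20))
        trend = rng.normal(0.05, 0.01, size=(20, 20))
        mask, frac = double_hazard(pws, trend, "high_pws_above_avg")
        assert not mask.any() and frac == 0.0

    def test_empty_joint_valid_errors(self):
        with pytest.raises(ValueError):
            double_hazard(np.full((2, 2), np.nan), np.ones((2, 2)))


class TestWuiExposure:
    def make_maps(self):
        hazard = np.array([[0, 0, 1], [1, 2, 2]])
        wui = np.ones_like(hazard, dtype=bool)
        pop90 = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        return hazard, wui, pop90

    def test_doubling_population_everywhere(self):
        hazard, wui, pop90 = self.make_maps()
        table = wui_exposure(wui, pop90, 2 * pop90, hazard)
        assert np.allclose(table["pct_change"], 100.0)

    def test_printed_totals_arithmetic(self):
        hazard = np.zeros((1, 2), dtype=int)
        wui = np.ones((1, 2), dtype=bool)
        table = wui_exposure(wui, np.array([[5e6, 5e6]]), np.array([[10.4e6, 10.4e6]]), hazard)
        assert table.loc["total", "pct_change"] == pytest.approx(108.0)

    def test_conservation_and_shares(self):
        hazard, wui, pop90 = self.make_maps()
        pop10 = pop90 * 1.5
        table = wui_exposure(wui, pop90, pop10, hazard)
        assert table.loc["total", "pop_1990"] == pytest.approx(pop90.sum())
        zones = table.drop("total")
        assert zones["pop_1990"].sum() == pytest.approx(table.loc["total", "pop_1990"])
        assert zones["share_1990"].sum() == pytest.approx(1.0, abs=1e-9)
        assert zones["share_2010"].sum() == pytest.approx(1.0, abs=1e-9)
        # moving one person between zones preserves the total
        moved = pop90.copy()
        moved[0, 0] -= 1.0
        moved[1, 2] += 1.0
        t2 = wui_exposure(wui, moved, pop10, hazard)
        assert t2.loc["total", "pop_1990"] == pytest.approx(table.loc["total", "pop_1990"])

    def test_zero_base_zone_flagged_not_infinite(self):
        hazard, wui, pop90 = self.make_maps()
        pop90 = pop90.copy()
        pop90[hazard == 2] = 0.0
        table = wui_exposure(wui, pop90, pop90 + 1.0, hazard)
        assert np.isnan(table.loc["high", "pct_change"])


class TestConfounders:
    def test_self_inverse_and_permuted(self, rng):
        pws = rng.normal(1.0, 0.4, size=(10, 10))
        perm = rng.permutation(pws.ravel()).reshape(pws.shape)
        rep = confounder_screen(
            pws, {"self": pws, "neg": -pws, "perm": perm}
        )
        assert rep.loc["self", "r2"] == pytest.approx(1.0)
        assert rep.loc["neg", "r"] == pytest.approx(-1.0)
        assert abs(rep.loc["perm", "r"]) < 0.25

    def test_constant_covariate_flagged(self, rng):
        pws = rng.normal(size=(8, 8))
        with pytest.warns(UserWarning, match="constant"):
            rep = confounder_screen(pws, {"const": np.ones((8, 8))})
        assert np.isnan(rep.loc["const", "r"])

    def test_too_few_pixels_errors(self, rng):
        pws = rng.normal(size=(4, 4))
        with pytest.raises(ValueError, match="valid pixels"):
            confounder_screen(pws, {"x": pws * 2})


class TestNdviPrecip:
    def test_null_simulation_near_zero_correlation(self):
        rng = np.random.default_rng(5)
        shape = (12, 12)
        ndvi = rng.normal(0.5, 0.05, size=(8, *shape))
        precip = rng.normal(300, 60, size=(8, *shape))
        pws = rng.uniform(0, 2, size=shape)
        lc = np.zeros(shape, dtype=int)
        rep = ndvi_precip_sensitivity(ndvi, precip, lc, pws)
        assert abs(rep["r"].iloc[0]) < 0.25

    def test_constant_slope_flagged(self):
        rng = np.random.default_rng(6)
        shape = (6, 6)
        precip = rng.normal(300, 60, size=(8, *shape))
        ndvi = 0.001 * precip
        pws = rng.uniform(0, 2, size=shape)
        rep = ndvi_precip_sensitivity(ndvi, precip, np.zeros(shape, int), pws)
        assert np.isnan(rep["r"].iloc[0])

    def test_anticorrelated_construction_negative(self):
        rng = np.random.default_rng(9)
        shape = (10, 10)
        pws = rng.uniform(0, 2, size=shape)
        precip = rng.normal(300, 60, size=(10, *shape))
        slope_true = 0.002 * (2.0 - pws)  # high PWS -> low precip sensitivity
        ndvi = 0.3 + slope_true[None] * (precip - 300) + rng.normal(0, 0.002, (10, *shape))
        rep = ndvi_precip_sensitivity(ndvi, precip, np.zeros(shape, int), pws)
        assert rep["r"].iloc[0] < -0.5

    def test_precip_groups_split_reported(self):
        rng = np.random.default_rng(10)
        shape = (8, 8)
        pws = rng.uniform(0, 2, size=shape)
        precip = rng.normal(300, 60, size=(8, *shape))
        ndvi = rng.normal(0.4, 0.05, size=(8, *shape))
        rep = ndvi_precip_sensitivity(ndvi, precip, np.zeros(shape, int), pws, precip_groups=2)
        assert set(rep["precip_group"]) == {0, 1}
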