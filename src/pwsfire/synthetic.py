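"""Synthetic gridded fixtures with recorded ground truth.

Every analysis stage can be exercised against data whose generating
parameters are known: dead-fuel moisture (DFMC) and VPD as pixel-specific
seasonal cycles plus AR(1) anomalies, live-fuel moisture (LFMC) as a known
non-negative lag-kernel convolution of the DFMC anomalies plus Gaussian
noise, burned area following an affine slope law d(BA)/d(VPD) = a + b*PWS,
trait rasters as noisy linear functions of block-averaged PWS at coarser
resolution, and WUI populations with hazard-zone-dependent growth. All
generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grid import GridDef, RasterStack, regrid
from .preprocess import EpochCalendar, EpochSeries
from .pws import LagConfig, estimate_pws_map
from .drivers import TRAIT_NAMES

__all__ = [
    "SyntheticTruth",
    "ClimateFields",
    "smooth_field",
    "make_truth",
    "simulate_climate",
    "simulate_lfmc",
    "calibrate_noise_sd",
    "simulate_annual_vpd",
    "simulate_fire",
    "simulate_traits",
    "simulate_wui",
    "standard_fixture",
    "STANDARD_FIXTURE",
]

#: versioned parameters of the standard test fixture
STANDARD_FIXTURE = {
    "grid": {"n_rows": 64, "n_cols": 64, "pixel_area": 16.0},
    "years": (2015, 2016, 2017, 2018, 2019, 2020),
    "lag_tau_steps": 3.0,
    "kernel_keep_prob": 0.6,
    "pws_range": (0.0, 2.0),
    "ar1": 0.7,
    "dfmc_anom_sd": 3.0,
    "target_fit_r2": 0.3,
    "slope_a": 350.0,
    "slope_b": 233.0,
}


@dataclass
class SyntheticTruth:
    """Generating parameters recorded for recovery tests."""

    beta: np.ndarray  # (n_lags, rows, cols), all >= 0
    pws: np.ndarray  # (rows, cols) = beta.sum(axis=0)
    grid: GridDef
    slope_a: float = 350.0
    slope_b: float = 233.0
    area_norm: float | None = None
    trait_effects: dict[str, float] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    seed: int | None = None


@dataclass
class ClimateFields:
    """Simulated meteorology plus its true (pre-climatology) anomalies."""

    dfmc: EpochSeries
    vpd: EpochSeries
    precip: EpochSeries
    dfmc_anom: np.ndarray
    vpd_anom: np.ndarray


def smooth_field(grid: GridDef, rng: np.random.Generator,
                 low: float, high: float, sigma: float = 8.0) -> np.ndarray:
    """Spatially smooth random field rank-mapped onto [low, high]."""
    raw = gaussian_filter(rng.standard_normal(grid.shape), sigma=sigma, mode="wrap")
    ranks = raw.ravel().argsort().argsort().astype(float)
    u = ranks / max(ranks.size - 1, 1)
    return (low + u * (high - low)).reshape(grid.shape)


def make_truth(
    grid: GridDef,
    seed: int,
    n_lags: int = 11,
    pws_range: tuple[float, float] = (0.0, 2.0),
    lag_tau_steps: float = 3.0,
    kernel_keep_prob: float = 0.6,
    slope_a: float = 350.0,
    slope_b: float = 233.0,
) -> SyntheticTruth:
    """Draw per-pixel sparse-exponential lag kernels summing to a smooth PWS field.

    Kernel weights are ``exp(-i / tau)`` on a random subset of lags (lag 0
    always kept), jittered and rescaled so their sum equals the target PWS.
    """
    rng = np.random.default_rng(seed)
    pws = smooth_field(grid, rng, *pws_range)
    lags = np.arange(n_lags, dtype=float)
    keep = rng.random((n_lags, *grid.shape)) < kernel_keep_prob
    keep[0] = True
    jitter = rng.uniform(0.5, 1.5, size=(n_lags, *grid.shape))
    shape = np.exp(-lags / lag_tau_steps)[:, None, None] * keep * jitter
    total = shape.sum(axis=0)
    beta = shape * (pws / np.maximum(total, 1e-12))[None]
    return SyntheticTruth(beta=beta, pws=beta.sum(axis=0), grid=grid,
                          slope_a=slope_a, slope_b=slope_b, seed=seed)


def _ar1(rng, n_steps: int, shape: tuple[int, ...], phi: float, sd: float) -> np.ndarray:
    """AR(1) process with stationary marginal standard deviation ``sd``."""
    innov_sd = sd * np.sqrt(max(1.0 - phi * phi, 1e-12))
    out = np.empty((n_steps, *shape))
    out[0] = rng.normal(0.0, sd, size=shape)
    for t in range(1, n_steps):
        out[t] = phi * out[t - 1] + rng.normal(0.0, innov_sd, size=shape)
    return out


def simulate_climate(
    grid: GridDef,
    years,
    seed: int,
    ar1: float = 0.7,
    dfmc_anom_sd: float = 3.0,
    vpd_anom_sd: float = 1.5,
    precip_anom_sd: float = 10.0,
    vpd_shared_weight: float = 0.5,
    vpd_trend: float | np.ndarray = 0.0,
) -> ClimateFields:
    """Simulate DFMC (%), VPD (hPa) and precipitation epoch series.

    Each series is a pixel-specific seasonal cycle plus AR(1) anomalies.
    VPD anomalies share a (negatively signed) component with DFMC anomalies
    weighted by ``vpd_shared_weight``; ``vpd_trend`` (hPa/yr, scalar or
    per-pixel map) adds a secular drift.
    """
    years = sorted(int(y) for y in years)
    if len(years) < 6:
        raise ValueError("at least 6 years required (lag spin-up plus analysis window)")
    for name, v in [("dfmc_anom_sd", dfmc_anom_sd), ("vpd_anom_sd", vpd_anom_sd),
                    ("precip_anom_sd", precip_anom_sd)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    rng = np.random.default_rng(seed)
    cal = EpochCalendar.from_years(years)
    n = len(cal)
    eoy = cal.eoy
    phase = 2.0 * np.pi * (eoy - 1) / 24.0

    def seasonal(mean_lo, mean_hi, amp_lo, amp_hi):
        mean = smooth_field(grid, rng, mean_lo, mean_hi)
        amp = smooth_field(grid, rng, amp_lo, amp_hi)
        ph0 = rng.uniform(0, 2 * np.pi, size=grid.shape)
        return mean[None] + amp[None] * np.cos(phase[:, None, None] - ph0[None])

    dfmc_cycle = seasonal(10.0, 20.0, 2.0, 5.0)
    vpd_cycle = seasonal(8.0, 25.0, 3.0, 8.0)
    precip_cycle = np.maximum(seasonal(20.0, 60.0, 10.0, 30.0), 0.0)

    dfmc_anom = _ar1(rng, n, grid.shape, ar1, dfmc_anom_sd)
    w = float(np.clip(vpd_shared_weight, 0.0, 1.0))
    own = _ar1(rng, n, grid.shape, ar1, vpd_anom_sd)
    vpd_anom = -w * (vpd_anom_sd / dfmc_anom_sd) * dfmc_anom + np.sqrt(1 - w * w) * own
    years_since = (cal.years - years[0]).astype(float)
    trend = np.asarray(vpd_trend, dtype=float)
    vpd_anom = vpd_anom + years_since[:, None, None] * trend
    precip_anom = _ar1(rng, n, grid.shape, ar1, precip_anom_sd)

    dfmc = EpochSeries(dfmc_cycle + dfmc_anom, cal, grid, "%")
    vpd = EpochSeries(vpd_cycle + vpd_anom, cal, grid, "hPa")
    precip = EpochSeries(np.maximum(precip_cycle + precip_anom, 0.0), cal, grid, "mm")
    return ClimateFields(dfmc, vpd, precip, dfmc_anom, vpd_anom)


def simulate_lfmc(
    climate: ClimateFields,
    truth: SyntheticTruth,
    noise_sd: float = 0.0,
    seed: int = 0,
    missing_fraction: float = 0.0,
) -> EpochSeries:
    """LFMC = seasonal cycle + lag-kernel convolution of DFMC anomalies + noise.

    Epochs whose full lag window precedes the record start are nodata, as
    are randomly masked epochs when ``missing_fraction > 0``.
    """
    n_lags = truth.beta.shape[0]
    if n_lags != 11:
        raise ValueError("lag kernel must have 11 entries (lags 0-150 d by 15 d)")
    rng = np.random.default_rng(seed)
    grid = truth.grid
    cal = climate.dfmc.calendar
    n = len(cal)
    anom = climate.dfmc_anom
    signal = np.full((n, *grid.shape), np.nan)
    for t in range(n_lags - 1, n):
        window = anom[t - n_lags + 1 : t + 1][::-1]  # index i = lag i
        signal[t] = np.einsum("irc,irc->rc", truth.beta, window)

    eoy = cal.eoy
    phase = 2.0 * np.pi * (eoy - 1) / 24.0
    mean = smooth_field(grid, rng, 80.0, 140.0)
    amp = smooth_field(grid, rng, 10.0, 30.0)
    ph0 = rng.uniform(0, 2 * np.pi, size=grid.shape)
    cycle = mean[None] + amp[None] * np.cos(phase[:, None, None] - ph0[None])

    data = cycle + signal
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    if missing_fraction > 0:
        mask = rng.random(data.shape) < missing_fraction
        data = np.where(mask, np.nan, data)
    return EpochSeries(data, cal, grid, "%")


def calibrate_noise_sd(
    climate: ClimateFields,
    truth: SyntheticTruth,
    cfg: LagConfig = LagConfig(),
    target_r2: float = 0.3,
    seed: int = 0,
    n_sample_pixels: int = 512,
    tol: float = 0.01,
    max_iter: int = 10,
) -> float:
    """Noise level at which the median per-pixel fit r^2 hits a target.

    Starts from the analytic value ``sd_signal * sqrt((1 - r2) / r2)``
    (exact for unconstrained fits at infinite sample size) and bisects a
    multiplier against the median r^2 measured on a pixel subsample, which
    accounts for the finite 60-row designs and the non-negativity
    constraint.
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    sel = rng.choice(grid.n_pixels, size=min(n_sample_pixels, grid.n_pixels), replace=False)
    rows, cols = np.unravel_index(sel, grid.shape)

    n_lags = truth.beta.shape[0]
    cal = climate.dfmc.calendar
    season = cal.select(years=cfg.years, months=cfg.season_months)
    sig = np.zeros((season.sum(), len(sel)))
    t_idx = np.flatnonzero(season)
    for j, t in enumerate(t_idx):
        window = climate.dfmc_anom[t - n_lags + 1 : t + 1, rows, cols][::-1]
        sig[j] = np.einsum("ik,ik->k", truth.beta[:, rows, cols], window)
    sd_signal = float(np.median(sig.std(axis=0)))
    base = sd_signal * np.sqrt((1.0 - target_r2) / target_r2)

    def median_r2(noise_sd: float) -> float:
        lfmc = simulate_lfmc(climate, truth, noise_sd=noise_sd, seed=seed + 1)
        sub_lfmc = EpochSeries(lfmc.data[:, rows, cols][:, :, None], cal,
                               GridDef(len(sel), 1, grid.pixel_area), lfmc.units)
        sub_pred = EpochSeries(climate.dfmc.data[:, rows, cols][:, :, None], cal,
                               GridDef(len(sel), 1, grid.pixel_area), climate.dfmc.units)
        pm = estimate_pws_map(sub_lfmc, sub_pred, cfg)
        return float(np.nanmedian(pm.r2))

    lo_mult, hi_mult = 0.25, 4.0
    mult = 1.0
    for _ in range(max_iter):
        r2 = median_r2(base * mult)
        if abs(r2 - target_r2) <= tol:
            break
        if r2 > target_r2:  # too clean -> more noise
            lo_mult = mult
        else:
            hi_mult = mult
        mult = float(np.sqrt(lo_mult * hi_mult))
    return base * mult


def simulate_annual_vpd(
    grid: GridDef,
    years,
    seed: int,
    mean_range: tuple[float, float] = (15.0, 25.0),
    interannual_sd: float = 1.5,
    pixel_sd: float = 0.2,
    trend: float | np.ndarray = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel annual-mean VPD: pixel mean + shared interannual signal + noise."""
    years = np.asarray(sorted(int(y) for y in years))
    rng = np.random.default_rng(seed)
    mean = smooth_field(grid, rng, *mean_range)
    common = rng.normal(0.0, interannual_sd, size=years.size)
    noise = rng.normal(0.0, pixel_sd, size=(years.size, *grid.shape))
    drift = (years - years[0])[:, None, None] * np.asarray(trend, dtype=float)
    return years, mean[None] + common[:, None, None] + noise + drift


def simulate_fire(
    truth: SyntheticTruth,
    years: np.ndarray,
    vpd_annual: np.ndarray,
    seed: int,
    noise_sd: float = 0.0,
    area_norm: float | None = None,
    n_bins: int = 15,
) -> np.ndarray:
    """Per-pixel annual burned area following the affine slope law.

    BA_{s,y} = base_s + (a + b * PWS*_s) * (VPD_{s,y} - ref_s) / area_norm
    + noise, clipped at zero. ``area_norm`` defaults to the expected bin
    membership (n_pixels / n_bins) so that summing over an equal-area bin
    yields a bin slope of about a + b * mean(PWS).
    """
    rng = np.random.default_rng(seed)
    pws = truth.pws
    a, b = truth.slope_a, truth.slope_b
    if area_norm is None:
        area_norm = truth.grid.n_pixels / n_bins
    truth.area_norm = float(area_norm)
    slope_pix = (a + b * pws) / area_norm
    if np.any(a + b * pws < 0):
        raise ValueError("slope law goes negative over the PWS range")
    ref = vpd_annual.mean(axis=0)
    dev = vpd_annual - ref[None]
    base = slope_pix * (np.abs(dev).max() + 1.0) + 4.0 * noise_sd
    ba = base[None] + slope_pix[None] * dev
    if noise_sd > 0:
        ba = ba + rng.normal(0.0, noise_sd, size=ba.shape)
    neg = ba < 0
    if neg.mean() > 0.01:
        import warnings

        warnings.warn(f"{neg.mean():.1%} of burned-area values clipped at 0", stacklevel=2)
    return np.clip(ba, 0.0, None)


def simulate_traits(
    truth: SyntheticTruth,
    coarse_factor: int = 4,
    seed: int = 0,
    effects: dict[str, float] | None = None,
    noise_sd: float = 0.3,
) -> dict[str, np.ndarray]:
    """14 trait rasters as linear + noise functions of block-averaged PWS.

    Traits are generated at ``coarse_factor``-times coarser resolution
    (emulating 25-km trait products vs the 4-km analysis grid), then
    nearest-neighbour upsampled. ``effects`` maps trait name to the linear
    coefficient on standardised coarse PWS; unlisted traits get 0.
    Sand/silt/clay are renormalised to fractions; the hydraulic functional
    type is integer-coded from quartiles of its latent value.
    """
    if coarse_factor < 1:
        raise ValueError("coarse_factor must be >= 1")
    if effects is None:
        effects = {"ks": 1.0, "n": 0.7, "max_rooting_depth": 0.5}
    rng = np.random.default_rng(seed)
    grid = truth.grid
    coarse = grid.coarsen(coarse_factor) if coarse_factor > 1 else grid
    pws_stack = RasterStack(grid, truth.pws[None], ["pws"], "1")
    pws_coarse = regrid(pws_stack, coarse, "block_mean").data[0]
    z = (pws_coarse - np.nanmean(pws_coarse)) / max(np.nanstd(pws_coarse), 1e-12)

    latent = {}
    for name in TRAIT_NAMES:
        eff = float(effects.get(name, 0.0))
        latent[name] = eff * z + rng.normal(0.0, noise_sd, size=coarse.shape)

    # physical post-processing at coarse resolution
    frac = np.stack([latent[f] for f in ("sand_fraction", "silt_fraction", "clay_fraction")])
    frac = np.exp(frac)
    frac = frac / frac.sum(axis=0)
    for i, f in enumerate(("sand_fraction", "silt_fraction", "clay_fraction")):
        latent[f] = frac[i]
    hft = latent["hydraulic_functional_type"]
    edges = np.quantile(hft, [0.25, 0.5, 0.75])
    latent["hydraulic_functional_type"] = np.digitize(hft, edges).astype(float)

    truth.trait_effects = dict(effects)
    truth.noise_sd["traits"] = noise_sd
    out = {}
    for name, arr in latent.items():
        stack = RasterStack(coarse, arr[None], [name], "1")
        out[name] = regrid(stack, grid, "nearest").data[0]
    return out


def simulate_wui(
    hazard: np.ndarray,
    seed: int,
    wui_fraction: float = 0.3,
    growth_by_zone: dict[int, float] = None,
    jitter_sd: float = 0.0,
    total_pop_1990: float = 10e6,
    zone_share_1990: dict[int, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """WUI mask plus 1990/2010 population rasters with zone-dependent growth.

    1990 populations are lognormal on WUI pixels, rescaled so each hazard
    zone's total matches ``zone_share_1990 * total_pop_1990`` (uniform
    shares when not given); 2010 populations multiply by the zone growth
    factor and an optional lognormal jitter.
    """
    if growth_by_zone is None:
        growth_by_zone = {0: 2.07, 1: 1.95, 2: 2.60}
    if any(g < 0 for g in growth_by_zone.values()):
        raise ValueError("growth factors must be >= 0")
    rng = np.random.default_rng(seed)
    eligible = hazard >= 0
    wui = np.zeros(hazard.shape, dtype=bool)
    flat = np.flatnonzero(eligible.ravel())
    n_wui = max(1, int(round(wui_fraction * flat.size)))
    wui.ravel()[rng.choice(flat, size=n_wui, replace=False)] = True

    pop90 = np.zeros(hazard.shape)
    pop90[wui] = rng.lognormal(mean=8.0, sigma=1.0, size=n_wui)
    zones = sorted(growth_by_zone)
    if zone_share_1990 is None:
        present = [z for z in zones if np.any(wui & (hazard == z))]
        zone_share_1990 = {z: 1.0 / len(present) for z in present}
    for z, share in zone_share_1990.items():
        sel = wui & (hazard == z)
        s = pop90[sel].sum()
        if s > 0:
            pop90[sel] *= share * total_pop_1990 / s
    pop10 = np.zeros(hazard.shape)
    for z, g in growth_by_zone.items():
        sel = wui & (hazard == z)
        jit = rng.lognormal(0.0, jitter_sd, size=sel.sum()) if jitter_sd > 0 else 1.0
        pop10[sel] = pop90[sel] * g * jit
    return wui, pop90, pop10


@dataclass
class StandardFixture:
    """Standard 64x64, 6-year closed-loop fixture with calibrated noise."""

    grid: GridDef
    truth: SyntheticTruth
    climate: ClimateFields
    lfmc: EpochSeries
    noise_sd: float
    cfg: LagConfig
    seed: int


def standard_fixture(seed: int = 42, calibrate: bool = True) -> StandardFixture:
    """Build the versioned standard fixture (see ``STANDARD_FIXTURE``)."""
    p = STANDARD_FIXTURE
    grid = GridDef(**p["grid"])
    truth = make_truth(
        grid, seed,
        pws_range=p["pws_range"],
        lag_tau_steps=p["lag_tau_steps"],
        kernel_keep_prob=p["kernel_keep_prob"],
        slope_a=p["slope_a"], slope_b=p["slope_b"],
    )
    climate = simulate_climate(grid, p["years"], seed + 1, ar1=p["ar1"],
                               dfmc_anom_sd=p["dfmc_anom_sd"])
    cfg = LagConfig()
    if calibrate:
        noise_sd = calibrate_noise_sd(climate, truth, cfg,
                                      target_r2=p["target_fit_r2"], seed=seed + 2)
    else:
        noise_sd = 0.0
    lfmc = simulate_lfmc(climate, truth, noise_sd=noise_sd, seed=seed + 3)
    return StandardFixture(grid, truth, climate, lfmc, noise_sd, cfg, seed)
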