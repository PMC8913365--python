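"""Plant-water sensitivity (PWS) estimation.

PWS at a pixel is the sum of the non-negative slopes of a distributed-lag
regression of live-fuel-moisture-content (LFMC) anomalies on dead-fuel-
moisture-content (DFMC) anomalies at lags 0-150 d in 15-d steps (11 lag
terms). Fitting uses June-November epochs of 2016-2020; pixels whose LFMC
record is more than half missing over that window, or with fewer complete
design rows than ``p_min``, are masked. Passing vapour-pressure-deficit
anomalies as the predictor instead of DFMC yields the "modified PWS"
confounder check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import GridDef
from .preprocess import EpochSeries, anomaly, seasonal_climatology
from .regression import NonNegativeLagRegressor

__all__ = [
    "LagConfig",
    "LagFit",
    "PWSMap",
    "build_lag_design",
    "fit_nonneg_lag_regression",
    "pws_from_fit",
    "estimate_pws_map",
]


@dataclass(frozen=True)
class LagConfig:
    """Configuration of the distributed-lag fit.

    Defaults follow the study design: lags 0-150 d in 15-d steps (11
    terms), June-November observation season, years 2016-2020, pixels with
    <= 50% of the LFMC record valid masked, and at least ``p_min = 30``
    design rows per pixel (about 2.7 observations per parameter; a complete
    record has 60 rows, so this tolerates 50% loss).
    """

    max_lag_days: int = 150
    step_days: int = 15
    season_months: tuple[int, ...] = (6, 7, 8, 9, 10, 11)
    years: tuple[int, ...] = (2016, 2017, 2018, 2019, 2020)
    min_valid_fraction: float = 0.5
    p_min: int = 30
    climatology_min_years: int = 2

    def __post_init__(self) -> None:
        if self.max_lag_days % self.step_days:
            raise ValueError("max_lag_days must be divisible by step_days")

    @property
    def n_lags(self) -> int:
        return self.max_lag_days // self.step_days + 1


@dataclass
class LagFit:
    """Per-pixel fit result of the non-negative lag regression."""

    beta: np.ndarray  # (n_lags,), all >= 0
    gamma: float
    r2: float
    n_obs: int
    zero_fraction: float
    rank_deficient: bool = False


@dataclass
class PWSMap:
    """Per-pixel PWS (sum of lag slopes), fit r2, and optional coefficients."""

    pws: np.ndarray
    r2: np.ndarray
    grid: GridDef
    n_obs: np.ndarray | None = None
    beta: np.ndarray | None = None  # (n_lags, rows, cols)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.pws)


def _target_epoch_indices(series: EpochSeries, cfg: LagConfig) -> np.ndarray:
    cal = series.calendar
    return np.flatnonzero(cal.select(years=cfg.years, months=cfg.season_months))


def build_lag_design(
    lfmc_anom: EpochSeries,
    dfmc_anom: EpochSeries,
    cfg: LagConfig,
    pixel: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Response vector and lagged design matrix for one pixel.

    One row per in-season epoch with a valid LFMC anomaly and valid DFMC
    anomalies at all lags (listwise deletion); column ``i`` holds the DFMC
    anomaly ``i`` half-monthly steps before the response epoch.
    """
    if len(lfmc_anom.calendar) != len(dfmc_anom.calendar):
        raise ValueError("LFMC and DFMC anomalies must share a calendar")
    r, c = pixel
    y_full = lfmc_anom.data[:, r, c]
    x_full = dfmc_anom.data[:, r, c]
    targets = _target_epoch_indices(lfmc_anom, cfg)
    n_lags = cfg.n_lags
    rows_y, rows_x = [], []
    for t in targets:
        if t - (n_lags - 1) < 0:
            continue
        lagged = x_full[t - n_lags + 1 : t + 1][::-1]  # column i = lag i
        if np.isfinite(y_full[t]) and np.all(np.isfinite(lagged)):
            rows_y.append(y_full[t])
            rows_x.append(lagged)
    if not rows_y:
        return np.empty(0), np.empty((0, n_lags))
    return np.asarray(rows_y), np.asarray(rows_x)


def fit_nonneg_lag_regression(y: np.ndarray, X: np.ndarray) -> LagFit:
    """Fit the constrained lag regression (beta >= 0, free intercept)."""
    est = NonNegativeLagRegressor().fit(X, y)
    return LagFit(
        beta=est.coef_,
        gamma=est.intercept_,
        r2=est.r2_,
        n_obs=est.n_obs_,
        zero_fraction=est.zero_fraction_,
        rank_deficient=est.rank_deficient_,
    )


def pws_from_fit(fit: LagFit) -> float:
    """PWS = unweighted sum of the lag slopes; the intercept is excluded."""
    return float(np.sum(fit.beta))


def estimate_pws_map(
    lfmc: EpochSeries,
    predictor: EpochSeries,
    cfg: LagConfig = LagConfig(),
    return_coefficients: bool = False,
) -> PWSMap:
    """Estimate PWS at every pixel of an LFMC stack.

    Anomalies for both series are computed against their epoch-of-year
    climatologies over ``cfg.years``. ``predictor`` is the DFMC stack for
    standard PWS, or a VPD stack for the modified variant.
    """
    lfmc_clim = seasonal_climatology(lfmc, cfg.years, cfg.climatology_min_years)
    pred_clim = seasonal_climatology(predictor, cfg.years, cfg.climatology_min_years)
    lfmc_anom = anomaly(lfmc, lfmc_clim)
    pred_anom = anomaly(predictor, pred_clim)

    targets = _target_epoch_indices(lfmc, cfg)
    n_record = len(targets)
    valid_frac = np.isfinite(lfmc.data[targets]).mean(axis=0)

    grid = lfmc.grid
    pws = np.full(grid.shape, np.nan)
    r2 = np.full(grid.shape, np.nan)
    n_obs = np.zeros(grid.shape, dtype=int)
    beta = np.full((cfg.n_lags, *grid.shape), np.nan) if return_coefficients else None

    candidates = np.argwhere(valid_frac > cfg.min_valid_fraction)
    if n_record == 0 or candidates.size == 0:
        warnings.warn("no valid pixels for PWS estimation", stacklevel=2)
        return PWSMap(pws, r2, grid, n_obs, beta)

    for r, c in candidates:
        y, X = build_lag_design(lfmc_anom, pred_anom, cfg, (r, c))
        if y.size < cfg.p_min:
            continue
        fit = fit_nonneg_lag_regression(y, X)
        pws[r, c] = pws_from_fit(fit)
        r2[r, c] = fit.r2
        n_obs[r, c] = fit.n_obs
        if beta is not None:
            beta[:, r, c] = fit.beta
    return PWSMap(pws, r2, grid, n_obs, beta)
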