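"""VPD trends, double-hazard classification, WUI exposure and confounder
screens.

Per-pixel trends are ordinary-least-squares slopes of annual-mean VPD on
year (1980-2020 in the study design); relative trends divide by the
pixel's long-term mean. "Double hazard" marks pixels where both PWS and
the VPD trend are high — either jointly above their medians, or PWS >= 1.5
with an above-average trend. Wildland-urban-interface (WUI) exposure sums
census populations per hazard zone for two epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sensitivity import HAZARD_HIGH, HAZARD_LOW, HAZARD_MEDIUM

__all__ = [
    "TrendMap",
    "vpd_trend_map",
    "double_hazard",
    "wui_exposure",
    "confounder_screen",
    "ndvi_precip_sensitivity",
]

_ZONE_NAMES = {HAZARD_LOW: "low", HAZARD_MEDIUM: "medium", HAZARD_HIGH: "high"}


@dataclass
class TrendMap:
    """Per-pixel VPD trend (hPa/yr), relative trend (1/yr) and mean (hPa)."""

    trend: np.ndarray
    relative_trend: np.ndarray
    mean: np.ndarray
    n_years: np.ndarray


def _pixelwise_ols(values: np.ndarray, t: np.ndarray, min_n: int) -> tuple[np.ndarray, ...]:
    """Vectorised per-pixel OLS slope of ``values`` (n_t, ...) on ``t``."""
    finite = np.isfinite(values)
    n = finite.sum(axis=0)
    w = finite.astype(float)
    v = np.nan_to_num(values)
    tcol = t.reshape((-1,) + (1,) * (values.ndim - 1))
    sw = w.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mt = (w * tcol).sum(axis=0) / sw
        mv = v.sum(axis=0) / sw
        stt = (w * (tcol - mt) ** 2).sum(axis=0)
        stv = (w * (tcol - mt) * (v - mv * w)).sum(axis=0)
        slope = stv / stt
    bad = (n < min_n) | (stt <= 0)
    slope = np.where(bad, np.nan, slope)
    mean = np.where(n > 0, mv, np.nan)
    return slope, mean, n


def vpd_trend_map(vpd_annual: np.ndarray, years, min_years: int = 10) -> TrendMap:
    """Per-pixel OLS trend of annual-mean VPD against year.

    ``vpd_annual`` has shape (n_years, rows, cols); pixels with fewer than
    ``min_years`` valid annual values get nodata.
    """
    years = np.asarray(list(years), dtype=float)
    vpd_annual = np.asarray(vpd_annual, dtype=float)
    if vpd_annual.shape[0] != years.size:
        raise ValueError("years and annual stack length mismatch")
    slope, mean, n = _pixelwise_ols(vpd_annual, years, min_years)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(mean > 0, slope / mean, np.nan)
    return TrendMap(slope, rel, mean, n)


def double_hazard(
    pws,
    trend: TrendMap | np.ndarray,
    criterion: str = "joint_median",
    pws_threshold: float = 1.5,
    trend_center: str = "mean",
) -> tuple[np.ndarray, float]:
    """Mask of jointly hazardous pixels and its areal fraction.

    ``joint_median``: PWS and trend both above their medians (computed
    over jointly valid pixels). ``high_pws_above_avg``: PWS >= 1.5 and
    trend above its spatial mean (or median via ``trend_center``).
    """
    pws_arr = getattr(pws, "pws", pws)
    trend_arr = trend.trend if isinstance(trend, TrendMap) else np.asarray(trend, dtype=float)
    valid = np.isfinite(pws_arr) & np.isfinite(trend_arr)
    if not valid.any():
        raise ValueError("no jointly valid pixels")
    p, t = pws_arr[valid], trend_arr[valid]
    mask = np.zeros(pws_arr.shape, dtype=bool)
    if criterion == "joint_median":
        mask[valid] = (p > np.median(p)) & (t > np.median(t))
    elif criterion == "high_pws_above_avg":
        center = np.mean(t) if trend_center == "mean" else np.median(t)
        mask[valid] = (p >= pws_threshold) & (t > center)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return mask, float(mask.sum() / valid.sum())


def wui_exposure(
    wui_mask: np.ndarray,
    pop_1990: np.ndarray,
    pop_2010: np.ndarray,
    hazard: np.ndarray,
) -> pd.DataFrame:
    """Population by hazard zone inside the WUI for both census epochs.

    Returns a table with rows low/medium/high/total: populations, percent
    change (NaN-flagged where the 1990 base is zero), and each zone's
    share of the total WUI population per epoch.
    """
    wui = np.asarray(wui_mask, dtype=bool)
    rows = []
    for code, name in _ZONE_NAMES.items():
        sel = wui & (hazard == code)
        rows.append((name, float(np.nansum(pop_1990[sel])), float(np.nansum(pop_2010[sel]))))
    total90 = sum(r[1] for r in rows)
    total10 = sum(r[2] for r in rows)
    rows.append(("total", total90, total10))
    df = pd.DataFrame(rows, columns=["zone", "pop_1990", "pop_2010"]).set_index("zone")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["pct_change"] = np.where(
            df["pop_1990"] > 0,
            100.0 * (df["pop_2010"] - df["pop_1990"]) / df["pop_1990"],
            np.nan,
        )
        df["share_1990"] = df["pop_1990"] / total90 if total90 > 0 else np.nan
        df["share_2010"] = df["pop_2010"] / total10 if total10 > 0 else np.nan
    df.loc["total", ["share_1990", "share_2010"]] = 1.0
    return df


def confounder_screen(
    pws, covariates: dict[str, np.ndarray], min_pixels: int = 30
) -> pd.DataFrame:
    """Pearson correlation of PWS with candidate biogeographic confounders.

    Returns per-covariate r, r^2 and pixel count over jointly valid
    pixels; constant covariates are flagged with NaN correlations.
    """
    pws_arr = getattr(pws, "pws", pws)
    rows = []
    for name, cov in covariates.items():
        cov = np.asarray(cov, dtype=float)
        ok = np.isfinite(pws_arr) & np.isfinite(cov)
        n = int(ok.sum())
        if n < min_pixels:
            raise ValueError(f"covariate {name!r}: only {n} jointly valid pixels")
        if np.ptp(cov[ok]) == 0 or np.ptp(pws_arr[ok]) == 0:
            warnings.warn(f"covariate {name!r} is constant; correlation undefined",
                          stacklevel=2)
            rows.append((name, np.nan, np.nan, n))
        else:
            r = float(stats.pearsonr(pws_arr[ok], cov[ok]).statistic)
            rows.append((name, r, r * r, n))
    return pd.DataFrame(rows, columns=["covariate", "r", "r2", "n"]).set_index("covariate")


def ndvi_precip_sensitivity(
    ndvi_annual: np.ndarray,
    precip_annual: np.ndarray,
    landcover: np.ndarray,
    pws,
    precip_groups: int | None = None,
    min_years: int = 5,
) -> pd.DataFrame:
    """Correlation of fuel-growth sensitivity to antecedent rain with PWS.

    Per pixel, the OLS slope of fire-season NDVI on antecedent (Dec-May)
    precipitation is computed; per land-cover class (and optionally per
    mean-precipitation quantile group) the Pearson correlation of that
    slope with PWS is reported.
    """
    ndvi_annual = np.asarray(ndvi_annual, dtype=float)
    precip_annual = np.asarray(precip_annual, dtype=float)
    pws_arr = getattr(pws, "pws", pws)
    if ndvi_annual.shape != precip_annual.shape:
        raise ValueError("NDVI and precipitation stacks must conform")
    n_years = ndvi_annual.shape[0]
    slopes = np.full(pws_arr.shape, np.nan)
    mean_p = np.full(pws_arr.shape, np.nan)
    for r in range(pws_arr.shape[0]):
        for c in range(pws_arr.shape[1]):
            y, x = ndvi_annual[:, r, c], precip_annual[:, r, c]
            ok = np.isfinite(y) & np.isfinite(x)
            if ok.sum() < min_years or np.ptp(x[ok]) == 0:
                continue
            res = stats.linregress(x[ok], y[ok])
            slopes[r, c] = res.slope
            mean_p[r, c] = x[ok].mean()

    rows = []
    for lc in np.unique(landcover[np.isfinite(pws_arr)]):
        in_lc = (landcover == lc) & np.isfinite(slopes) & np.isfinite(pws_arr)
        if precip_groups:
            edges = np.nanquantile(mean_p[in_lc], np.linspace(0, 1, precip_groups + 1))
            groups = np.searchsorted(edges[1:-1], mean_p, side="right")
            group_ids = range(precip_groups)
        else:
            groups = np.zeros(pws_arr.shape, dtype=int)
            group_ids = [0]
        for g in group_ids:
            sel = in_lc & (groups == g)
            n = int(sel.sum())

            def _constant(v):  # tolerance absorbs rounding of exact fits
                return np.ptp(v) <= 1e-10 * max(1.0, float(np.abs(v).max()))

            if n < 3 or _constant(slopes[sel]) or _constant(pws_arr[sel]):
                rows.append((lc, g, np.nan, n))
            else:
                r_val = float(stats.pearsonr(slopes[sel], pws_arr[sel]).statistic)
                rows.append((lc, g, r_val, n))
    return pd.DataFrame(rows, columns=["landcover", "precip_group", "r", "n"])
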