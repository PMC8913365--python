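"""Burned-area sensitivity to atmospheric aridity across PWS classes.

The PWS map is split into ``k`` bins of equal vegetated area; within each
bin, annual burned area (sum over member pixels) is regressed on annual
mean VPD (area-weighted over member pixels) with an unconstrained
intercept. A final regression of the per-bin slope d(BA)/d(VPD) on the
bin-representative PWS quantifies how plant-water sensitivity amplifies
the fire response to aridity. PWS also defines three hazard classes
(low < 1, medium 1-1.5, high > 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import AnnualFireSeries
from .pws import PWSMap

__all__ = [
    "BinAssignment",
    "SensitivitySlope",
    "equal_area_bins",
    "bin_annual_series",
    "ols_slope",
    "sensitivity_curve",
    "classify_hazard",
    "percent_change_sensitivity",
    "HAZARD_LOW",
    "HAZARD_MEDIUM",
    "HAZARD_HIGH",
    "HAZARD_INVALID",
]

HAZARD_INVALID, HAZARD_LOW, HAZARD_MEDIUM, HAZARD_HIGH = -1, 0, 1, 2


@dataclass
class BinAssignment:
    """Equal-vegetated-area partition of the PWS map."""

    k: int
    bin_index: np.ndarray  # int map, -1 outside the partition
    bin_area: np.ndarray  # (k,) vegetated area per bin, km^2
    rep_pws: np.ndarray  # (k,) representative (area-weighted mean) PWS
    counts: np.ndarray  # (k,) member pixels per bin


@dataclass
class SensitivitySlope:
    """OLS slope with its classical standard error and fit statistics."""

    slope: float
    stderr: float
    intercept: float
    r2: float
    p_value: float
    n: int


def _as_pws_array(pws) -> np.ndarray:
    return pws.pws if isinstance(pws, PWSMap) else np.asarray(pws, dtype=float)


def equal_area_bins(
    pws,
    veg_mask: np.ndarray,
    pixel_area,
    k: int,
    representative: str = "mean",
) -> BinAssignment:
    """Split valid vegetated pixels into ``k`` bins of equal vegetated area.

    Pixels are sorted by PWS (ties broken by flat pixel index via a stable
    sort) and the cumulative vegetated area is cut into ``k`` near-equal
    parts, so bin areas differ by at most one pixel's area.
    """
    values = _as_pws_array(pws)
    veg_mask = np.asarray(veg_mask, dtype=bool)
    area = np.broadcast_to(np.asarray(pixel_area, dtype=float), values.shape)
    valid = np.isfinite(values) & veg_mask
    n_valid = int(valid.sum())
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_valid < k:
        raise ValueError(f"k={k} exceeds the {n_valid} valid vegetated pixels")

    flat_idx = np.flatnonzero(valid.ravel())
    order = flat_idx[np.argsort(values.ravel()[flat_idx], kind="stable")]
    areas = area.ravel()[order]
    cum = np.cumsum(areas)
    total = cum[-1]
    bins = np.minimum(np.ceil(cum * k / total).astype(int) - 1, k - 1)
    bins = np.maximum(bins, 0)

    bin_index = np.full(values.shape, -1, dtype=int)
    bin_index.ravel()[order] = bins

    bin_area = np.bincount(bins, weights=areas, minlength=k)
    counts = np.bincount(bins, minlength=k)
    vals_sorted = values.ravel()[order]
    if representative == "mean":
        rep = np.bincount(bins, weights=areas * vals_sorted, minlength=k) / bin_area
    elif representative == "median":
        rep = np.array([np.median(vals_sorted[bins == b]) for b in range(k)])
    else:
        raise ValueError("representative must be 'mean' or 'median'")
    return BinAssignment(k, bin_index, bin_area, rep, counts)


def bin_annual_series(
    fire: AnnualFireSeries,
    bins: BinAssignment,
    pixel_area,
    weighted_vpd: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate per-pixel annual series to per-bin series.

    Returns ``(years, ba, vpd)`` where ``ba[y, b]`` is the summed burned
    area and ``vpd[y, b]`` the (vegetated-area-weighted by default) mean
    VPD of bin ``b`` in fire year ``y``.
    """
    if fire.burned is None or fire.vpd is None:
        raise ValueError("fire series must carry both burned area and VPD")
    k = bins.k
    area = np.broadcast_to(np.asarray(pixel_area, dtype=float), bins.bin_index.shape)
    n_years = len(fire.years)
    ba = np.zeros((n_years, k))
    vpd = np.zeros((n_years, k))
    member = bins.bin_index >= 0
    idx = bins.bin_index[member]
    w = area[member] if weighted_vpd else np.ones(member.sum())
    for j in range(n_years):
        ba_j = np.nan_to_num(fire.burned[j][member], nan=0.0)
        ba[j] = np.bincount(idx, weights=ba_j, minlength=k)
        v = fire.vpd[j][member]
        wv = np.where(np.isfinite(v), w, 0.0)
        vpd[j] = np.bincount(idx, weights=np.nan_to_num(v) * wv, minlength=k)
        denom = np.bincount(idx, weights=wv, minlength=k)
        vpd[j] = np.where(denom > 0, vpd[j] / np.maximum(denom, 1e-300), np.nan)
    return fire.years.copy(), ba, vpd


def ols_slope(y, x) -> SensitivitySlope:
    """Ordinary-least-squares slope of ``y`` on ``x`` with classical SE."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    if y.size < 3:
        raise ValueError("ols_slope requires at least 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("ols_slope requires a non-constant predictor")
    res = stats.linregress(x, y)
    return SensitivitySlope(
        slope=float(res.slope),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(y.size),
    )


def sensitivity_curve(bins: BinAssignment, slopes: list[SensitivitySlope]) -> SensitivitySlope:
    """Unweighted OLS of the per-bin d(BA)/d(VPD) slope on representative PWS."""
    if len(slopes) != bins.k:
        raise ValueError("one slope per bin required")
    if bins.k < 3:
        raise ValueError("sensitivity curve requires at least 3 bins")
    return ols_slope([s.slope for s in slopes], bins.rep_pws)


def classify_hazard(pws, thresholds: tuple[float, float] = (1.0, 1.5)) -> np.ndarray:
    """PWS hazard classes: low (< t1), medium (t1..t2 inclusive), high (> t2).

    Nodata pixels are coded ``HAZARD_INVALID`` (-1).
    """
    values = _as_pws_array(pws)
    t1, t2 = thresholds
    out = np.full(values.shape, HAZARD_INVALID, dtype=int)
    ok = np.isfinite(values)
    out[ok & (values < t1)] = HAZARD_LOW
    out[ok & (values >= t1) & (values <= t2)] = HAZARD_MEDIUM
    out[ok & (values > t2)] = HAZARD_HIGH
    return out


def percent_change_sensitivity(
    years: np.ndarray, ba: np.ndarray, vpd: np.ndarray, baseline_year: int = 2001
) -> list[SensitivitySlope]:
    """Per-bin slope of percent change in burned area (vs baseline) on VPD.

    Burned area is transformed to ``100 * (BA_y - BA_base) / BA_base``
    before the OLS fit, giving slopes in % per hPa.
    """
    years = np.asarray(years)
    if baseline_year not in years:
        raise ValueError(f"baseline year {baseline_year} not in series")
    j0 = int(np.flatnonzero(years == baseline_year)[0])
    out = []
    for b in range(ba.shape[1]):
        base = ba[j0, b]
        if not np.isfinite(base) or base <= 0:
            raise ValueError(f"bin {b}: baseline burned area must be positive")
        pct = 100.0 * (ba[:, b] - base) / base
        out.append(ols_slope(pct, vpd[:, b]))
    return out
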