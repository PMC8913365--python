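"""Half-monthly epoch calendar, seasonal climatologies, anomalies and
fire-year aggregates.

The fuel-moisture products are carried on a half-monthly ("epoch")
calendar: each month splits into days 1-15 and day 16 to month end, giving
24 epochs per year. Anomalies are raw values minus the pixel-specific
epoch-of-year climatology, which removes spatially varying seasonal cycles
before any regression. Fire years run April-March and are labelled by the
calendar year containing April.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridDef

__all__ = [
    "EpochCalendar",
    "EpochSeries",
    "Climatology",
    "AnnualFireSeries",
    "epoch_composite",
    "seasonal_climatology",
    "anomaly",
    "fire_year_aggregate",
]

EPOCHS_PER_YEAR = 24


@dataclass(frozen=True)
class EpochCalendar:
    """Ordered half-monthly epochs: (year, epoch_of_year in 1..24)."""

    frame: pd.DataFrame  # columns: year, eoy, month, start, end

    @classmethod
    def from_years(cls, years) -> "EpochCalendar":
        years = sorted(int(y) for y in years)
        rows = []
        for y in years:
            for m in range(1, 13):
                month_end = pd.Timestamp(y, m, 1) + pd.offsets.MonthEnd(0)
                rows.append((y, 2 * m - 1, m, pd.Timestamp(y, m, 1), pd.Timestamp(y, m, 15)))
                rows.append((y, 2 * m, m, pd.Timestamp(y, m, 16), month_end))
        frame = pd.DataFrame(rows, columns=["year", "eoy", "month", "start", "end"])
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def years(self) -> np.ndarray:
        return self.frame["year"].to_numpy()

    @property
    def eoy(self) -> np.ndarray:
        return self.frame["eoy"].to_numpy()

    @property
    def months(self) -> np.ndarray:
        return self.frame["month"].to_numpy()

    def index_of(self, year: int, eoy: int) -> int:
        hits = np.flatnonzero((self.years == year) & (self.eoy == eoy))
        if hits.size != 1:
            raise KeyError(f"epoch (year={year}, eoy={eoy}) not on calendar")
        return int(hits[0])

    def select(self, years=None, months=None) -> np.ndarray:
        """Boolean mask over epochs for given year/month subsets."""
        mask = np.ones(len(self), dtype=bool)
        if years is not None:
            mask &= np.isin(self.years, list(years))
        if months is not None:
            mask &= np.isin(self.months, list(months))
        return mask


@dataclass
class EpochSeries:
    """Per-pixel values on an epoch calendar: data (n_epochs, rows, cols)."""

    data: np.ndarray
    calendar: EpochCalendar
    grid: GridDef
    units: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.calendar), *self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} != "
                f"({len(self.calendar)}, {self.grid.n_rows}, {self.grid.n_cols})"
            )


@dataclass
class Climatology:
    """Per-pixel epoch-of-year means: data (24, rows, cols) and year counts."""

    data: np.ndarray
    counts: np.ndarray
    grid: GridDef
    units: str


@dataclass
class AnnualFireSeries:
    """Per-pixel fire-year aggregates labelled by the April-side year."""

    years: np.ndarray  # fire-year labels
    burned: np.ndarray | None  # (n_years, rows, cols), km^2, annual sum
    vpd: np.ndarray | None  # (n_years, rows, cols), hPa, annual mean
    grid: GridDef


def epoch_composite(
    daily: np.ndarray, dates: pd.DatetimeIndex, cal: EpochCalendar, grid: GridDef, units: str
) -> EpochSeries:
    """Average daily fields into half-monthly epochs.

    ``daily`` has shape (n_days, rows, cols) aligned with ``dates``. Each
    epoch value is the arithmetic mean of its valid days; epochs with no
    valid day are nodata.
    """
    daily = np.asarray(daily, dtype=float)
    if daily.shape[0] != len(dates):
        raise ValueError("daily stack and dates length mismatch")
    span_lo, span_hi = dates.min(), dates.max()
    cal_lo = cal.frame["start"].min()
    cal_hi = cal.frame["end"].max()
    if cal_lo < span_lo or cal_hi > span_hi:
        raise ValueError(
            f"daily data span {span_lo.date()}..{span_hi.date()} does not cover "
            f"calendar span {cal_lo.date()}..{cal_hi.date()}"
        )
    out = np.full((len(cal), *grid.shape), np.nan)
    # map each day to its epoch: eoy = 2*month - 1 + (day > 15)
    day_year = dates.year.to_numpy()
    day_eoy = 2 * dates.month.to_numpy() - 1 + (dates.day.to_numpy() > 15)
    key = day_year * 100 + day_eoy
    cal_key = cal.years * 100 + cal.eoy
    pos = {k: i for i, k in enumerate(cal_key)}
    idx = np.array([pos.get(k, -1) for k in key])
    for i in np.unique(idx):
        if i < 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[i] = np.nanmean(daily[idx == i], axis=0)
    return EpochSeries(out, cal, grid, units)


def seasonal_climatology(series: EpochSeries, years, min_years: int = 2) -> Climatology:
    """Per-pixel mean for each epoch of year across the given years.

    Entries with fewer than ``min_years`` contributing years are nodata.
    """
    years = sorted(set(int(y) for y in years))
    if not years:
        raise ValueError("empty year set for climatology")
    cal = series.calendar
    out = np.full((EPOCHS_PER_YEAR, *series.grid.shape), np.nan)
    counts = np.zeros((EPOCHS_PER_YEAR, *series.grid.shape), dtype=int)
    in_years = np.isin(cal.years, years)
    for e in range(1, EPOCHS_PER_YEAR + 1):
        sel = in_years & (cal.eoy == e)
        if not sel.any():
            continue
        vals = series.data[sel]
        n = np.isfinite(vals).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(vals, axis=0)
        mean[n < min_years] = np.nan
        out[e - 1] = mean
        counts[e - 1] = n
    return Climatology(out, counts, series.grid, series.units)


def anomaly(series: EpochSeries, clim: Climatology) -> EpochSeries:
    """Raw values minus the matching epoch-of-year climatology (nodata-propagating)."""
    if clim.grid.shape != series.grid.shape:
        raise ValueError("climatology grid does not conform to series grid")
    eoy_idx = series.calendar.eoy - 1
    out = series.data - clim.data[eoy_idx]
    return EpochSeries(out, series.calendar, series.grid, series.units)


def fire_year_aggregate(
    burned: EpochSeries | None,
    vpd: EpochSeries | None,
    year_start_month: int = 4,
) -> AnnualFireSeries:
    """Aggregate to fire years (annual burned-area sum, annual mean VPD).

    A fire year labelled ``y`` spans ``year_start_month`` of year ``y``
    through the month before it in year ``y+1`` (April-March by default).
    Fire years without complete calendar coverage are dropped.
    """
    ref = burned if burned is not None else vpd
    if ref is None:
        raise ValueError("at least one of burned or vpd is required")
    cal = ref.calendar
    fy = np.where(cal.months >= year_start_month, cal.years, cal.years - 1)
    labels = []
    for y in np.unique(fy):
        if np.sum(fy == y) == EPOCHS_PER_YEAR:
            labels.append(int(y))
    if not labels:
        warnings.warn("no complete fire year in the record", stacklevel=2)
    shape = (len(labels), *ref.grid.shape)
    ba_out = np.full(shape, np.nan) if burned is not None else None
    vpd_out = np.full(shape, np.nan) if vpd is not None else None
    for j, y in enumerate(labels):
        sel = fy == y
        if burned is not None:
            vals = burned.data[sel]
            any_valid = np.isfinite(vals).any(axis=0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                s = np.nansum(vals, axis=0)
            ba_out[j] = np.where(any_valid, s, np.nan)
        if vpd is not None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vpd_out[j] = np.nanmean(vpd.data[sel], axis=0)
    return AnnualFireSeries(np.array(labels), ba_out, vpd_out, ref.grid)
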