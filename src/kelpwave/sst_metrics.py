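"""Daily SST climatology, anomaly series, and annual heatwave temperature metrics.

The three annual metrics summarise thermal exposure over the September–August
"water year" preceding each annual kelp canopy survey:

* ``warmest_month_mean_sst`` — mean daily SST of the warmest calendar month,
* ``max_monthly_ssta`` — maximum over months of the monthly mean daily SST
  anomaly (SSTA = SST minus a day-of-year climatology),
* ``days_ssta_positive`` — count of days in the window with SSTA strictly > 0 °C.

The climatology is a day-of-year mean over user-chosen reference years, with
daily observations pooled over a centred circular smoothing window. February 29
shares the February 28 climatology (day-of-year 59), so March 1 is always day 60.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DailySstSeries",
    "Climatology",
    "DailyAnomalySeries",
    "WaterYearWindow",
    "day_of_year_365",
    "build_climatology",
    "anomaly_series",
    "monthly_summaries",
    "metric_warmest_month",
    "metric_max_monthly_ssta",
    "metric_days_positive",
    "compute_annual_metrics",
]

SST_SANITY_LOW = -5.0
SST_SANITY_HIGH = 40.0


def day_of_year_365(dates: pd.DatetimeIndex) -> np.ndarray:
    """Map calendar dates to a 365-day day-of-year index.

    Feb 29 maps to 59 (sharing Feb 28); every date from Mar 1 onward gets the
    same index in leap and non-leap years.
    """
    dates = pd.DatetimeIndex(dates)
    doy = dates.dayofyear.to_numpy().copy()
    leap_shift = dates.is_leap_year & (doy >= 60)
    doy[leap_shift] -= 1
    return doy


@dataclass(frozen=True)
class DailySstSeries:
    """Per-zone daily sea-surface temperature record (°C)."""

    zone_id: str
    dates: pd.DatetimeIndex
    sst: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        sst = np.asarray(self.sst, dtype=float)
        if len(dates) != len(sst):
            raise ValueError(f"zone {self.zone_id}: dates and sst length mismatch")
        if len(dates) == 0:
            raise ValueError(f"zone {self.zone_id}: empty series")
        if dates.has_duplicates:
            raise ValueError(f"zone {self.zone_id}: duplicate dates")
        if not dates.is_monotonic_increasing:
            raise ValueError(f"zone {self.zone_id}: dates must be sorted increasing")
        if not np.all(np.isfinite(sst)):
            raise ValueError(f"zone {self.zone_id}: non-finite SST values")
        if np.any(sst < SST_SANITY_LOW) or np.any(sst > SST_SANITY_HIGH):
            warnings.warn(
                f"zone {self.zone_id}: SST outside sanity bounds "
                f"[{SST_SANITY_LOW}, {SST_SANITY_HIGH}] °C",
                stacklevel=2,
            )
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "sst", sst)

    def __len__(self) -> int:
        return len(self.dates)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"zone_id": self.zone_id, "date": self.dates, "sst_c": self.sst}
        )


@dataclass(frozen=True)
class Climatology:
    """Day-of-year climatological mean SST (°C), 365 entries.

    ``values[d - 1]`` is the climatology for day-of-year ``d`` in the 365-day
    mapping of :func:`day_of_year_365`.
    """

    values: np.ndarray
    reference_years: tuple[int, ...] = ()
    smoothing_halfwidth: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (365,):
            raise ValueError("climatology must have exactly 365 day-of-year entries")
        if not np.all(np.isfinite(values)):
            raise ValueError("climatology contains non-finite values")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "reference_years", tuple(self.reference_years))

    def at(self, dates: pd.DatetimeIndex) -> np.ndarray:
        """Climatological mean for each date."""
        return self.values[day_of_year_365(dates) - 1]


@dataclass(frozen=True)
class DailyAnomalySeries:
    """Daily SST anomaly series: SST minus the day-of-year climatology."""

    zone_id: str
    dates: pd.DatetimeIndex
    ssta: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        ssta = np.asarray(self.ssta, dtype=float)
        if len(dates) != len(ssta):
            raise ValueError("dates and ssta length mismatch")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "ssta", ssta)

    def __len__(self) -> int:
        return len(self.dates)


@dataclass(frozen=True)
class WaterYearWindow:
    """September–August window preceding an annual survey.

    For ``survey_year`` 2014 the window is 2013-09-01 through 2014-08-31
    inclusive.
    """

    survey_year: int
    start: pd.Timestamp = field(init=False)
    end: pd.Timestamp = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.survey_year - 1, 9, 1))
        object.__setattr__(self, "end", pd.Timestamp(self.survey_year, 8, 31))

    @property
    def n_calendar_days(self) -> int:
        return int((self.end - self.start).days) + 1

    def months(self) -> pd.PeriodIndex:
        """Calendar months Sept (year−1) .. Aug (year), in window order."""
        return pd.period_range(self.start, self.end, freq="M")

    def mask(self, dates: pd.DatetimeIndex) -> np.ndarray:
        dates = pd.DatetimeIndex(dates)
        return (dates >= self.start) & (dates <= self.end)


def build_climatology(
    series: DailySstSeries,
    reference_years: Iterable[int],
    smoothing_halfwidth: int = 15,
) -> Climatology:
    """Day-of-year mean SST over reference years, with circular window pooling.

    For each day-of-year ``d`` the climatology is the mean of every reference-year
    observation whose day-of-year falls within ``d ± smoothing_halfwidth``
    (wrapping around the year boundary). ``smoothing_halfwidth=0`` gives the
    plain per-day mean. A warning is issued if any day-of-year has less than 50%
    of the expected observation count.
    """
    reference_years = sorted(set(int(y) for y in reference_years))
    if smoothing_halfwidth < 0:
        raise ValueError("smoothing_halfwidth must be >= 0")
    in_ref = np.isin(series.dates.year, reference_years)
    if not in_ref.any():
        raise ValueError(
            f"zone {series.zone_id}: no observations in reference years {reference_years}"
        )
    doy = day_of_year_365(series.dates[in_ref])
    vals = series.sst[in_ref]

    sums = np.bincount(doy - 1, weights=vals, minlength=365)
    counts = np.bincount(doy - 1, minlength=365).astype(float)

    if smoothing_halfwidth > 0:
        kernel = np.ones(2 * smoothing_halfwidth + 1)
        # circular pooling across the year boundary
        sums = _circular_convolve(sums, kernel)
        counts = _circular_convolve(counts, kernel)

    if np.any(counts == 0):
        missing = int(np.sum(counts == 0))
        raise ValueError(
            f"zone {series.zone_id}: {missing} day(s)-of-year have no reference "
            "observations; supply more reference data or widen the smoothing window"
        )
    expected = len(reference_years) * (2 * smoothing_halfwidth + 1)
    if np.any(counts < 0.5 * expected):
        warnings.warn(
            f"zone {series.zone_id}: some days-of-year have <50% reference coverage",
            stacklevel=2,
        )
    return Climatology(
        values=sums / counts,
        reference_years=tuple(reference_years),
        smoothing_halfwidth=smoothing_halfwidth,
    )


def _circular_convolve(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    h = (len(kernel) - 1) // 2
    padded = np.concatenate([x[-h:], x, x[:h]])
    return np.convolve(padded, kernel, mode="valid")


def anomaly_series(series: DailySstSeries, clim: Climatology) -> DailyAnomalySeries:
    """SSTA series: ``sst[t] − clim[day_of_year(t)]``, length preserved."""
    return DailyAnomalySeries(
        zone_id=series.zone_id,
        dates=series.dates,
        ssta=series.sst - clim.at(series.dates),
    )


def monthly_summaries(
    dates: pd.DatetimeIndex, values: np.ndarray, window: WaterYearWindow
) -> pd.Series:
    """Per-calendar-month means of a daily series within the window.

    Returns a Series indexed by month period, Sept..Aug in window order; months
    with no observations are NaN (flagged missing). Raises if the window holds
    no observations at all.
    """
    dates = pd.DatetimeIndex(dates)
    values = np.asarray(values, dtype=float)
    m = window.mask(dates)
    if not m.any():
        raise ValueError(
            f"no observations in window {window.start.date()}..{window.end.date()}"
        )
    periods = dates[m].to_period("M")
    by_month = pd.Series(values[m]).groupby(periods.to_numpy()).mean()
    return by_month.reindex(window.months())


def metric_warmest_month(
    series: DailySstSeries, window: WaterYearWindow
) -> tuple[pd.Period, float]:
    """Warmest calendar month in the window and its mean daily SST.

    Ties are broken by the earliest month in the Sept..Aug ordering.
    """
    means = monthly_summaries(series.dates, series.sst, window)
    if means.isna().all():
        raise ValueError("no month defined in window")
    # idxmax on the Sept..Aug-ordered Series returns the earliest tied month
    month = means.idxmax(skipna=True)
    return month, float(means.loc[month])


def metric_max_monthly_ssta(
    anoms: DailyAnomalySeries, window: WaterYearWindow
) -> float:
    """Maximum over months of the monthly mean daily SST anomaly."""
    means = monthly_summaries(anoms.dates, anoms.ssta, window)
    if means.isna().all():
        raise ValueError("no month defined in window")
    return float(means.max(skipna=True))


def metric_days_positive(anoms: DailyAnomalySeries, window: WaterYearWindow) -> int:
    """Count of days in the window with SSTA strictly greater than 0 °C."""
    m = window.mask(anoms.dates)
    return int(np.sum(anoms.ssta[m] > 0.0))


def _window_metrics(
    series: DailySstSeries, clim: Climatology, window: WaterYearWindow
) -> dict:
    anoms = anomaly_series(series, clim)
    n_days = int(window.mask(series.dates).sum())
    if n_days == 0:
        raise ValueError("empty window")
    if n_days < 0.8 * window.n_calendar_days:
        logger.warning(
            "zone %s, survey year %d: only %d/%d days available",
            series.zone_id,
            window.survey_year,
            n_days,
            window.n_calendar_days,
        )
    month, warm = metric_warmest_month(series, window)
    return {
        "survey_year": window.survey_year,
        "warmest_month": str(month),
        "warmest_month_mean_sst": warm,
        "max_monthly_ssta": metric_max_monthly_ssta(anoms, window),
        "days_ssta_positive": metric_days_positive(anoms, window),
        "n_days_available": n_days,
    }


def compute_annual_metrics(
    series_map: Mapping[str, DailySstSeries],
    clim: Climatology | Mapping[str, Climatology],
    survey_years: Sequence[int],
    zone_cells: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Annual temperature metrics for every zone × survey year.

    ``zone_cells`` maps zones to shared satellite grid cells; zones in the same
    cell receive identical metric rows (computed once from the first zone's
    series). ``clim`` may be a single climatology or a per-zone mapping.
    Windows that fail (no data) are skipped with a logged reason.
    """
    if not series_map:
        warnings.warn("no zones supplied; returning empty metrics table", stacklevel=2)
        return pd.DataFrame(
            columns=[
                "zone_id",
                "survey_year",
                "warmest_month",
                "warmest_month_mean_sst",
                "max_monthly_ssta",
                "days_ssta_positive",
                "n_days_available",
            ]
        )

    def clim_for(zone: str) -> Climatology:
        if isinstance(clim, Climatology):
            return clim
        return clim[zone]

    cells: dict[str, list[str]] = {}
    for zone in series_map:
        cell = zone_cells.get(zone, zone) if zone_cells else zone
        cells.setdefault(cell, []).append(zone)

    rows: list[dict] = []
    for cell, zones in cells.items():
        rep = zones[0]
        series = series_map[rep]
        for year in survey_years:
            window = WaterYearWindow(int(year))
            try:
                rec = _window_metrics(series, clim_for(rep), window)
            except ValueError as exc:
                logger.warning(
                    "cell %s, survey year %d skipped: %s", cell, year, exc
                )
                continue
            for zone in zones:
                rows.append({"zone_id": zone, **rec})
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["zone_id", "survey_year"]).reset_index(drop=True)
    return out
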