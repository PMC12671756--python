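"""Kelp canopy baseline, loss/recovery, scaling, and species comparison statistics.

Canopy area (hectares of floating kelp visible from the air) is tracked per
zone and year, optionally per species (bull kelp *Nereocystis luetkeana*,
giant kelp *Macrocystis pyrifera*, or both combined). The pre-heatwave
baseline is the mean ± sample s.d. over a reference period (2011–2013 by
default); "recovery" is the first post-decline year in which canopy area
returns to within one baseline standard deviation of the baseline mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BaselineStats",
    "RecoveryResult",
    "baseline_stats",
    "percent_of_baseline",
    "fold_difference",
    "max_loss",
    "recovery_year",
    "scale_to_max",
    "species_correlation",
    "subregion_annual_totals",
    "summary_table",
]

SCALE_CLAMP_LOW = 0.01
SCALE_CLAMP_HIGH = 0.99


@dataclass(frozen=True)
class BaselineStats:
    """Pre-heatwave canopy baseline for one unit (zone or sub-region)."""

    unit_id: str
    baseline_years: tuple[int, ...]
    mean_ha: float
    sd_ha: float  # sample (n−1) standard deviation

    def __post_init__(self) -> None:
        if self.sd_ha < 0:
            raise ValueError("sd_ha must be non-negative")


@dataclass(frozen=True)
class RecoveryResult:
    """Decline/recovery classification of an annual canopy series.

    ``decline_year`` is the first year at/after the heatwave onset with area
    below ``threshold_ha``; ``recovery_year`` is the first later year at or
    above it. ``None`` encodes "never".
    """

    unit_id: str
    decline_year: int | None
    recovery_year: int | None
    threshold_ha: float

    def __post_init__(self) -> None:
        if (
            self.decline_year is not None
            and self.recovery_year is not None
            and self.recovery_year <= self.decline_year
        ):
            raise ValueError("recovery_year must follow decline_year")


def _as_year_series(areas: Mapping[int, float] | pd.Series) -> pd.Series:
    s = pd.Series(dict(areas)) if not isinstance(areas, pd.Series) else areas
    s = s.astype(float).sort_index()
    s.index = s.index.astype(int)
    return s


def baseline_stats(
    areas: Mapping[int, float] | pd.Series,
    baseline_years: Iterable[int],
    unit_id: str = "",
) -> BaselineStats:
    """Mean and sample s.d. of canopy area over the baseline years present.

    Requires at least two baseline years with data (the sample s.d. needs
    n ≥ 2).
    """
    s = _as_year_series(areas)
    years = [y for y in sorted(set(int(y) for y in baseline_years)) if y in s.index]
    if len(years) < 2:
        raise ValueError(
            f"unit {unit_id or '<unnamed>'}: need >=2 baseline years with data, "
            f"got {len(years)}"
        )
    vals = s.loc[years].to_numpy()
    return BaselineStats(
        unit_id=unit_id,
        baseline_years=tuple(years),
        mean_ha=float(np.mean(vals)),
        sd_ha=float(np.std(vals, ddof=1)),
    )


def percent_of_baseline(area_ha: float, baseline: BaselineStats) -> float:
    """Percent difference of an annual area from the baseline mean."""
    if baseline.mean_ha <= 0:
        raise ValueError(f"unit {baseline.unit_id}: baseline mean must be positive")
    return 100.0 * (area_ha - baseline.mean_ha) / baseline.mean_ha


def fold_difference(min_ha: float, max_ha: float, decimals: int = 1) -> float:
    """Ratio of the highest to the lowest annual canopy area, to one decimal."""
    if min_ha <= 0:
        raise ValueError("fold difference undefined for non-positive minimum area")
    return round(max_ha / min_ha, decimals)


def max_loss(
    areas: Mapping[int, float] | pd.Series,
    baseline: BaselineStats,
    loss_window: Sequence[int],
) -> float:
    """Maximum loss within a year window, as integer percent of the baseline mean.

    ``100 × (baseline mean − window minimum) / baseline mean``, rounded to the
    nearest integer percent.
    """
    s = _as_year_series(areas)
    years = [y for y in loss_window if y in s.index]
    if not years:
        raise ValueError(f"no data in loss window {list(loss_window)}")
    if baseline.mean_ha <= 0:
        raise ValueError("baseline mean must be positive")
    window_min = float(s.loc[years].min())
    return round(100.0 * (baseline.mean_ha - window_min) / baseline.mean_ha)


def recovery_year(
    areas: Mapping[int, float] | pd.Series,
    baseline: BaselineStats,
    onset_year: int = 2014,
    symmetric: bool = False,
) -> RecoveryResult:
    """Classify decline and recovery of an annual canopy series.

    The threshold is ``mean − 1·sd``. Decline is the first year at/after
    ``onset_year`` with area below the threshold; recovery is the first later
    year at/above it. With ``symmetric=True``, recovery instead requires
    ``|area − mean| < sd`` (a band around the baseline mean); the decline
    definition is unchanged.
    """
    s = _as_year_series(areas)
    threshold = baseline.mean_ha - baseline.sd_ha

    decline: int | None = None
    for year, area in s.items():
        if year >= onset_year and area < threshold:
            decline = int(year)
            break

    recovery: int | None = None
    if decline is not None:
        for year, area in s.items():
            if year <= decline:
                continue
            recovered = (
                abs(area - baseline.mean_ha) < baseline.sd_ha
                if symmetric
                else area >= threshold
            )
            if recovered:
                recovery = int(year)
                break

    return RecoveryResult(
        unit_id=baseline.unit_id,
        decline_year=decline,
        recovery_year=recovery,
        threshold_ha=threshold,
    )


def scale_to_max(
    survey: pd.DataFrame,
    period: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Scale canopy area to the fraction of the zone × species maximum.

    Scaling is per zone and per species over the configured analysis period.
    Exact 0 is replaced with 0.01 and exact 1 with 0.99 so the result lies
    strictly inside (0, 1), as beta-regression responses must.

    Parameters
    ----------
    survey : DataFrame with columns zone_id, survey_year, species, area_ha
        (extra columns such as sub_region are carried through).
    period : optional year range restricting both the maximum and the output.
    """
    df = survey.copy()
    if period is not None:
        df = df[df["survey_year"].isin(list(period))]
    if df.empty:
        raise ValueError("no observations in the scaling period")

    zmax = df.groupby(["zone_id", "species"])["area_ha"].transform("max")
    bad = zmax <= 0
    if bad.any():
        zones = sorted(df.loc[bad, "zone_id"].unique())
        raise ValueError(f"all-zero canopy series cannot be scaled: zones {zones}")
    scaled = df["area_ha"] / zmax
    scaled = scaled.mask(scaled == 0.0, SCALE_CLAMP_LOW)
    scaled = scaled.mask(scaled == 1.0, SCALE_CLAMP_HIGH)
    out = df.copy()
    out["scaled"] = scaled
    return out.reset_index(drop=True)


def species_correlation(
    area_a: Sequence[float], area_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between matched zone-year areas of two species.

    Returns ``(r, p)`` with the two-sided t-test p-value. Requires at least
    three pairs and non-degenerate variance in both vectors.
    """
    a = np.asarray(area_a, dtype=float)
    b = np.asarray(area_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired area vectors must be 1-D and equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 matched pairs")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in one of the paired vectors")
    res = stats.pearsonr(a, b)
    return float(res.statistic), float(res.pvalue)


def subregion_annual_totals(survey: pd.DataFrame) -> pd.DataFrame:
    """Sum canopy area over zones and species to sub-region annual totals."""
    return (
        survey.groupby(["sub_region", "survey_year"], as_index=False)["area_ha"]
        .sum()
        .sort_values(["sub_region", "survey_year"])
        .reset_index(drop=True)
    )


def summary_table(
    survey: pd.DataFrame,
    period: Sequence[int],
    baseline_years: Sequence[int],
    loss_window: Sequence[int] = (2014, 2015, 2016),
) -> pd.DataFrame:
    """Per-sub-region descriptive statistics over an analysis period.

    One row per sub-region with: min/max annual total canopy area, fold
    difference (1 decimal), period mean ± s.d., baseline mean ± s.d., and the
    maximum loss within the loss window as integer percent of the baseline
    mean. Species are summed before aggregation.
    """
    totals = subregion_annual_totals(survey[survey["survey_year"].isin(list(period))])
    rows = []
    for sub_region, grp in totals.groupby("sub_region"):
        s = grp.set_index("survey_year")["area_ha"]
        base = baseline_stats(s, baseline_years, unit_id=str(sub_region))
        rows.append(
            {
                "sub_region": sub_region,
                "min_ha": float(s.min()),
                "max_ha": float(s.max()),
                "fold_difference": fold_difference(float(s.min()), float(s.max())),
                "mean_ha": float(s.mean()),
                "sd_ha": float(s.std(ddof=1)),
                "baseline_mean_ha": base.mean_ha,
                "baseline_sd_ha": base.sd_ha,
                "max_loss_pct": max_loss(s, base, loss_window),
            }
        )
    return pd.DataFrame(rows)
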