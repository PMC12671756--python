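"""Synthetic SST and canopy generators with known ground truth.

The SST generator produces a seasonal cosine cycle plus AR(1) noise and
boxcar heatwave events (a constant °C offset over a date range). The seasonal
cycle is evaluated on the same 365-day day-of-year mapping the climatology
builder uses, so a noise-free series reproduces its own halfwidth-0
climatology exactly — which is what makes the injected-event metric checks
exact rather than approximate.

The canopy generator draws zone-year scaled canopy fractions from a beta
regression with a Cauchy mean link on a standardized temperature metric, then
converts them to areas with a per-zone baseline scale; the generating
parameters are returned alongside so estimator-recovery tests have a truth
record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .beta_regression import inverse_cauchy_link
from .sst_metrics import (
    Climatology,
    DailySstSeries,
    compute_annual_metrics,
    day_of_year_365,
)

__all__ = [
    "SstSimParams",
    "CanopySimParams",
    "simulate_sst",
    "simulate_canopy",
    "make_fixture",
    "FixtureBundle",
]


@dataclass(frozen=True)
class SstSimParams:
    """Configuration for one zone-set of synthetic daily SST series.

    ``noise_sd`` is the stationary marginal standard deviation of the AR(1)
    noise (innovation sd = noise_sd·sqrt(1 − ar1²)). Events are
    (start date ISO, duration days, intensity °C) boxcars added to the cycle.
    Defaults emulate a cool temperate sea: 10 °C mean, ±4 °C seasonal range
    peaking in mid-August (day 227), day-to-day autocorrelation 0.8 with
    0.4 °C marginal noise.
    """

    mean_sst: float = 10.0
    seasonal_amplitude: float = 4.0
    peak_day: int = 227
    ar1_coefficient: float = 0.8
    noise_sd: float = 0.4
    heatwave_events: tuple[tuple[str, int, float], ...] = ()
    years: tuple[int, int] = (2011, 2018)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.ar1_coefficient < 1.0):
            raise ValueError("ar1_coefficient must be in [0, 1)")
        for start, duration, _ in self.heatwave_events:
            pd.Timestamp(start)
            if duration < 1:
                raise ValueError("event durations must be >= 1 day")


@dataclass(frozen=True)
class CanopySimParams:
    """Ground-truth beta-regression parameters for synthetic canopy areas.

    ``beta0``/``beta1`` act on the Cauchy-link scale applied to the chosen
    temperature metric standardized (z-scored) within sub-region; ``phi`` is
    the beta precision. ``baseline_scale_ha`` maps scaled fractions to areas.
    """

    zones: tuple[str, ...]
    centroids: tuple[tuple[float, float], ...]
    years: tuple[int, ...]
    beta0: float = 0.3
    beta1: float = -0.8
    phi: float = 20.0
    baseline_scale_ha: float = 100.0
    metric: str = "max_monthly_ssta"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if len(self.zones) < 3:
            raise ValueError("need at least 3 zones")
        if len(self.centroids) != len(self.zones):
            raise ValueError("one centroid per zone required")


def seasonal_cycle(dates: pd.DatetimeIndex, mean: float, amplitude: float, peak_day: int) -> np.ndarray:
    doy = day_of_year_365(dates)
    return mean + amplitude * np.cos(2.0 * np.pi * (doy - peak_day) / 365.0)


def expected_climatology(params: SstSimParams) -> Climatology:
    """The noise-free, event-free climatology implied by the seasonal cycle."""
    doy = np.arange(1, 366)
    values = params.mean_sst + params.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - params.peak_day) / 365.0
    )
    return Climatology(values=values, reference_years=(), smoothing_halfwidth=0)


def _event_offsets(dates: pd.DatetimeIndex, events) -> np.ndarray:
    offset = np.zeros(len(dates))
    for start, duration, intensity in events:
        t0 = pd.Timestamp(start)
        t1 = t0 + pd.Timedelta(days=int(duration) - 1)
        offset[(dates >= t0) & (dates <= t1)] += intensity
    return offset


def simulate_sst(
    params: SstSimParams,
    zone_ids: Sequence[str] = ("Z1",),
    rng: np.random.Generator | None = None,
) -> dict[str, DailySstSeries]:
    """Generate one daily SST series per zone (independent noise, shared cycle).

    sst[t] = mean + amplitude·cos(2π(doy(t) − peak_day)/365) + AR(1) noise
             + Σ event intensities active at t.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    y0, y1 = params.years
    dates = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    base = seasonal_cycle(dates, params.mean_sst, params.seasonal_amplitude, params.peak_day)
    base = base + _event_offsets(dates, params.heatwave_events)

    out: dict[str, DailySstSeries] = {}
    n = len(dates)
    innov_sd = params.noise_sd * np.sqrt(1.0 - params.ar1_coefficient**2)
    for zone in zone_ids:
        if params.noise_sd == 0.0:
            noise = np.zeros(n)
        else:
            innov = rng.normal(0.0, innov_sd, size=n)
            noise = np.empty(n)
            noise[0] = rng.normal(0.0, params.noise_sd)
            for t in range(1, n):
                noise[t] = params.ar1_coefficient * noise[t - 1] + innov[t]
        out[zone] = DailySstSeries(zone_id=str(zone), dates=dates, sst=base + noise)
    return out


def simulate_canopy(
    params: CanopySimParams,
    metrics: pd.DataFrame,
    sub_region: str = "Synthetic",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Draw zone-year canopy areas from the ground-truth beta regression.

    ``metrics`` must hold the chosen temperature metric for every zone × year
    (columns zone_id, survey_year, and ``params.metric``). The metric is
    z-scored across the zone-year rows, μ = inverse Cauchy link of
    β0 + β1·z, and the scaled response is Beta(μφ, (1−μ)φ). Returns the survey
    table (with the drawn ``scaled_true`` fraction) and a truth record.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    rows = metrics.set_index(["zone_id", "survey_year"])[params.metric]
    idx = pd.MultiIndex.from_product(
        [params.zones, params.years], names=["zone_id", "survey_year"]
    )
    missing = idx.difference(rows.index)
    if len(missing):
        raise ValueError(f"metrics missing for zone-years: {list(missing)[:5]}")
    m = rows.loc[idx].to_numpy()
    sd = m.std()
    z = np.zeros_like(m) if sd == 0 else (m - m.mean()) / sd
    mu = inverse_cauchy_link(params.beta0 + params.beta1 * z)
    scaled = rng.beta(mu * params.phi, (1.0 - mu) * params.phi)

    df = pd.DataFrame(
        {
            "zone_id": idx.get_level_values("zone_id"),
            "sub_region": sub_region,
            "survey_year": idx.get_level_values("survey_year"),
            "species": "nereocystis",
            "area_ha": scaled * params.baseline_scale_ha,
            "scaled_true": scaled,
            "mu_true": mu,
            "metric_z": z,
        }
    )
    truth = {
        "beta0": params.beta0,
        "beta1": params.beta1,
        "phi": params.phi,
        "metric": params.metric,
        "metric_mean": float(m.mean()),
        "metric_sd": float(sd),
    }
    return df, truth


@dataclass(frozen=True)
class FixtureBundle:
    """End-to-end synthetic study: SST series, canopy tables, zone centroids."""

    sst: dict[str, DailySstSeries]
    canopy: pd.DataFrame
    zones: pd.DataFrame  # zone_id, sub_region, x, y
    sub_regions: tuple[str, ...]
    truth: dict = field(default_factory=dict)

    def sst_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.sst.values()], ignore_index=True)


# escalating heatwave exposure from open coast to the innermost basin:
# (intensity °C, duration days from Sept 2014)
_FIXTURE_SUBREGIONS: tuple[tuple[str, float, int], ...] = (
    ("Coast", 1.0, 180),
    ("Western Strait", 1.3, 270),
    ("Eastern Strait", 1.8, 420),
    ("Smith Minor", 2.3, 560),
    ("Cypress", 3.0, 760),
    ("Cherry Point", 3.5, 940),
)


def make_fixture(
    seed: int = 0,
    n_zones_per_subregion: int = 10,
    years: tuple[int, int] = (1989, 2021),
    beta1: float = -1.5,
    phi: float = 60.0,
) -> FixtureBundle:
    """A miniature of the full study's structure for end-to-end tests.

    Six sub-regions × ``n_zones_per_subregion`` zones with centroids, daily SST
    over ``years``, a heatwave block beginning September 2014 whose intensity
    and duration escalate inland, and canopy tables driven by the maximum
    monthly SSTA through a Cauchy-link beta regression with slope ``beta1``.
    The mean-SST gradient (warmer inland) and the event gradient together make
    inland sub-regions both warmer and longer-anomalous, as in the study area.
    """
    if years[0] > 2010 or years[1] < 2018:
        raise ValueError(
            "fixture years must cover the 2011-2018 survey windows "
            "(September 2010 through August 2018)"
        )
    rng = np.random.default_rng(seed)
    sst: dict[str, DailySstSeries] = {}
    canopy_parts: list[pd.DataFrame] = []
    zone_rows: list[dict] = []
    truth: dict[str, dict] = {}

    survey_years = tuple(range(2011, 2019))
    for i, (name, intensity, duration) in enumerate(_FIXTURE_SUBREGIONS):
        params = SstSimParams(
            mean_sst=9.5 + 0.6 * i,
            seasonal_amplitude=3.5,
            peak_day=227,
            ar1_coefficient=0.7,
            noise_sd=0.3,
            heatwave_events=(("2014-09-15", duration, intensity),),
            years=years,
            seed=seed,
        )
        zones = tuple(f"{name.replace(' ', '')}-{j:02d}" for j in range(n_zones_per_subregion))
        sub_sst = simulate_sst(params, zone_ids=zones, rng=rng)
        sst.update(sub_sst)

        # centroids on a coarse coastline: sub-regions offset east, zones north
        for j, zone in enumerate(zones):
            zone_rows.append(
                {
                    "zone_id": zone,
                    "sub_region": name,
                    "x": 20_000.0 * i + rng.normal(0, 1_000),
                    "y": 3_000.0 * j + rng.normal(0, 500),
                }
            )

        # annual metric driving the canopy: computed from the event-free
        # climatology so the truth record is exact
        clim = expected_climatology(params)
        metrics = compute_annual_metrics(sub_sst, clim, survey_years)
        cparams = CanopySimParams(
            zones=zones,
            centroids=tuple((r["x"], r["y"]) for r in zone_rows[-len(zones):]),
            years=survey_years,
            beta0=1.0,
            beta1=beta1,
            phi=phi,
            baseline_scale_ha=400.0 / (1 + i),
            metric="max_monthly_ssta",
            seed=seed,
        )
        canopy, ctruth = simulate_canopy(cparams, metrics, sub_region=name, rng=rng)
        canopy_parts.append(canopy)
        truth[name] = {**ctruth, "intensity": intensity, "duration": duration}

    canopy_df = pd.concat(canopy_parts, ignore_index=True)
    zones_df = pd.DataFrame(zone_rows)
    return FixtureBundle(
        sst=sst,
        canopy=canopy_df[
            ["zone_id", "sub_region", "survey_year", "species", "area_ha"]
        ].copy(),
        zones=zones_df,
        sub_regions=tuple(s[0] for s in _FIXTURE_SUBREGIONS),
        truth=truth,
    )
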