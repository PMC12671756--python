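"""Climatology, anomaly, and annual temperature-metric behaviour."""

import numpy as np
import pandas as pd
import pytest

from kelpwave import sst_metrics as sm
from kelpwave import synthetic_data as sd

from conftest import make_series


def sinusoid_series(years=(2001, 2003), mean=10.0, amp=4.0, peak=227):
    params = sd.SstSimParams(
        mean_sst=mean, seasonal_amplitude=amp, peak_day=peak, noise_sd=0.0, years=years
    )
    return sd.simulate_sst(params)["Z1"], params


class TestDayOfYear:
    def test_feb29_shares_feb28(self):
        dates = pd.DatetimeIndex(["2004-02-28", "2004-02-29", "2004-03-01", "2003-03-01"])
        assert list(sm.day_of_year_365(dates)) == [59, 59, 60, 60]

    def test_year_end_is_365_in_both_calendars(self):
        dates = pd.DatetimeIndex(["2003-12-31", "2004-12-31"])
        assert list(sm.day_of_year_365(dates)) == [365, 365]


class TestClimatology:
    def test_constant_series_gives_constant_climatology(self, constant_series):
        clim = sm.build_climatology(constant_series, [2001, 2002, 2003], 15)
        assert np.allclose(clim.values, 10.0)

    def test_two_reference_years_hand_average(self):
        s1 = make_series("2001-01-01", "2001-12-31", 5.0)
        s2 = make_series("2002-01-01", "2002-12-31", 7.0)
        merged = sm.DailySstSeries(
            zone_id="Z1",
            dates=s1.dates.append(s2.dates),
            sst=np.concatenate([s1.sst, s2.sst]),
        )
        clim = sm.build_climatology(merged, [2001, 2002], 0)
        assert np.allclose(clim.values, 6.0)

    def test_sinusoid_halfwidth0_reproduces_cycle(self):
        series, params = sinusoid_series()
        clim = sm.build_climatology(series, [2001, 2002, 2003], 0)
        expected = sd.expected_climatology(params)
        assert np.allclose(clim.values, expected.values, atol=1e-12)

    def test_reference_anomaly_is_zero(self):
        """Anomalies of the reference series against its own climatology ≈ 0."""
        series, _ = sinusoid_series()
        clim = sm.build_climatology(series, [2001, 2002, 2003], 0)
        anoms = sm.anomaly_series(series, clim)
        assert np.allclose(anoms.ssta, 0.0, atol=1e-12)

    def test_no_reference_data_errors(self, constant_series):
        with pytest.raises(ValueError, match="reference"):
            sm.build_climatology(constant_series, [1990], 0)

    def test_series_validation(self):
        with pytest.raises(ValueError, match="sorted"):
            sm.DailySstSeries(
                zone_id="Z",
                dates=pd.DatetimeIndex(["2001-01-02", "2001-01-01"]),
                sst=np.array([1.0, 2.0]),
            )
        with pytest.warns(UserWarning, match="sanity"):
            make_series("2001-01-01", "2001-12-31", 45.0)


class TestAnomalies:
    def test_single_day_subtraction(self):
        series = make_series("2001-01-01", "2001-12-31", 10.0)
        sst = series.sst.copy()
        sst[100] = 12.5
        series = sm.DailySstSeries("Z1", series.dates, sst)
        clim = sm.Climatology(values=np.full(365, 10.0))
        anoms = sm.anomaly_series(series, clim)
        assert anoms.ssta[100] == pytest.approx(2.5)
        assert np.count_nonzero(anoms.ssta) == 1

    def test_injected_block_recovered_exactly(self):
        params = sd.SstSimParams(
            noise_sd=0.0,
            heatwave_events=(("2003-04-10", 30, 2.0),),
            years=(2001, 2003),
        )
        series = sd.simulate_sst(params)["Z1"]
        clim = sd.expected_climatology(params)
        anoms = sm.anomaly_series(series, clim)
        block = (series.dates >= "2003-04-10") & (series.dates <= "2003-05-09")
        assert np.allclose(anoms.ssta[block], 2.0)
        assert np.allclose(anoms.ssta[~block], 0.0)


class TestMonthlySummaries:
    def test_constant(self, constant_series):
        means = sm.monthly_summaries(
            constant_series.dates, constant_series.sst, sm.WaterYearWindow(2003)
        )
        assert len(means) == 12
        assert np.allclose(means.to_numpy(), 10.0)

    def test_alternating_hand_average(self):
        dates = pd.date_range("2013-09-01", "2013-09-30", freq="D")
        vals = np.where(np.arange(30) % 2 == 0, 10.0, 12.0)
        means = sm.monthly_summaries(dates, vals, sm.WaterYearWindow(2014))
        assert means.loc[pd.Period("2013-09", "M")] == pytest.approx(11.0)

    def test_missing_month_flagged(self):
        dates = pd.date_range("2012-09-01", "2013-08-31", freq="D")
        keep = ~((dates.month == 10) & (dates.year == 2012))
        means = sm.monthly_summaries(
            dates[keep], np.full(keep.sum(), 10.0), sm.WaterYearWindow(2013)
        )
        assert np.isnan(means.loc[pd.Period("2012-10", "M")])
        assert means.drop(pd.Period("2012-10", "M")).notna().all()

    def test_empty_window_errors(self, constant_series):
        with pytest.raises(ValueError, match="no observations"):
            sm.monthly_summaries(
                constant_series.dates, constant_series.sst, sm.WaterYearWindow(1990)
            )


class TestMetrics:
    def test_warmest_month_tie_breaks_earliest(self, constant_series):
        month, value = sm.metric_warmest_month(constant_series, sm.WaterYearWindow(2003))
        assert month == pd.Period("2002-09", "M")
        assert value == pytest.approx(10.0)

    def test_warmest_month_single_warm_month(self):
        dates = pd.date_range("2012-09-01", "2013-08-31", freq="D")
        vals = np.full(len(dates), 12.0)
        vals[(dates.month == 1)] = 15.0
        series = sm.DailySstSeries("Z", dates, vals)
        month, value = sm.metric_warmest_month(series, sm.WaterYearWindow(2013))
        assert month == pd.Period("2013-01", "M")
        assert value == pytest.approx(15.0)

    def test_warmest_month_sinusoid_peaks_august(self):
        series, _ = sinusoid_series()
        month, _ = sm.metric_warmest_month(series, sm.WaterYearWindow(2003))
        assert month == pd.Period("2003-08", "M")

    def test_max_monthly_ssta_zero_and_negative(self):
        dates = pd.date_range("2012-09-01", "2013-08-31", freq="D")
        zero = sm.DailyAnomalySeries("Z", dates, np.zeros(len(dates)))
        assert sm.metric_max_monthly_ssta(zero, sm.WaterYearWindow(2013)) == 0.0
        ssta = np.full(len(dates), -1.0)
        ssta[dates.month == 6] = -0.5
        neg = sm.DailyAnomalySeries("Z", dates, ssta)
        assert sm.metric_max_monthly_ssta(neg, sm.WaterYearWindow(2013)) == pytest.approx(-0.5)

    def test_days_positive_strict_and_bounds(self):
        dates = pd.date_range("2012-09-01", "2013-08-31", freq="D")
        w = sm.WaterYearWindow(2013)
        zero = sm.DailyAnomalySeries("Z", dates, np.zeros(len(dates)))
        assert sm.metric_days_positive(zero, w) == 0
        allpos = sm.DailyAnomalySeries("Z", dates, np.full(len(dates), 0.1))
        assert sm.metric_days_positive(allpos, w) == 365

    def test_days_positive_shift_invariance(self):
        """Adding a constant to both series and climatology leaves the count."""
        params = sd.SstSimParams(
            noise_sd=0.3, ar1_coefficient=0.5, years=(2001, 2003), seed=7
        )
        series = sd.simulate_sst(params)["Z1"]
        clim = sd.expected_climatology(params)
        w = sm.WaterYearWindow(2003)
        n0 = sm.metric_days_positive(sm.anomaly_series(series, clim), w)
        shifted = sm.DailySstSeries("Z1", series.dates, series.sst + 3.0)
        clim_shifted = sm.Climatology(values=clim.values + 3.0)
        n1 = sm.metric_days_positive(sm.anomaly_series(shifted, clim_shifted), w)
        assert n0 == n1

    def test_monthly_maxima_bounded_by_daily_maxima(self):
        params = sd.SstSimParams(noise_sd=0.5, years=(2001, 2003), seed=3)
        series = sd.simulate_sst(params)["Z1"]
        clim = sd.expected_climatology(params)
        anoms = sm.anomaly_series(series, clim)
        w = sm.WaterYearWindow(2003)
        in_w = w.mask(series.dates)
        assert sm.metric_max_monthly_ssta(anoms, w) <= anoms.ssta[in_w].max() + 1e-12
        _, warm = sm.metric_warmest_month(series, w)
        assert warm <= series.sst[in_w].max() + 1e-12


class TestAnnualMetricsTable:
    def test_shared_cell_rows_identical(self):
        params = sd.SstSimParams(noise_sd=0.2, years=(2001, 2003), seed=5)
        series = sd.simulate_sst(params, zone_ids=["A", "B"])
        clim = sd.expected_climatology(params)
        table = sm.compute_annual_metrics(
            series, clim, [2002, 2003], zone_cells={"A": "cell1", "B": "cell1"}
        )
        a = table[table.zone_id == "A"].drop(columns="zone_id").reset_index(drop=True)
        b = table[table.zone_id == "B"].drop(columns="zone_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_table_matches_per_window_computation(self):
        params = sd.SstSimParams(
            noise_sd=0.0,
            heatwave_events=(("2002-06-01", 30, 1.5), ("2003-06-01", 30, 2.5)),
            years=(2001, 2003),
        )
        series = sd.simulate_sst(params)
        clim = sd.expected_climatology(params)
        table = sm.compute_annual_metrics(series, clim, [2002, 2003])
        anoms = sm.anomaly_series(series["Z1"], clim)
        for year in (2002, 2003):
            w = sm.WaterYearWindow(year)
            row = table[table.survey_year == year].iloc[0]
            assert row.days_ssta_positive == sm.metric_days_positive(anoms, w)
            assert row.max_monthly_ssta == pytest.approx(
                sm.metric_max_monthly_ssta(anoms, w)
            )
            _, warm = sm.metric_warmest_month(series["Z1"], w)
            assert row.warmest_month_mean_sst == pytest.approx(warm)
        assert table.loc[table.survey_year == 2002, "days_ssta_positive"].iloc[0] == 30
        assert table.loc[table.survey_year == 2003, "days_ssta_positive"].iloc[0] == 30

    def test_empty_zone_set_warns(self):
        clim = sm.Climatology(values=np.full(365, 10.0))
        with pytest.warns(UserWarning, match="no zones"):
            table = sm.compute_annual_metrics({}, clim, [2013])
        assert table.empty

    def test_determinism_bit_identical(self):
        params = sd.SstSimParams(noise_sd=0.4, years=(2001, 2003), seed=11)
        series = sd.simulate_sst(params)
        clim = sd.expected_climatology(params)
        t1 = sm.compute_annual_metrics(series, clim, [2002, 2003])
        t2 = sm.compute_annual_metrics(series, clim, [2002, 2003])
        pd.testing.assert_frame_equal(t1, t2)
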