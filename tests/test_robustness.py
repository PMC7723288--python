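import numpy as np
import pandas as pd
import pytest

from springtrigger import (
    DailySeries,
    SampleSeries,
    SyntheticParams,
    annual_variable_matrix,
    anytime_trigger_scan,
    boundary_scan,
    compute_stt,
    fit_trigger_model,
    generate_study,
    lagged_crosscorr,
    peak_eggs,
    seasonal_aggregate_corr,
    smoothing_scan,
    window_width_scan,
)


@pytest.fixture(scope="module")
def quiet_scan_study():
    """Noise-free coupled study with events shorter than every scanned window."""
    return generate_study(
        SyntheticParams(
            seed=21, sst_amplitude=0.0, ar_sd=0.0, peak_noise_sd=0.0,
            tow_noise_cv=0.0, event_duration=5,
            # keep each event fully capturable by the shortest scanned window
            event_day_window=(95, 140),
        )
    )


class TestWindowWidthScan:
    def test_noise_free_coupled_is_perfect_at_every_width(self, quiet_scan_study):
        sst, eggs, _ = quiet_scan_study
        res = window_width_scan(sst, eggs, [14, 21, 28, 35])
        assert res.table["valid"].all()
        assert (res.table["rho"] > 0.999).all()

    def test_single_width_matches_direct_fit(self, coupled_study):
        sst, eggs, _ = coupled_study
        res = window_width_scan(sst, eggs, [28])
        stts = [compute_stt(sst, y, 28).stt for y in range(2013, 2020)]
        peaks = [peak_eggs(eggs, y)[0] for y in range(2013, 2020)]
        model = fit_trigger_model(stts, peaks)
        assert res.rho_at(L=28) == pytest.approx(model.rho, abs=1e-12)

    def test_invalid_widths_marked_not_dropped(self, coupled_study):
        sst, eggs, _ = coupled_study
        res = window_width_scan(sst, eggs, [28, 4000])  # longer than the record
        assert len(res.table) == 2
        row = res.table[res.table["L"] == 4000].iloc[0]
        assert not row["valid"]


class TestBoundaryScan:
    def test_center_cell_matches_window_scan(self, coupled_study):
        sst, eggs, _ = coupled_study
        b = boundary_scan(sst, eggs, [-7, 0, 7], [-7, 0, 7], 28)
        w = window_width_scan(sst, eggs, [28])
        assert b.rho_at(spring_end_offset=0, summer_start_offset=0) == w.rho_at(L=28)

    def test_each_cell_matches_direct_per_cell_analysis(self, coupled_study):
        sst, eggs, _ = coupled_study
        offsets = [-10, 0, 10]
        b = boundary_scan(sst, eggs, offsets, offsets, 28)
        for ds in offsets:
            for dss in offsets:
                stts, peaks = [], []
                for y in range(2013, 2020):
                    try:
                        stts.append(compute_stt(sst, y, 28, spring_end_offset=ds).stt)
                        peaks.append(
                            peak_eggs(eggs, y, ((6, 1), (8, 31)), start_offset=dss)[0]
                        )
                    except ValueError:
                        continue
                expected = fit_trigger_model(stts, peaks).rho
                got = b.rho_at(spring_end_offset=ds, summer_start_offset=dss)
                assert got == pytest.approx(expected, abs=1e-12)

    def test_flat_surface_when_peak_is_deep_inside_summer(self):
        sst, eggs, _ = generate_study(
            SyntheticParams(
                seed=22, sst_amplitude=0.0, ar_sd=0.0, peak_noise_sd=0.0,
                tow_noise_cv=0.0, peak_day_window=(190, 215),
                event_day_window=(95, 140),
            )
        )
        res = boundary_scan(sst, eggs, range(-7, 8), range(-7, 8), 28)
        rhos = res.table.loc[res.table["valid"], "rho"]
        assert rhos.max() - rhos.min() < 0.02

    def test_null_surface_is_fragile(self):
        # the overfitting hazard: under the null the surface swings widely
        ranges = []
        for s in range(15):
            sst, eggs, _ = generate_study(SyntheticParams(seed=s, null_model=True))
            res = boundary_scan(sst, eggs, range(-21, 22), range(-21, 22), 28)
            rhos = res.table.loc[res.table["valid"], "rho"].abs()
            ranges.append(rhos.max() - rhos.min())
        assert np.median(ranges) >= 0.3

    def test_empty_shifted_interval_is_invalid(self, coupled_study):
        sst, eggs, _ = coupled_study
        res = boundary_scan(sst, eggs, [-120, 0], [0], 28)
        bad = res.table[res.table["spring_end_offset"] == -120].iloc[0]
        assert not bad["valid"]


class TestAnytimeTrigger:
    def test_superset_of_spring_restricted_trigger(self, coupled_study):
        sst, eggs, _ = coupled_study
        _, records = anytime_trigger_scan(sst, eggs, 28)
        for _, row in records.iterrows():
            spring_stt = compute_stt(sst, int(row["year"]), 28).stt
            assert row["trigger"] >= spring_stt - 1e-12

    def test_winter_confound_degrades_correlation(self, quiet_scan_study):
        # a larger winter excursion uncorrelated with peaks hijacks the
        # any-time trigger while the spring-restricted STT is untouched
        sst, eggs, _ = quiet_scan_study
        data = sst.data.copy()
        rng = np.random.default_rng(0)
        for year in range(2013, 2020):
            day = pd.Timestamp(year, 2, 1)
            mag = rng.uniform(6.0, 12.0)
            for k in range(10):
                data.loc[day + pd.Timedelta(days=k)] += mag * k / 9
        confounded = DailySeries(data)
        spring_rho = window_width_scan(confounded, eggs, [28]).rho_at(L=28)
        anytime_rho, _ = anytime_trigger_scan(confounded, eggs, 28)
        assert anytime_rho < spring_rho - 0.2

    def test_single_year_rejected(self):
        sst, eggs, _ = generate_study(SyntheticParams(seed=23, n_years=1))
        with pytest.raises(ValueError, match="3"):
            anytime_trigger_scan(sst, eggs, 28)


class TestSmoothingScan:
    def test_width_one_equals_unsmoothed(self, coupled_study):
        sst, eggs, _ = coupled_study
        res = smoothing_scan(sst, eggs, [1], 28)
        assert res.rho_at(width=1) == window_width_scan(sst, eggs, [28]).rho_at(L=28)

    def test_monthly_averaging_shrinks_sharp_events_every_year(self, quiet_scan_study):
        sst, eggs, _ = quiet_scan_study
        from springtrigger import moving_average

        smoothed = moving_average(sst, 31)
        for year in range(2013, 2020):
            raw = compute_stt(sst, year, 28).stt
            sm = compute_stt(smoothed, year, 28).stt
            assert sm < raw

    def test_constant_sst_is_invalid_everywhere(self, coupled_study):
        _, eggs, _ = coupled_study
        days = pd.date_range("2013-01-01", "2019-12-31", freq="D")
        flat = DailySeries.from_pairs(days, np.full(len(days), 15.0))
        res = smoothing_scan(flat, eggs, [1, 7, 31], 28)
        assert not res.table["valid"].any()


class TestLaggedCrosscorr:
    def test_exact_linear_lag_recovered(self):
        days = pd.date_range("2013-01-01", "2016-12-31", freq="D")
        rng = np.random.default_rng(3)
        sst = DailySeries.from_pairs(days, rng.normal(15, 2, len(days)))
        # eggs on every day, an exact linear function of SST 30 days earlier
        egg_days = days[30:]
        eggs = SampleSeries.from_pairs(
            egg_days, 100.0 + 10.0 * sst.data.loc[egg_days - pd.Timedelta(days=30)].to_numpy()
        )
        res = lagged_crosscorr(sst, eggs, [0, 15, 30, 45])
        assert res.rho_at(delay=30) == pytest.approx(1.0, abs=1e-9)
        assert abs(res.rho_at(delay=0)) < 0.3

    def test_zero_tolerance_without_same_day_collections_is_invalid(self):
        days = pd.date_range("2015-01-01", "2016-12-31", freq="D")
        sst = DailySeries.from_pairs(days, np.arange(len(days), dtype=float))
        eggs = SampleSeries.from_pairs(
            pd.to_datetime(["2016-06-01", "2016-06-05"]), [5.0, 8.0]
        )
        res = lagged_crosscorr(sst, eggs, [0, 10], match_tolerance=0)
        assert not res.table["valid"].any()

    def test_independent_series_show_no_strong_delay(self):
        maxima = []
        for s in range(5):
            rng = np.random.default_rng(s)
            days = pd.date_range("2013-01-01", "2018-12-31", freq="D")
            sst = DailySeries.from_pairs(days, rng.normal(15, 2, len(days)))
            tow_days = days[:: 3][1:]
            eggs = SampleSeries.from_pairs(tow_days, rng.lognormal(3, 1, len(tow_days)))
            res = lagged_crosscorr(sst, eggs, range(0, 181, 5))
            maxima.append(res.table.loc[res.table["valid"], "rho"].abs().max())
        assert np.median(maxima) < 0.5


class TestSeasonalAggregate:
    def test_exact_negative_construction(self):
        days = pd.date_range("2013-01-01", "2019-12-31", freq="D")
        rng = np.random.default_rng(4)
        sst = DailySeries.from_pairs(days, rng.normal(15, 2, len(days)))
        rows_d, rows_v = [], []
        for year in range(2014, 2020):
            lo = pd.Timestamp(year - 1, 12, 1)
            hi = pd.Timestamp(year, 3, 1) - pd.Timedelta(days=1)  # Feb 28/29
            target = 400.0 - 10.0 * float(sst.between(lo, hi).mean())
            for month in (4, 6, 8):
                rows_d.append(pd.Timestamp(year, month, 15))
                rows_v.append(target)
        eggs = SampleSeries.from_pairs(pd.to_datetime(rows_d), rows_v)
        rho, per_year = seasonal_aggregate_corr(sst, eggs)
        assert rho == pytest.approx(-1.0, abs=1e-9)
        assert len(per_year) == 6

    def test_constant_winter_rejected(self):
        days = pd.date_range("2013-01-01", "2019-12-31", freq="D")
        sst = DailySeries.from_pairs(days, np.full(len(days), 14.0))
        _, eggs, _ = generate_study(SyntheticParams(seed=25))
        with pytest.raises(ValueError, match="zero variance"):
            seasonal_aggregate_corr(sst, eggs)

    def test_recovers_negative_winter_coupling(self):
        # winter -> eggs coupling injected through the latent peak height
        signs = []
        for s in range(20):
            p = SyntheticParams(seed=s)
            sst, eggs, truth = generate_study(p)
            data = eggs.data.copy()
            for year in range(2013, 2020):
                w = sst.between(pd.Timestamp(year - 1, 12, 1), pd.Timestamp(year, 2, 28))
                wmean = float(w.mean()) if len(w) else p.sst_mean
                mask = (data.index >= pd.Timestamp(year, 3, 1)) & (
                    data.index <= pd.Timestamp(year, 8, 31)
                )
                data.loc[mask] = np.maximum(
                    data.loc[mask] + 400.0 * (p.sst_mean - wmean), 0.0
                )
            rho, _ = seasonal_aggregate_corr(sst, SampleSeries(data))
            signs.append(rho < 0)
        assert np.mean(signs) >= 0.95


class TestAnnualVariableMatrix:
    def test_symmetric_unit_diagonal(self, coupled_study):
        sst, eggs, _ = coupled_study
        m = annual_variable_matrix(sst, eggs)
        assert np.allclose(np.diag(m.to_numpy()), 1.0)
        assert np.allclose(m.to_numpy(), m.to_numpy().T, atol=1e-12)

    def test_peak_and_mean_summer_eggs_positively_related(self, coupled_study):
        sst, eggs, _ = coupled_study
        m = annual_variable_matrix(sst, eggs)
        assert m.loc["peak_summer_eggs", "mean_summer_eggs"] > 0


class TestScanSupersetInvariant:
    def test_grid_growth_never_lowers_the_maximum(self, coupled_study):
        sst, eggs, _ = coupled_study
        small = window_width_scan(sst, eggs, [21, 28])
        large = window_width_scan(sst, eggs, [14, 21, 28, 35, 42])
        assert large.max_abs_rho >= small.max_abs_rho - 1e-15
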