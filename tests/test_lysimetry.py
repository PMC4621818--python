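"""Trace processing: VPD, Topp conversion, rates, PDT, dPW, WUE, ETW."""

import numpy as np
import pandas as pd
import pytest

from drylysim import lysimetry as lys
from drylysim import synth


def _flat_trace(hours=48, step_min=10, weight=3000.0, slope_g_min=0.0):
    idx = pd.date_range("2010-08-01", periods=hours * 60 // step_min,
                        freq=f"{step_min}min")
    w = weight - slope_g_min * np.arange(len(idx)) * step_min
    return lys.WeighTrace(
        plant_id="p0",
        data=pd.DataFrame(
            {"weight_g": w, "irrigation": False, "drainage": False}, index=idx
        ),
    )


class TestVpd:
    def test_saturated_air_has_zero_deficit(self):
        assert lys.compute_vpd(25.0, 100.0) == pytest.approx(0.0)

    def test_tetens_closed_form(self):
        # e_sat(25) = 0.6108 * exp(17.27*25/262.3) ~ 3.167 kPa; half at RH 50
        expected = 0.6108 * np.exp(17.27 * 25 / (25 + 237.3)) * 0.5
        assert lys.compute_vpd(25.0, 50.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.584, abs=2e-3)

    def test_monotone_in_temperature(self):
        assert lys.compute_vpd(30.0, 50.0) > lys.compute_vpd(20.0, 50.0)

    def test_humidity_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lys.compute_vpd(25.0, 101.0)


class TestToppVwc:
    def test_standard_coefficients_at_permittivity_20(self):
        vwc, clipped = lys.topp_vwc(20.0)
        c0, c1, c2, c3 = lys.TOPP_DEFAULT_COEFFS
        expected = c0 + c1 * 20 + c2 * 400 + c3 * 8000
        assert vwc == pytest.approx(expected, rel=1e-12)
        assert vwc == pytest.approx(0.346, abs=5e-3)
        assert not clipped

    def test_polynomial_root_maps_to_zero(self):
        # at eps ~ 1.84 the cubic crosses zero; just below it is clipped
        vwc, clipped = lys.topp_vwc(0.0)
        assert vwc == 0.0 and clipped  # c0 < 0 at eps=0

    def test_monotone_over_calibrated_range(self):
        eps = np.linspace(2, 60, 200)
        vwc, _ = lys.topp_vwc(eps)
        assert (np.diff(vwc) >= 0).all()

    def test_missing_coefficients_rejected(self):
        with pytest.raises(ValueError):
            lys.topp_vwc(20.0, coeffs=(1.0, 2.0))


class TestSmoothAndRate:
    def test_linear_decline_recovers_constant_rate(self):
        b = 0.25  # g/min
        trace = _flat_trace(hours=24, slope_g_min=b)
        rate = lys.smooth_and_rate(trace, window_min=30)
        inner = rate.iloc[5:-5]
        assert np.nanmax(np.abs(inner - b)) < 1e-9

    def test_constant_weight_gives_zero_rate(self):
        rate = lys.smooth_and_rate(_flat_trace(hours=24), window_min=30)
        assert np.nanmax(np.abs(rate)) < 1e-12

    def test_irrigation_interval_masked(self, noisefree_run):
        rate = lys.smooth_and_rate(noisefree_run.trace, window_min=30)
        irr_times = noisefree_run.trace.data.index[
            noisefree_run.trace.data["irrigation"]
        ]
        assert rate.loc[irr_times].isna().all()

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            lys.smooth_and_rate(_flat_trace(hours=1), window_min=600)


class TestDailyLedger:
    def test_constant_weight_day_zero_pdt(self):
        pdt = lys.daily_transpiration(_flat_trace(hours=48))
        assert (pdt["pdt_g"].abs() < 1e-12).all()

    def test_pdt_matches_simulated_transpiration_exactly(self, noisefree_run):
        daily = lys.daily_transpiration(noisefree_run.trace)
        ledger = noisefree_run.ledger["transpiration_g"]
        assert np.abs(daily["pdt_g"].to_numpy() - ledger.to_numpy()).max() < 1e-6

    def test_pdt_consistent_with_rate_integral(self, noisefree_run):
        """PDT and the integral of the smoothed rate measure the same water."""
        daily = lys.daily_transpiration(noisefree_run.trace)
        rate = lys.smooth_and_rate(noisefree_run.trace, window_min=30)
        step = noisefree_run.trace.step_min
        # drought days only (no irrigation mask), daytime span only: the
        # nightly biomass booking is not transpiration
        daytime = rate.between_time("05:00", "20:00")
        for day in daily.index[8:16]:
            integral = daytime[daytime.index.normalize() == day].sum() * step
            assert integral == pytest.approx(daily.loc[day, "pdt_g"], rel=0.02)

    def test_dpw_matches_simulated_biomass_gain(self, noisefree_run):
        dpw = lys.daily_weight_gain(noisefree_run.trace)
        gain = noisefree_run.ledger["biomass_gain_g"]
        joined = dpw["dpw_g"].dropna()
        for day, val in joined.items():
            k = (day - noisefree_run.trace.data.index[0].normalize()).days
            assert val == pytest.approx(gain.iloc[k], abs=1e-6)

    def test_zero_transpiration_gives_flat_weight_and_zero_gain(self, climate17):
        truth = synth.LysimeterTruth("null", e_max_true=0.0)
        run = synth.simulate_lysimeter_run(truth, climate17, phases=(4, 0, 0))
        dpw = lys.daily_weight_gain(run.trace)
        assert (dpw["dpw_g"].dropna().abs() < 1e-9).all()
        # outside the nightly irrigation-to-drainage window the weight is flat
        w = run.trace.data["weight_g"].between_time("00:00", "21:50")
        assert w.groupby(w.index.normalize()).std().max() < 1e-9

    def test_cumulative_dpw_telescopes(self, noisefree_run):
        """Summed dPW equals the difference of the bracketing morning weights."""
        dpw = lys.daily_weight_gain(noisefree_run.trace)
        valid = dpw.dropna()
        total = valid["dpw_g"].sum()
        tr = noisefree_run.trace
        w = tr.data["weight_g"]
        first, last = valid.index[0], valid.index[-1] + pd.Timedelta(days=1)
        wm = lambda day: w[(w.index >= day + pd.Timedelta("04:30:00"))
                           & (w.index <= day + pd.Timedelta("05:00:00"))].mean()
        assert total == pytest.approx(wm(last) - wm(first), abs=1e-6)


class TestWue:
    def test_exact_linear_relation(self):
        daily = pd.DataFrame(
            {
                "pdt_g": np.full(6, 50.0),
                "dpw_g": np.full(6, 5.0),
            }
        )
        daily["cum_transp_g"] = daily["pdt_g"].cumsum()
        daily["cum_gain_g"] = daily["dpw_g"].cumsum()
        fit = lys.fit_wue(daily)
        assert fit.wue == pytest.approx(0.1, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_too_few_days_rejected(self):
        daily = pd.DataFrame(
            {"pdt_g": [1.0, 2.0], "dpw_g": [0.1, 0.2],
             "cum_transp_g": [1.0, 3.0], "cum_gain_g": [0.1, 0.3]}
        )
        with pytest.raises(ValueError):
            lys.fit_wue(daily)

    def test_degenerate_transpiration_rejected(self):
        daily = pd.DataFrame(
            {"pdt_g": [0.0] * 4, "dpw_g": [0.1] * 4,
             "cum_transp_g": [0.0] * 4, "cum_gain_g": np.arange(4) * 0.1}
        )
        with pytest.raises(ValueError):
            lys.fit_wue(daily)

    def test_simulator_wue_recovered_exactly_without_noise(self, noisefree_run):
        daily = lys.build_daily(noisefree_run.trace)
        fit = lys.fit_wue(daily, phase=(0, 7))
        assert fit.wue == pytest.approx(noisefree_run.truth.wue_true, rel=1e-6)


class TestEtw:
    def test_arithmetic(self):
        idx = pd.date_range("2010-08-01 12:00", periods=3, freq="10min")
        rate = pd.Series([1.0, 1.0, 1.0], index=idx)
        weight = pd.Series([10.0], index=idx.normalize().unique())
        vpd = pd.Series([2.0, 2.0, 2.0], index=idx)
        etw = lys.normalize_etw(rate, weight, vpd)
        assert np.allclose(etw, 0.05)

    def test_homogeneity_in_plant_weight(self):
        idx = pd.date_range("2010-08-01 12:00", periods=3, freq="10min")
        rate = pd.Series([1.0, 2.0, 3.0], index=idx)
        vpd = pd.Series([2.0, 2.0, 2.0], index=idx)
        day = idx.normalize().unique()
        small = lys.normalize_etw(rate, pd.Series([10.0], index=day), vpd)
        large = lys.normalize_etw(rate, pd.Series([20.0], index=day), vpd)
        assert np.allclose(large * 2, small)

    def test_low_vpd_masked(self):
        idx = pd.date_range("2010-08-01 03:00", periods=2, freq="10min")
        rate = pd.Series([0.1, 0.1], index=idx)
        vpd = pd.Series([0.05, 0.5], index=idx)
        etw = lys.normalize_etw(rate, pd.Series([10.0], index=idx.normalize().unique()), vpd)
        assert np.isnan(etw.iloc[0]) and np.isfinite(etw.iloc[1])

    def test_nonpositive_weight_rejected(self):
        idx = pd.date_range("2010-08-01 12:00", periods=2, freq="10min")
        rate = pd.Series([1.0, 1.0], index=idx)
        vpd = pd.Series([2.0, 2.0], index=idx)
        with pytest.raises(ValueError):
            lys.normalize_etw(rate, pd.Series([0.0], index=idx.normalize().unique()), vpd)

    def test_equal_e_max_plants_have_equal_midday_plateaus(self, climate17):
        """Different-size plants with the same intrinsic response reach the
        same weight-normalized midday plateau."""
        plateaus = []
        for w0 in (20.0, 40.0):
            truth = synth.LysimeterTruth("x")
            run = synth.simulate_lysimeter_run(
                truth, climate17, phases=(4, 0, 0), initial_plant_weight_g=w0
            )
            daily = lys.build_daily(run.trace)
            rate = lys.smooth_and_rate(run.trace, 30)
            vpd = pd.Series(
                lys.compute_vpd(
                    climate17["air_temp_c"].to_numpy(),
                    climate17["rel_humidity_pct"].to_numpy(),
                ),
                index=climate17.index,
            )
            wbd = lys.plant_weight_series(daily, w0)
            etw = lys.normalize_etw(rate, wbd, vpd)
            mid = etw.between_time("11:00", "14:00")
            plateaus.append(np.nanmedian(mid))
        assert plateaus[0] == pytest.approx(plateaus[1], rel=0.05)
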