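"""Kinetic extraction: baseline, crossing, doubling time, lag, biomass ratio."""

import dataclasses
import math

import numpy as np
import pytest

from platequant import simulate
from platequant.errors import DataError, NoGrowthError, UndefinedRatioError
from platequant.io_plate import WellSeries
from platequant.kinetics import (
    FitConfig,
    baseline_correct,
    doubling_time,
    fit_growth,
    relative_biomass,
    threshold_crossing,
)


class TestBaselineCorrect:
    def test_median_and_floor(self):
        s = WellSeries("A1", np.arange(5) * 5.0, [0.05, 0.05, 0.05, 0.10, 0.30])
        corrected, baseline = baseline_correct(s, n_initial=3)
        assert baseline == 0.05
        assert np.allclose(corrected.od, [1e-4, 1e-4, 1e-4, 0.05, 0.25])

    def test_constant_series_floors_everywhere(self):
        s = WellSeries("A1", np.arange(4) * 5.0, [0.05] * 4)
        corrected, _ = baseline_correct(s, n_initial=2)
        assert np.all(corrected.od == 1e-4)

    def test_single_point_baseline(self):
        s = WellSeries("A1", [0.0, 5.0], [0.07, 0.3])
        corrected, baseline = baseline_correct(s, n_initial=1)
        assert baseline == 0.07
        assert corrected.od[1] == pytest.approx(0.23)

    def test_input_untouched_and_bad_n(self):
        od = np.array([0.05, 0.06, 0.3])
        s = WellSeries("A1", np.arange(3) * 5.0, od.copy())
        baseline_correct(s, 2)
        assert np.array_equal(s.od, od)
        with pytest.raises(DataError):
            baseline_correct(s, 3)


class TestThresholdCrossing:
    def test_closed_form_exponential(self):
        # OD = 0.01 * 2**(t/30) reaches 0.3 at t = 30*log2(30) ~ 147.2 min
        t = np.arange(0, 300, 5.0)
        s = WellSeries("A1", t, 0.01 * 2 ** (t / 30.0))
        got = threshold_crossing(s, 0.3)
        assert got == pytest.approx(30 * math.log2(30), abs=5.0)

    def test_flat_series_censored(self):
        s = WellSeries("A1", np.arange(10) * 5.0, [0.05] * 10)
        assert threshold_crossing(s, 0.3) is None

    def test_already_above_threshold_is_zero(self):
        s = WellSeries("A1", [0.0, 5.0], [0.4, 0.5])
        assert threshold_crossing(s, 0.3) == 0.0


class TestDoublingTime:
    @pytest.mark.parametrize("preset,td", [("OP50-like", 25.0), ("BY4742-like", 90.0)])
    def test_noise_free_recovery_within_1pct(self, preset, td):
        params = dataclasses.replace(simulate.strain_preset(preset), noise_cv=0.0)
        fit = fit_growth(simulate.simulate_well(params, 50, seed=1), 0.3)
        assert fit.doubling_time_min == pytest.approx(td, rel=0.01)

    def test_flat_series_is_no_growth(self):
        s = WellSeries("A1", np.arange(20) * 5.0, [0.05] * 20)
        corrected, _ = baseline_correct(s)
        with pytest.raises(NoGrowthError):
            doubling_time(corrected)
        fit = fit_growth(s, 0.3)
        assert fit.no_growth and fit.censored


class TestLagTime:
    def test_mid_growth_exponential_clamps_to_zero(self):
        # already growing at t=0: the tangent extrapolates below the floor
        t = np.arange(0, 300, 5.0)
        s = WellSeries("A1", t, 0.01 * 2 ** (t / 30.0))
        fit = fit_growth(s, 0.3)
        assert fit.lag_min == pytest.approx(0.0, abs=5.0)

    def test_inserted_lag_recovered(self):
        # initial biomass signal equals the corrected-OD floor, so the
        # floor-referenced tangent lands on the generative lag; a high
        # carrying capacity keeps the fit window purely exponential
        params = simulate.SimParams(
            doubling_time_min=25.0,
            lag_min=60.0,
            carrying_capacity_od=30.0,
            noise_cv=0.0,
            duration_min=400.0,
        )
        n0 = round(1e-4 / params.od_per_cell)  # 3333 cells
        cfg = FitConfig(band_lo_min_od=0.03)
        fit = fit_growth(simulate.simulate_well(params, n0, seed=1), 0.3, cfg)
        assert fit.lag_min == pytest.approx(60.0, abs=5.0)

    def test_doubling_inoculum_shifts_crossing_not_lag_shape(self):
        params = simulate.SimParams(
            doubling_time_min=25.0,
            lag_min=60.0,
            carrying_capacity_od=30.0,
            noise_cv=0.0,
            duration_min=400.0,
        )
        f1 = fit_growth(simulate.simulate_well(params, 3333, seed=1), 0.3)
        f2 = fit_growth(simulate.simulate_well(params, 6666, seed=1), 0.3)
        assert f1.crossing_min - f2.crossing_min == pytest.approx(25.0, abs=5.0)


class TestShiftLawAndMonotonicity:
    def test_crossing_strictly_decreasing_in_n0(self, op50_quiet):
        crossings = [
            fit_growth(simulate.simulate_well(op50_quiet, n0, seed=1), 0.3).crossing_min
            for n0 in (1, 2, 10, 100, 1000)
        ]
        assert all(a > b for a, b in zip(crossings, crossings[1:]))

    def test_doubling_n0_advances_crossing_by_td(self, op50_quiet):
        c1 = fit_growth(simulate.simulate_well(op50_quiet, 64, seed=1), 0.3).crossing_min
        c2 = fit_growth(simulate.simulate_well(op50_quiet, 128, seed=1), 0.3).crossing_min
        assert c1 - c2 == pytest.approx(25.0, abs=5.0)


class TestRelativeBiomass:
    def test_identity(self, op50_quiet):
        f = fit_growth(simulate.simulate_well(op50_quiet, 10, seed=3), 0.3)
        assert relative_biomass(f, f) == 1.0

    def test_two_cells_twice_one_cell(self, op50_quiet):
        one = fit_growth(simulate.simulate_well(op50_quiet, 1, seed=1), 0.3)
        two = fit_growth(simulate.simulate_well(op50_quiet, 2, seed=2), 0.3)
        ratio = relative_biomass(two, one)
        # +/- one sampling interval of interpolation tolerance on the shift
        assert 2 ** (1 - 5 / 25) <= ratio <= 2 ** (1 + 5 / 25)

    def test_decade_delay_is_tenth(self, op50_quiet):
        ref = fit_growth(simulate.simulate_well(op50_quiet, 100, seed=1), 0.3)
        tenth = fit_growth(simulate.simulate_well(op50_quiet, 10, seed=1), 0.3)
        assert relative_biomass(tenth, ref) == pytest.approx(0.1, rel=0.05)

    def test_censored_input_rejected(self, op50_quiet):
        grown = fit_growth(simulate.simulate_well(op50_quiet, 100, seed=1), 0.3)
        flat = fit_growth(simulate.simulate_well(op50_quiet, 0, seed=1), 0.3)
        with pytest.raises(UndefinedRatioError):
            relative_biomass(flat, grown)


class TestFitGrowthComposition:
    def test_default_well_fully_populated(self, op50_noisy):
        fit = fit_growth(simulate.simulate_well(op50_noisy, 1000, seed=5), 0.3)
        assert fit.crossing_min is not None
        assert fit.doubling_time_min is not None
        assert fit.lag_min is not None and fit.lag_min >= 0
        assert fit.od_max >= fit.baseline_od
        assert 0 < fit.r_squared <= 1

    def test_blank_well_flags(self, op50_noisy):
        fit = fit_growth(simulate.simulate_well(op50_noisy, 0, seed=5), 0.3)
        assert fit.censored and fit.no_growth

    def test_saturated_from_start_flags(self):
        s = WellSeries("A1", np.arange(10) * 5.0, np.full(10, 0.9))
        fit = fit_growth(s, 0.3)
        assert fit.crossing_min == 0.0
        assert "saturated-at-start" in fit.flags
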