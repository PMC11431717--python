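"""Ladder calibration: survival, linear range, CFU/mL, end-to-end recovery."""

import dataclasses
import itertools
import math

import numpy as np
import pytest
from platequant import simulate
from platequant.errors import CalibrationError, DomainError, UndefinedRatioError
from platequant.kinetics import GrowthFit
from platequant.quantify import (
    DilutionPoint,
    build_dilution_points,
    cfu_per_ml,
    correlate_actual_vs_expected,
    dynamic_range,
    find_linear_range,
    quantify_run,
    relative_survival,
)


def _fit(crossing, td=25.0, well="A1"):
    return GrowthFit(
        well_id=well,
        baseline_od=0.05,
        crossing_min=crossing,
        doubling_time_min=td,
        max_slope_log2_per_min=1 / td if td else None,
        lag_min=60.0,
        od_max=1.0,
        threshold_od=0.3,
        window=(10, 15),
        r_squared=1.0,
    )


class TestRelativeSurvival:
    def test_identical_fits_give_one(self):
        f = _fit(200.0)
        assert relative_survival(f, f).value == 1.0

    def test_one_td_delay_halves(self):
        assert relative_survival(_fit(225.0), _fit(200.0)).value == pytest.approx(0.5)

    def test_decade_law(self):
        delayed = _fit(200.0 + math.log2(10) * 25.0)
        assert relative_survival(delayed, _fit(200.0)).value == pytest.approx(0.1)

    def test_denser_than_reference_flagged(self):
        est = relative_survival(_fit(175.0), _fit(200.0))
        assert est.value == pytest.approx(2.0) and est.flagged_gt1

    def test_censored_sample_yields_upper_bound(self):
        est = relative_survival(_fit(None), _fit(200.0), duration_min=1440.0)
        assert est.is_upper_bound
        assert est.value == pytest.approx(2 ** (-(1440 - 200) / 25))

    def test_censored_reference_rejected(self):
        with pytest.raises(UndefinedRatioError):
            relative_survival(_fit(200.0), _fit(None))


class TestBuildDilutionPoints:
    def test_identical_replicates_equal_single_value(self):
        fbe = {0: [_fit(200.0)] * 6, -1: [_fit(200.0 + 25 * math.log2(10))] * 6}
        points, ref, td = build_dilution_points(fbe, td_source="reference")
        assert ref == 0
        by_exp = {p.exponent: p for p in points}
        assert by_exp[-1].survival == pytest.approx(0.1)
        assert by_exp[-1].n_detected == 6

    def test_censored_replicate_excluded_from_mean(self):
        fbe = {0: [_fit(200.0)] * 6, -1: [_fit(283.0)] * 5 + [_fit(None)]}
        points, _, _ = build_dilution_points(fbe, td_source="reference")
        p = {p.exponent: p for p in points}[-1]
        assert p.n_detected == 5 and p.survival is not None

    def test_all_censored_exponent_is_nondetect(self):
        fbe = {0: [_fit(200.0)] * 3, -8: [_fit(None)] * 3}
        points, _, _ = build_dilution_points(fbe, td_source="reference")
        p = {p.exponent: p for p in points}[-8]
        assert p.is_nondetect and p.survival is None


def _point(exp, survival, n=6):
    return DilutionPoint(exp, [], survival, n if survival else 0, survival is None)


def _brute_force_range(points, slope_tol=0.1, r2_min=0.99, min_len=3):
    """Independent oracle: try every contiguous run, pick (length, least
    diluted start) among qualifiers using plain linear algebra."""
    usable = sorted(
        [p for p in points if p.survival is not None], key=lambda p: -p.exponent
    )
    best = None
    for i, j in itertools.combinations(range(len(usable) + 1), 2):
        run = usable[i:j]
        if len(run) < min_len:
            continue
        exps = [p.exponent for p in run]
        if exps != list(range(exps[0], exps[0] - len(exps), -1)):
            continue
        x = np.array(exps, float)
        y = np.log10([p.survival for p in run])
        A = np.vstack([x, np.ones_like(x)]).T
        (slope, _), res, *_ = np.linalg.lstsq(A, y, rcond=None)
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 if ss_tot == 0 else 1.0 - (res[0] if len(res) else 0.0) / ss_tot
        if abs(slope - 1) <= slope_tol and r2 >= r2_min:
            key = (len(run), exps[0])
            if best is None or key > best[0]:
                best = (key, (exps[0], exps[-1]))
    return None if best is None else best[1]


class TestFindLinearRange:
    def test_perfect_ladder(self):
        points = [_point(-k, 10.0**-k) for k in range(7)]
        cal = find_linear_range(points)
        assert cal.linear_range == (0, -6)
        assert cal.slope == pytest.approx(1.0)
        assert cal.r == pytest.approx(1.0)
        assert dynamic_range(cal) == 7

    def test_nondetect_tail_ignored(self):
        points = [_point(-k, 10.0**-k) for k in range(7)] + [_point(-7, None)]
        assert find_linear_range(points).linear_range == (0, -6)

    def test_saturated_top_point_excluded(self):
        points = [_point(0, 1.0), _point(-1, 1.0)] + [
            _point(-k, 10.0 ** -(k - 1)) for k in range(2, 8)
        ]
        cal = find_linear_range(points)
        assert cal.linear_range == (-1, -7)
        assert cal.survival_by_exponent[-1] == pytest.approx(1.0)

    def test_no_qualifying_run_raises_with_diagnostics(self):
        points = [_point(0, 1.0), _point(-1, 0.9), _point(-2, 0.8)]
        with pytest.raises(CalibrationError) as exc:
            find_linear_range(points)
        assert exc.value.diagnostics

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        survivals = 10.0 ** (
            -np.arange(8) * rng.uniform(0.85, 1.15) + rng.normal(0, 0.02, 8)
        )
        # corrupt a random point and censor a random tail
        k = rng.integers(0, 8)
        survivals[k] *= 10 ** rng.normal(0, 0.5)
        points = [_point(-i, s) for i, s in enumerate(survivals)]
        if rng.random() < 0.5:
            points[-1] = _point(-7, None)
        expected = _brute_force_range(points)
        if expected is None:
            with pytest.raises(CalibrationError):
                find_linear_range(points)
        else:
            assert find_linear_range(points).linear_range == expected


class TestCfuPerMl:
    @pytest.mark.parametrize(
        "n_min,vn,expected",
        [
            (1_982_500, 1.0, 3.965e8),  # yeast reference count
            (1, 1.0, 200.0),  # the x200 unit conversion
            (1_315_000, 0.5, 1.315e8),  # E. coli count at half survival
        ],
    )
    def test_worked_examples(self, n_min, vn, expected):
        assert cfu_per_ml(n_min, vn, 5.0) == pytest.approx(expected)

    def test_linear_in_nmin_and_vn_and_volume(self):
        q = cfu_per_ml(1000, 0.3, 5.0)
        assert cfu_per_ml(2000, 0.3, 5.0) == pytest.approx(2 * q)
        assert cfu_per_ml(1000, 0.6, 5.0) == pytest.approx(2 * q)
        assert cfu_per_ml(1000, 0.3, 2.5) == pytest.approx(2 * q)

    def test_nonpositive_rejected(self):
        with pytest.raises(DomainError):
            cfu_per_ml(0, 1.0, 5.0)


class TestCorrelation:
    def test_perfect_ladder_r_one(self):
        cfu = [10.0**k for k in range(3, 9)]
        assert correlate_actual_vs_expected(cfu, cfu) == pytest.approx(1.0)

    def test_anti_ordered_r_minus_one(self):
        a = [10.0**k for k in range(3, 7)]
        assert correlate_actual_vs_expected(a, a[::-1]) == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(DomainError):
            correlate_actual_vs_expected([1, 10], [1, 10])


class TestEndToEndRecovery:
    def test_decade_law_on_noise_free_ladder(self, op50_quiet):
        run, layout, _ = simulate.simulate_dilution_series(
            op50_quiet, 2e5, list(range(0, -4, -1)), replicates=6, seed=3,
            poisson_seeding=False,
        )
        res = quantify_run(run, layout, n_min=2e5 * 0.005)["S"]
        for exp, vn in res.calibration.survival_by_exponent.items():
            assert vn == pytest.approx(10.0**exp, rel=0.01)

    def test_stock_recovery_noise_free_within_5pct(self, op50_quiet):
        stock = 4e8
        run, layout, _ = simulate.simulate_dilution_series(
            op50_quiet, stock, list(range(-1, -8, -1)), replicates=6, seed=5,
            poisson_seeding=False,
        )
        res = quantify_run(run, layout, n_min=stock * 1e-1 * 0.005)["S"]
        assert res.stock_cfu_per_ml == pytest.approx(stock, rel=0.05)

    def test_stock_recovery_5pct_noise_within_25pct(self, op50_quiet):
        stock = 4e8
        noisy = dataclasses.replace(op50_quiet, noise_cv=0.05)
        logs = []
        for k in range(3):  # three independent plates, median pooled
            run, layout, _ = simulate.simulate_dilution_series(
                noisy, stock, list(range(-1, -8, -1)), replicates=6, seed=100 + k
            )
            res = quantify_run(run, layout, n_min=stock * 1e-1 * 0.005)["S"]
            logs.append(math.log10(res.stock_cfu_per_ml))
        assert 10 ** np.median(logs) == pytest.approx(stock, rel=0.25)

    def test_seven_decade_noisy_ladder_correlation(self, op50_noisy):
        stock = 2.63e9
        run, layout, _ = simulate.simulate_dilution_series(
            op50_noisy, stock, list(range(-1, -8, -1)), replicates=6, seed=17
        )
        n_min = stock * 1e-1 * 0.005
        res = quantify_run(run, layout, n_min=n_min)["S"]
        cal = res.calibration
        assert dynamic_range(cal) == 7
        exps = sorted(cal.survival_by_exponent, reverse=True)
        r = correlate_actual_vs_expected(
            [n_min * cal.survival_by_exponent[e] * 200 for e in exps],
            [stock * 10.0**e for e in exps],
        )
        assert r >= 0.9991
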