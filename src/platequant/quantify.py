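"""Dilution-ladder calibration: relative survival, linear range, CFU/mL.

The enumeration logic: across a ten-fold dilution ladder, each extra decade
of dilution delays the threshold crossing by log2(10) doubling times, so the
relative survival Vn = 2**(-dt/Td) of a dilution versus the least-diluted
point in the linear range falls exactly one decade per dilution.  The least
diluted point inside the linear range (the "minimal dilution") is defined as
100% viability; one spread-plate count N_min anchors it in absolute CFU, and

    Q = N_min * Vn * (1000 / inoculum_volume_uL)

converts to CFU/mL (exactly the x200 factor for the standard 5 uL inoculum).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError, DomainError, UndefinedRatioError
from .io_plate import PlateLayout, PlateRun
from .kinetics import DEFAULT_CONFIG, FitConfig, GrowthFit, fit_growth


@dataclass
class SurvivalEstimate:
    """Relative survival of a sample versus a reference condition.

    ``value`` is 2**(-(t_c - t_c,ref)/Td); ``is_upper_bound`` marks a
    censored sample (survival below detection, bounded by the run length);
    ``flagged_gt1`` marks a sample denser than its reference (allowed, but
    worth a look)."""

    value: float
    is_upper_bound: bool = False
    flagged_gt1: bool = False


def relative_survival(
    fit: GrowthFit,
    reference: GrowthFit,
    td_ref: Optional[float] = None,
    duration_min: Optional[float] = None,
) -> SurvivalEstimate:
    """Vn = 2**(-(crossing - crossing_ref)/Td_ref).

    Uses the reference's doubling time unless ``td_ref`` overrides it.  A
    censored sample yields an upper bound computed from the run duration
    (requires ``duration_min``)."""
    if reference.crossing_min is None:
        raise UndefinedRatioError("reference crossing is censored")
    td = td_ref if td_ref is not None else reference.doubling_time_min
    if td is None or td <= 0:
        raise UndefinedRatioError("no usable doubling time for the reference")
    if fit.crossing_min is None:
        if duration_min is None:
            raise UndefinedRatioError(
                "sample crossing censored and no run duration given for a bound"
            )
        bound = 2.0 ** (-(duration_min - reference.crossing_min) / td)
        return SurvivalEstimate(value=bound, is_upper_bound=True)
    v = 2.0 ** (-(fit.crossing_min - reference.crossing_min) / td)
    return SurvivalEstimate(value=v, flagged_gt1=v > 1.0)


@dataclass
class DilutionPoint:
    """One rung of the ladder: replicate fits and their pooled survival."""

    exponent: int
    fits: list[GrowthFit]
    survival: Optional[float]  # geometric mean over detected replicates
    n_detected: int
    is_nondetect: bool = False
    flags: list[str] = field(default_factory=list)


@dataclass
class Calibration:
    """Accepted linear range of a dilution ladder plus its regression."""

    reference_exponent: int
    linear_range: tuple[int, int]  # (least-diluted, most-diluted) exponents
    slope: float
    intercept: float
    r: float
    survival_by_exponent: dict[int, float]  # renormalised: reference == 1
    td_used_min: float
    n_min: Optional[float] = None  # CFU per inoculum at the reference dilution
    q_cfu_per_ml: Optional[float] = None  # N_min * 200 at the reference

    @property
    def dynamic_range_decades(self) -> int:
        lo, hi = self.linear_range
        return lo - hi + 1


def _detected(fit: GrowthFit) -> bool:
    return fit.crossing_min is not None


def _usable_reference(fits: Sequence[GrowthFit]) -> bool:
    return all(
        _detected(f) and "saturated-at-start" not in f.flags for f in fits
    )


def _pool_td(fits_by_exponent: dict[int, list[GrowthFit]], td_source: str,
             reference_exponent: int) -> float:
    """Pick the doubling time used for all survival ratios.

    "dilute" (default): median Td over every exponent more dilute than the
    reference — those wells have the smallest inocula, whose exponential
    window is least distorted by inoculum carry-over in the baseline or by
    saturation (falls back to the reference exponent when nothing deeper
    detected).
    "reference": median Td of the reference-exponent wells.
    "pooled": median over every valid fit.
    """
    def valid_tds(fits):
        return [
            f.doubling_time_min
            for f in fits
            if f.doubling_time_min is not None and "unreliable-td" not in f.flags
        ]

    if td_source == "reference":
        tds = valid_tds(fits_by_exponent[reference_exponent])
    elif td_source == "pooled":
        tds = [td for fits in fits_by_exponent.values() for td in valid_tds(fits)]
    elif td_source == "dilute":
        tds = [
            td
            for exp, fits in fits_by_exponent.items()
            if exp < reference_exponent
            for td in valid_tds(fits)
        ]
        if not tds:
            tds = valid_tds(fits_by_exponent[reference_exponent])
    else:
        raise DomainError(f"unknown td_source {td_source!r}")
    if not tds:
        raise UndefinedRatioError("no valid doubling-time estimates in ladder")
    return float(np.median(tds))


def build_dilution_points(
    fits_by_exponent: dict[int, list[GrowthFit]],
    duration_min: Optional[float] = None,
    td_source: str = "dilute",
) -> tuple[list[DilutionPoint], int, float]:
    """Pool replicate fits per exponent into survival estimates.

    The provisional reference is the least-diluted exponent whose replicates
    all crossed the threshold without starting saturated; per-exponent
    survival is the geometric mean over detected replicates relative to that
    reference (survival is multiplicative, so the geometric mean is the
    right pooling).  Returns (points, provisional reference exponent, Td
    used)."""
    if not fits_by_exponent:
        raise DomainError("no dilution points supplied")
    eligible = [
        e for e, fits in fits_by_exponent.items() if fits and _usable_reference(fits)
    ]
    if not eligible:
        raise CalibrationError("no exponent has all replicates detected")
    ref_exp = max(eligible)
    td = _pool_td(fits_by_exponent, td_source, ref_exp)
    ref_fits = fits_by_exponent[ref_exp]
    t_ref = float(np.mean([f.crossing_min for f in ref_fits]))
    points = []
    for exp in sorted(fits_by_exponent, reverse=True):
        fits = fits_by_exponent[exp]
        detected = [f for f in fits if _detected(f)]
        flags = []
        if any("saturated-at-start" in f.flags for f in fits):
            flags.append("saturated")
        if not detected:
            points.append(
                DilutionPoint(exp, list(fits), None, 0, is_nondetect=True, flags=flags)
            )
            continue
        logs = [
            -(f.crossing_min - t_ref) / td * math.log10(2.0) for f in detected
        ]
        survival = 10.0 ** float(np.mean(logs))  # geometric mean
        points.append(
            DilutionPoint(exp, list(fits), survival, len(detected), flags=flags)
        )
    return points, ref_exp, td


def find_linear_range(
    points: Sequence[DilutionPoint],
    slope_tol: float = 0.1,
    r2_min: float = 0.99,
    min_len: int = 3,
    td_used_min: float = float("nan"),
) -> Calibration:
    """Select the longest run of >= ``min_len`` consecutive exponents whose
    log10(survival)-vs-exponent regression has slope within 1 +/- slope_tol
    and R^2 >= r2_min.  Ties go to the run containing less-diluted points.
    Survivals are renormalised so the accepted reference (least-diluted
    member) is exactly 1."""
    usable = sorted(
        (p for p in points if p.survival is not None and p.survival > 0),
        key=lambda p: -p.exponent,
    )
    diagnostics = []
    best = None  # (length, max_exponent, run, regression)
    n = len(usable)
    for i in range(n):
        for j in range(i + min_len, n + 1):
            run = usable[i:j]
            exps = [p.exponent for p in run]
            if any(exps[k] - exps[k + 1] != 1 for k in range(len(exps) - 1)):
                continue
            x = np.array(exps, dtype=float)
            y = np.log10([p.survival for p in run])
            reg = stats.linregress(x, y)
            r2 = reg.rvalue**2
            ok = abs(reg.slope - 1.0) <= slope_tol and r2 >= r2_min
            diagnostics.append(
                {"run": (exps[0], exps[-1]), "slope": reg.slope, "r2": r2, "ok": ok}
            )
            if not ok:
                continue
            key = (len(run), exps[0])
            if best is None or key > (len(best[2]), best[2][0].exponent):
                best = (len(run), exps[0], run, reg)
    if best is None:
        raise CalibrationError(
            "no contiguous run of >= %d dilutions satisfies slope 1+/-%.2g "
            "and R^2 >= %.3g" % (min_len, slope_tol, r2_min),
            diagnostics=diagnostics,
        )
    _, _, run, reg = best
    ref_exp = run[0].exponent
    v_ref = run[0].survival
    norm = {p.exponent: p.survival / v_ref for p in run}
    x = np.array([p.exponent for p in run], dtype=float)
    y = np.log10([norm[p.exponent] for p in run])
    reg2 = stats.linregress(x, y)
    return Calibration(
        reference_exponent=ref_exp,
        linear_range=(run[0].exponent, run[-1].exponent),
        slope=float(reg2.slope),
        intercept=float(reg2.intercept),
        r=float(reg2.rvalue),
        survival_by_exponent=norm,
        td_used_min=td_used_min,
    )


def cfu_per_ml(n_min: float, vn: float, inoculum_volume_uL: float = 5.0) -> float:
    """Q = N_min * Vn * (1000 / inoculum volume); the x200 factor at 5 uL."""
    if n_min <= 0 or vn <= 0 or inoculum_volume_uL <= 0:
        raise DomainError("n_min, vn and inoculum_volume_uL must all be positive")
    return n_min * vn * (1000.0 / inoculum_volume_uL)


def correlate_actual_vs_expected(
    actual_cfu: Sequence[float], expected_cfu: Sequence[float]
) -> float:
    """Pearson r between log10(actual) and log10(expected) CFU."""
    a = np.asarray(actual_cfu, dtype=float)
    e = np.asarray(expected_cfu, dtype=float)
    if len(a) != len(e) or len(a) < 3:
        raise DomainError("need at least 3 paired CFU values")
    if np.any(a <= 0) or np.any(e <= 0):
        raise DomainError("CFU values must be positive for a log-log correlation")
    r, _ = stats.pearsonr(np.log10(a), np.log10(e))
    return float(r)


def dynamic_range(calibration: Calibration) -> int:
    """Width of the linear range in orders of magnitude (inclusive)."""
    return calibration.dynamic_range_decades


@dataclass
class QuantResult:
    """Per-sample enumeration result."""

    sample_id: str
    calibration: Calibration
    points: list[DilutionPoint]
    n_min: float
    inoculum_volume_uL: float
    q_reference_cfu_per_ml: float  # concentration at the reference dilution
    stock_cfu_per_ml: float  # back-extrapolated undiluted concentration
    actual_cfu_by_exponent: dict[int, float]  # N_min * Vn * (1000/vol)

    def to_json_dict(self) -> dict:
        cal = self.calibration
        return {
            "sample_id": self.sample_id,
            "reference_exponent": cal.reference_exponent,
            "linear_range": list(cal.linear_range),
            "dynamic_range_decades": cal.dynamic_range_decades,
            "slope": cal.slope,
            "intercept": cal.intercept,
            "r": cal.r,
            "doubling_time_min": cal.td_used_min,
            "N_min": self.n_min,
            "Q_cfu_per_ml": self.q_reference_cfu_per_ml,
            "stock_cfu_per_ml": self.stock_cfu_per_ml,
            "per_dilution": [
                {
                    "exponent": p.exponent,
                    "survival": p.survival,
                    "n_detected": p.n_detected,
                    "nondetect": p.is_nondetect,
                }
                for p in self.points
            ],
        }


def quantify_sample(
    fits_by_exponent: dict[int, list[GrowthFit]],
    n_min: float,
    sample_id: str = "sample",
    inoculum_volume_uL: float = 5.0,
    duration_min: Optional[float] = None,
    td_source: str = "dilute",
    slope_tol: float = 0.1,
    r2_min: float = 0.99,
) -> QuantResult:
    """Ladder -> calibration -> CFU for one sample.

    ``n_min`` is the spread-plate anchor: CFU per inoculum volume at the
    reference dilution.  The stock estimate pools, geometrically, the
    per-dilution back-extrapolations N_min * Vn_k * (1000/vol) * 10**(-k)
    over the accepted linear range."""
    points, _, td = build_dilution_points(fits_by_exponent, duration_min, td_source)
    cal = find_linear_range(
        points, slope_tol=slope_tol, r2_min=r2_min, td_used_min=td
    )
    factor = 1000.0 / inoculum_volume_uL
    cal.n_min = n_min
    cal.q_cfu_per_ml = n_min * factor
    actual = {
        exp: cfu_per_ml(n_min, vn, inoculum_volume_uL)
        for exp, vn in cal.survival_by_exponent.items()
    }
    stock_logs = [
        math.log10(actual[exp]) - exp for exp in cal.survival_by_exponent
    ]
    stock = 10.0 ** float(np.mean(stock_logs))
    return QuantResult(
        sample_id=sample_id,
        calibration=cal,
        points=points,
        n_min=n_min,
        inoculum_volume_uL=inoculum_volume_uL,
        q_reference_cfu_per_ml=n_min * factor,
        stock_cfu_per_ml=stock,
        actual_cfu_by_exponent=actual,
    )


def quantify_run(
    run: PlateRun,
    layout: PlateLayout,
    n_min: float | dict[str, float],
    config: FitConfig = DEFAULT_CONFIG,
    td_source: str = "dilute",
) -> dict[str, QuantResult]:
    """Fit every sample well in a run and calibrate each sample's ladder.

    ``n_min`` may be a single anchor or a per-sample mapping."""
    results = {}
    for sample_id in layout.sample_ids():
        entries = [e for e in layout.wells_for(sample_id) if e.well in run]
        if not entries:
            continue
        fits_by_exponent: dict[int, list[GrowthFit]] = {}
        vol = entries[0].inoculum_volume_uL
        for e in entries:
            if e.dilution_exponent is None:
                warnings.warn(
                    f"well {e.well}: sample well without dilution_exponent skipped"
                )
                continue
            thr = config.threshold_for(e.strain_preset)
            fit = fit_growth(run[e.well], thr, config)
            fits_by_exponent.setdefault(e.dilution_exponent, []).append(fit)
        anchor = n_min[sample_id] if isinstance(n_min, dict) else n_min
        results[sample_id] = quantify_sample(
            fits_by_exponent,
            anchor,
            sample_id=sample_id,
            inoculum_volume_uL=vol,
            duration_min=run.duration_minutes,
            td_source=td_source,
        )
    return results
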