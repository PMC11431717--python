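"""Per-well growth-curve kinetics.

From a single well's OD(t) series this module extracts the quantities the
enumeration method needs:

* ``baseline_od`` — median of the first readings (medium + instrument offset).
* ``crossing_min`` — first time the *raw* OD reaches the strain's absolute
  detection threshold (0.3 OD for yeast/E. coli-type strains, 0.15 for
  lactobacilli-type), linearly interpolated between samples; censored if the
  run ends below threshold.
* ``doubling_time_min`` (Td) — reciprocal of the steepest slope of
  log2(baseline-corrected OD) over a sliding window restricted to the
  exponential band.
* ``lag_min`` — tangent-intersection lag: the time at which the max-slope
  tangent extrapolates back to the initial corrected OD level.

The central algebra of time-to-threshold enumeration: each missing doubling
of the inoculum delays the crossing by exactly one doubling time, so a
crossing delay dt relative to a reference implies an initial-biomass ratio
2**(-dt/Td).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DataError, NoGrowthError, UndefinedRatioError
from .io_plate import WellSeries

#: Corrected-OD floor keeping logarithms finite after baseline subtraction.
OD_FLOOR = 1e-4


@dataclass(frozen=True)
class FitConfig:
    """Tunable knobs of the kinetic extraction.

    threshold_od
        Absolute OD detection threshold compared against *raw* OD.
    window_w
        Sliding-window width in samples for the max-slope fit (5 points =
        25 min on the 5-min grid).
    band_hi_frac
        Upper edge of the fitting band as a fraction of the corrected OD
        maximum; excludes the saturation phase.
    band_lo_min_od
        Absolute lower edge of the fitting band; the effective lower edge is
        max(3 * baseline noise, band_lo_min_od), keeping the window off the
        log-floor plateau even on noise-free data.
    slope_se_z
        Window selection maximises slope minus ``slope_se_z`` predicted
        standard errors rather than the raw slope: near the noise floor the
        log-scale scatter is huge and a plain argmax would ride it.  With
        zero baseline noise the penalty vanishes and selection is the exact
        max-slope rule.
    baseline_n
        Number of initial readings whose median defines the baseline.
    floor_od
        Corrected-OD floor (see :data:`OD_FLOOR`).
    median_filter
        Optional 3-point median prefilter (off by default to preserve
        bit-exact reproducibility).
    strain_thresholds
        Per-preset absolute thresholds used when a layout names a preset.
    """

    threshold_od: float = 0.3
    window_w: int = 5
    band_hi_frac: float = 0.75
    band_lo_min_od: float = 5 * OD_FLOOR
    slope_se_z: float = 2.0
    baseline_n: int = 5
    floor_od: float = OD_FLOOR
    median_filter: bool = False
    strain_thresholds: dict = field(
        default_factory=lambda: {
            "BY4742": 0.3,
            "BY4742-like": 0.3,
            "OP50": 0.3,
            "OP50-like": 0.3,
            "LGG": 0.15,
            "LGG-like": 0.15,
        }
    )

    def threshold_for(self, strain_preset: Optional[str]) -> float:
        if strain_preset is None:
            return self.threshold_od
        try:
            return self.strain_thresholds[strain_preset]
        except KeyError:
            raise DataError(
                f"unknown strain preset {strain_preset!r}; known: "
                + ", ".join(sorted(self.strain_thresholds))
            ) from None


DEFAULT_CONFIG = FitConfig()


@dataclass
class GrowthFit:
    """Kinetic parameters extracted from one well."""

    well_id: str
    baseline_od: float
    crossing_min: Optional[float]  # None == censored (never reached threshold)
    doubling_time_min: Optional[float]
    max_slope_log2_per_min: Optional[float]
    lag_min: Optional[float]
    od_max: float
    threshold_od: float
    window: Optional[tuple[int, int]]  # [start, stop) indices of winning window
    r_squared: Optional[float]
    flags: list[str] = field(default_factory=list)

    @property
    def censored(self) -> bool:
        return self.crossing_min is None

    @property
    def no_growth(self) -> bool:
        return "no-growth" in self.flags


def baseline_correct(
    series: WellSeries, n_initial: int = 5, floor: float = OD_FLOOR
) -> tuple[WellSeries, float]:
    """Subtract the median of the first ``n_initial`` readings, clipping the
    result at ``floor`` so logs stay finite.  Returns a new series; the input
    is untouched."""
    if n_initial < 1 or n_initial >= len(series):
        raise DataError(
            f"n_initial must be in [1, {len(series) - 1}] (got {n_initial})"
        )
    baseline = float(np.median(series.od[:n_initial]))
    corrected = np.maximum(series.od - baseline, floor)
    return WellSeries(series.well_id, series.times.copy(), corrected), baseline


def baseline_noise(series: WellSeries, n_initial: int = 5) -> float:
    """Sample standard deviation of the first readings; 0 for n_initial < 2."""
    if n_initial < 2:
        return 0.0
    return float(np.std(series.od[:n_initial], ddof=1))


def threshold_crossing(series: WellSeries, threshold_od: float) -> Optional[float]:
    """First time raw OD reaches ``threshold_od``, linearly interpolated
    between the bracketing samples.  Returns ``None`` (censored) if the run
    never reaches the threshold; 0 if the first reading is already above."""
    if threshold_od <= 0:
        raise DataError("threshold_od must be positive")
    od = series.od
    if not np.all(np.isfinite(od)):
        raise DataError(f"well {series.well_id}: non-finite OD")
    above = od >= threshold_od
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return 0.0
    t0, t1 = series.times[i - 1], series.times[i]
    y0, y1 = od[i - 1], od[i]
    return float(t0 + (threshold_od - y0) * (t1 - t0) / (y1 - y0))


@dataclass
class _WindowFit:
    slope: float  # log2 OD per minute
    intercept: float
    start: int
    stop: int  # exclusive
    r_squared: float


def _median3(x: np.ndarray) -> np.ndarray:
    out = x.copy()
    out[1:-1] = np.median(np.column_stack([x[:-2], x[1:-1], x[2:]]), axis=1)
    return out


def _point_log2_sd(od_vals: np.ndarray, noise_sd: float, baseline_od: float):
    """Predicted per-point noise sd of log2(corrected OD).

    The reader noise model is multiplicative with a CV estimated from the
    baseline readings (sd noise_sd at level baseline_od), so the absolute
    noise at corrected level x is ~ noise_sd * (x + baseline)/baseline and
    the log2-scale sd is that over x*ln2.  With an unknown (zero) baseline
    the noise is treated as additive."""
    if noise_sd <= 0:
        return np.zeros_like(od_vals)
    if baseline_od > 0:
        abs_sd = noise_sd * (od_vals + baseline_od) / baseline_od
    else:
        abs_sd = np.full_like(od_vals, noise_sd)
    return abs_sd / (od_vals * math.log(2.0))


def doubling_time(
    corrected: WellSeries,
    noise_sd: float = 0.0,
    config: FitConfig = DEFAULT_CONFIG,
    baseline_od: float = 0.0,
) -> tuple[float, _WindowFit]:
    """Doubling time from the steepest sliding-window slope of
    log2(corrected OD).

    The fit is restricted to the exponential band
    [max(3*noise_sd, band_lo_min_od), band_hi_frac * od_max].  Window
    selection maximises the slope penalised by ``slope_se_z`` predicted
    standard errors (see :class:`FitConfig`); ties go to the earliest
    window.  The winning window is then refit over a w//2-widened in-band
    neighbourhood, which averages out the selection noise while leaving
    noise-free data exact.  Raises :class:`NoGrowthError` when no window of
    ``window_w`` consecutive in-band points exists or the best slope is not
    positive.
    """
    w = config.window_w
    od = _median3(corrected.od) if config.median_filter else corrected.od
    t = corrected.times
    od_max = float(od.max())
    lo = max(3.0 * noise_sd, config.band_lo_min_od)
    hi = config.band_hi_frac * od_max
    mask = (od >= lo) & (od <= hi)
    best: Optional[_WindowFit] = None
    best_score = -math.inf
    n = len(od)
    if w >= 3:
        for start in range(0, n - w + 1):
            if not mask[start : start + w].all():
                continue
            x = t[start : start + w]
            yv = od[start : start + w]
            y = np.log2(yv)
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
            c = (x - x.mean()) / float(np.sum((x - x.mean()) ** 2))
            se = math.sqrt(
                float(np.sum((c * _point_log2_sd(yv, noise_sd, baseline_od)) ** 2))
            )
            score = slope - config.slope_se_z * se
            if score > best_score:
                best_score = score
                best = _WindowFit(float(slope), float(intercept), start, start + w, r2)
    if best is None or best.slope <= 0:
        raise NoGrowthError(
            f"well {corrected.well_id}: no exponential-phase window in band "
            f"[{lo:.3g}, {hi:.3g}]"
        )
    best = _refit_widened(t, od, mask, best, w)
    return 1.0 / best.slope, best


def _refit_widened(t, od, mask, best: _WindowFit, w: int) -> _WindowFit:
    """Refit the slope over the winning window widened by w//2 in-band
    points on each side.  Choosing the location by max slope rides the noise
    of that particular window; refitting over a wider stretch (still inside
    the band) averages it out while leaving noise-free data exact."""
    start, stop = best.start, best.stop
    pad = w // 2
    lo_i = start
    while lo_i > 0 and start - lo_i < pad and mask[lo_i - 1]:
        lo_i -= 1
    hi_i = stop
    n = len(od)
    while hi_i < n and hi_i - stop < pad and mask[hi_i]:
        hi_i += 1
    if (lo_i, hi_i) == (start, stop):
        return best
    x = t[lo_i:hi_i]
    y = np.log2(od[lo_i:hi_i])
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:  # widening should never flip the sign; keep the original
        return best
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return _WindowFit(float(slope), float(intercept), lo_i, hi_i, r2)


def lag_time(
    corrected: WellSeries, window_fit: _WindowFit, floor: float = OD_FLOOR
) -> float:
    """Tangent-intersection lag: extrapolate the max-slope tangent back to
    the initial corrected OD level (>= floor); clamped at 0."""
    t = corrected.times[window_fit.start : window_fit.stop]
    y = np.log2(corrected.od[window_fit.start : window_fit.stop])
    t_w = float(t.mean())
    y_w = float(y.mean())  # least-squares line passes through the centroid
    od0 = max(float(corrected.od[0]), floor)
    lag = t_w - (y_w - math.log2(od0)) / window_fit.slope
    return max(lag, 0.0)


def relative_biomass(fit: GrowthFit, reference: GrowthFit) -> float:
    """Inferred initial-biomass ratio of ``fit`` relative to ``reference``
    under pure exponential growth: 2**(-(t_c - t_c,ref)/Td_ref).

    A crossing earlier than the reference by exactly one doubling time means
    twice the starting biomass.  Warns when the two doubling times differ by
    more than 20% (the shift law assumes a shared Td).
    """
    if fit.crossing_min is None or reference.crossing_min is None:
        raise UndefinedRatioError(
            "relative biomass undefined: censored threshold crossing"
        )
    td = reference.doubling_time_min
    if td is None or td <= 0:
        raise UndefinedRatioError("reference has no doubling-time estimate")
    if (
        fit.doubling_time_min is not None
        and abs(fit.doubling_time_min - td) > 0.2 * td
    ):
        warnings.warn(
            f"doubling times differ by more than 20% "
            f"({fit.doubling_time_min:.1f} vs {td:.1f} min); "
            "biomass ratio assumes a shared Td",
            stacklevel=2,
        )
    return 2.0 ** (-(fit.crossing_min - reference.crossing_min) / td)


def fit_growth(
    series: WellSeries,
    threshold_od: Optional[float] = None,
    config: FitConfig = DEFAULT_CONFIG,
) -> GrowthFit:
    """Full per-well extraction: baseline -> crossing -> doubling time -> lag.

    Deterministic given inputs and config.  Sub-step failures are recorded as
    flags rather than raised: ``no-growth`` (no exponential window),
    ``censored`` (never reached threshold), ``saturated-at-start`` (already
    above threshold at t=0, doubling time unreliable).
    """
    if threshold_od is None:
        threshold_od = config.threshold_od
    flags: list[str] = []
    crossing = threshold_crossing(series, threshold_od)
    if crossing is None:
        flags.append("censored")
    elif crossing == 0.0:
        flags.append("saturated-at-start")
    corrected, baseline = baseline_correct(series, config.baseline_n, config.floor_od)
    noise = baseline_noise(series, config.baseline_n)
    td = slope = lag = r2 = None
    window = None
    try:
        td, wfit = doubling_time(corrected, noise, config, baseline)
        slope = wfit.slope
        window = (wfit.start, wfit.stop)
        r2 = wfit.r_squared
        lag = lag_time(corrected, wfit, config.floor_od)
    except NoGrowthError:
        flags.append("no-growth")
    if "saturated-at-start" in flags and td is not None:
        flags.append("unreliable-td")
    return GrowthFit(
        well_id=series.well_id,
        baseline_od=baseline,
        crossing_min=crossing,
        doubling_time_min=td,
        max_slope_log2_per_min=slope,
        lag_min=lag,
        od_max=float(series.od.max()),
        threshold_od=threshold_od,
        window=window,
        r_squared=r2,
        flags=flags,
    )
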