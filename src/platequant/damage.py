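"""Thermal-injury comparison of treated versus control growth curves.

Sublethal heat damage shows up in a growth curve in two ways a colony count
cannot separate: a reduced surviving fraction (later threshold crossing) and
an extended lag in the survivors.  Comparing a treated well's fit against an
untreated control quantifies both and classifies the well as
normal / damaged / dead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import UndefinedRatioError
from .kinetics import GrowthFit
from .quantify import SurvivalEstimate, relative_survival


@dataclass(frozen=True)
class DamageThresholds:
    """Classification thresholds (this package's convention; the underlying
    assay reports damage qualitatively).  ``survival_lo`` is the surviving
    fraction below which a condition counts as damaged; ``lag_shift_min`` is
    the lag extension (default two 5-min sampling intervals) that also
    counts as damage."""

    survival_lo: float = 0.5
    lag_shift_min: float = 10.0


@dataclass
class TreatmentComparison:
    survival: SurvivalEstimate
    crossing_shift_min: Optional[float]  # treated - control; None if censored
    lag_shift_min: Optional[float]
    state: str  # "normal" | "damaged" | "dead"
    temperature_C: Optional[float] = None
    minutes: Optional[float] = None
    thresholds: DamageThresholds = DamageThresholds()


def classify_state(
    survival: SurvivalEstimate,
    lag_shift_min: Optional[float],
    thresholds: DamageThresholds = DamageThresholds(),
) -> str:
    """dead if the treated well never grew; damaged if survival fell below
    ``survival_lo`` or lag extended beyond ``lag_shift_min``; else normal."""
    if survival.is_upper_bound:
        return "dead"
    if survival.value < thresholds.survival_lo:
        return "damaged"
    if lag_shift_min is not None and lag_shift_min > thresholds.lag_shift_min:
        return "damaged"
    return "normal"


def compare_treated(
    treated: GrowthFit,
    control: GrowthFit,
    duration_min: Optional[float] = None,
    thresholds: DamageThresholds = DamageThresholds(),
    temperature_C: Optional[float] = None,
    minutes: Optional[float] = None,
) -> TreatmentComparison:
    """Quantify heat injury of ``treated`` relative to ``control``.

    Survival uses the time-to-threshold ratio (control's doubling time); a
    treated well censored over the whole run is reported dead with survival
    as an upper bound.  Raises if the control itself is censored."""
    if control.crossing_min is None:
        raise UndefinedRatioError("control crossing is censored; cannot compare")
    survival = relative_survival(treated, control, duration_min=duration_min)
    if treated.crossing_min is not None:
        crossing_shift = treated.crossing_min - control.crossing_min
    else:
        crossing_shift = None
    if treated.lag_min is not None and control.lag_min is not None:
        lag_shift = treated.lag_min - control.lag_min
    else:
        lag_shift = None
    state = classify_state(survival, lag_shift, thresholds)
    return TreatmentComparison(
        survival=survival,
        crossing_shift_min=crossing_shift,
        lag_shift_min=lag_shift,
        state=state,
        temperature_C=temperature_C,
        minutes=minutes,
        thresholds=thresholds,
    )
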