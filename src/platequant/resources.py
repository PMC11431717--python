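"""Consumable and cost accounting: spread plates versus the 96-well assay.

A parameterised calculator for the classic comparison: enumerating 96
samples by spread plating consumes hundreds of dishes and litres of agar,
while one 96-well plate with 100 uL of medium per well uses 9.6 mL.  All
unit quantities and costs are inputs; the defaults mirror the standard
workflow (7 tips and 3 plated dilutions per sample, 20 mL agar per dish;
2 tips and one shared plate for the microplate route).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import DomainError


@dataclass(frozen=True)
class ProtocolSpec:
    """Per-sample consumable usage and unit costs of one workflow.

    ``vessels_per_sample`` may be fractional (one 96-well plate shared by 96
    samples is 1/96 per sample).  ``medium_uL_per_vessel`` is the medium in
    one vessel (dish or whole plate).  If ``cost_per_sample_usd`` is given
    it overrides the component-based cost."""

    name: str
    samples: int
    tips_per_sample: float
    vessels_per_sample: float
    medium_uL_per_vessel: float
    cost_per_tip: float = 0.0
    cost_per_vessel: float = 0.0
    cost_per_mL_medium: float = 0.0
    cost_per_sample_usd: Optional[float] = None

    def __post_init__(self):
        numeric = (
            self.samples,
            self.tips_per_sample,
            self.vessels_per_sample,
            self.medium_uL_per_vessel,
            self.cost_per_tip,
            self.cost_per_vessel,
            self.cost_per_mL_medium,
        )
        if any(v < 0 for v in numeric):
            raise DomainError("protocol quantities must be non-negative")

    @property
    def tips_total(self) -> float:
        return self.tips_per_sample * self.samples

    @property
    def vessels_total(self) -> float:
        return self.vessels_per_sample * self.samples

    @property
    def medium_total_mL(self) -> float:
        return self.vessels_total * self.medium_uL_per_vessel / 1000.0

    @property
    def cost_per_sample(self) -> float:
        if self.cost_per_sample_usd is not None:
            return self.cost_per_sample_usd
        per_sample = (
            self.tips_per_sample * self.cost_per_tip
            + self.vessels_per_sample * self.cost_per_vessel
            + self.vessels_per_sample
            * self.medium_uL_per_vessel
            / 1000.0
            * self.cost_per_mL_medium
        )
        return per_sample


def spread_plate_default(samples: int = 96) -> ProtocolSpec:
    """Classical workflow: 7 tips/sample, 3 plated dilutions per sample
    (288 dishes for 96 samples), 20 mL agar per dish, US$0.9/sample."""
    return ProtocolSpec(
        name="spread-plate",
        samples=samples,
        tips_per_sample=7,
        vessels_per_sample=3,
        medium_uL_per_vessel=20_000.0,
        cost_per_sample_usd=0.9,
    )


def high_throughput_default(samples: int = 96) -> ProtocolSpec:
    """Microplate workflow: 2 tips/sample, one 96-well plate per 96 samples,
    100 uL medium per well (9.6 mL per plate), US$0.08/sample."""
    return ProtocolSpec(
        name="high-throughput",
        samples=samples,
        tips_per_sample=2,
        vessels_per_sample=1.0 / 96.0,
        medium_uL_per_vessel=96 * 100.0,
        cost_per_sample_usd=0.08,
    )


def _ratio(a: float, b: float) -> Optional[float]:
    return a / b if b else None


def compare_protocols(spread: ProtocolSpec, hts: ProtocolSpec) -> dict:
    """Totals and spread/high-throughput ratios for tips, vessels, medium
    and cost.  Pure arithmetic; totals are linear in sample count and the
    ratios are invariant to rescaling the currency unit."""
    if spread.samples != hts.samples:
        raise DomainError(
            f"sample counts differ: {spread.samples} vs {hts.samples}"
        )
    rows = {}
    for spec in (spread, hts):
        rows[spec.name] = {
            "samples": spec.samples,
            "tips_total": spec.tips_total,
            "vessels_total": spec.vessels_total,
            "medium_total_mL": spec.medium_total_mL,
            "cost_per_sample": spec.cost_per_sample,
            "cost_total": spec.cost_per_sample * spec.samples,
        }
    s, h = rows[spread.name], rows[hts.name]
    rows["ratios"] = {
        "tips": _ratio(s["tips_total"], h["tips_total"]),
        "vessels": _ratio(s["vessels_total"], h["vessels_total"]),
        "medium": _ratio(s["medium_total_mL"], h["medium_total_mL"]),
        "cost_per_sample": _ratio(s["cost_per_sample"], h["cost_per_sample"]),
    }
    return rows
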