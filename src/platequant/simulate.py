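"""Synthetic plate runs with known ground truth.

The generative model is the minimal one reproducing the assay's curve
shapes: a Poisson-seeded inoculum of N0 cells per well sits at N0 through a
lag phase, then grows logistically,

    N(t) = K / (1 + (K/N0 - 1) * exp(-mu (t - lag))),   mu = ln2 / Td,

with K = carrying_capacity_od / od_per_cell.  The reader signal is
OD(t) = background + od_per_cell * N(t), each reading multiplied by
lognormal noise of coefficient of variation ``noise_cv`` (reader noise
scales with signal).  A key consequence used throughout: logistic curves
sharing K and mu but differing in N0 are exact time-translates, so threshold
crossings shift by Td per missing doubling.

All generative constants are configuration, not measurements; the strain
presets carry the assay's real detection thresholds (0.3 / 0.15 OD) but
their doubling times and lags are synthetic test defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .io_plate import LayoutEntry, PlateLayout, PlateRun, WellSeries, well_names


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one strain/condition.

    Units: minutes for times, OD units for optical densities;
    ``od_per_cell`` is the OD contribution of one cell in a well (default
    3e-8, so ~1e7 cells read ~0.3 above background)."""

    doubling_time_min: float = 25.0
    lag_min: float = 60.0
    carrying_capacity_od: float = 1.0
    od_per_cell: float = 3e-8
    background_od: float = 0.05
    noise_cv: float = 0.01
    interval_min: float = 5.0
    duration_min: float = 1440.0
    threshold_od: float = 0.3

    def __post_init__(self):
        if self.doubling_time_min <= 0 or self.carrying_capacity_od <= 0:
            raise DomainError("doubling time and carrying capacity must be positive")
        if self.od_per_cell <= 0 or self.interval_min <= 0:
            raise DomainError("od_per_cell and interval_min must be positive")
        if self.lag_min < 0 or self.noise_cv < 0 or self.background_od < 0:
            raise DomainError("lag, noise_cv and background must be >= 0")
        if self.duration_min < self.interval_min:
            raise DomainError("duration must cover at least one interval")

    @property
    def carrying_capacity_cells(self) -> float:
        return self.carrying_capacity_od / self.od_per_cell


_PRESETS = {
    "BY4742-like": SimParams(doubling_time_min=90.0, lag_min=120.0, threshold_od=0.3),
    "OP50-like": SimParams(doubling_time_min=25.0, lag_min=60.0, threshold_od=0.3),
    "LGG-like": SimParams(doubling_time_min=60.0, lag_min=90.0, threshold_od=0.15),
}


def strain_preset(name: str) -> SimParams:
    """Named parameter presets.  Thresholds are the assay's published
    per-strain OD cutoffs; doubling times and lags (90/25/60 min and
    120/60/90 min) are synthetic defaults for testing."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise DomainError(
            f"unknown preset {name!r}; available: " + ", ".join(sorted(_PRESETS))
        ) from None


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def cell_count(params: SimParams, n0: float, t: np.ndarray) -> np.ndarray:
    """Deterministic N(t) for the lagged-logistic model (n0 may be 0)."""
    n = np.full_like(t, float(n0), dtype=float)
    if n0 <= 0:
        return np.zeros_like(t, dtype=float)
    k = params.carrying_capacity_cells
    mu = math.log(2.0) / params.doubling_time_min
    grow = t > params.lag_min
    c = k / n0 - 1.0
    n[grow] = k / (1.0 + c * np.exp(-mu * (t[grow] - params.lag_min)))
    return n


def simulate_well(
    params: SimParams,
    n0: int,
    seed: int | np.random.Generator = 0,
    well_id: str = "A1",
) -> WellSeries:
    """One well's OD series for an inoculum of ``n0`` cells.

    n0 = 0 yields flat background (plus noise).  Reproducible: the same
    params, n0 and seed give bit-identical output."""
    if n0 < 0:
        raise DomainError("n0 must be >= 0")
    rng = _rng(seed)
    t = np.arange(0.0, params.duration_min + 1e-9, params.interval_min)
    od = params.background_od + params.od_per_cell * cell_count(params, n0, t)
    if params.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + params.noise_cv**2))
        od = od * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=len(t))
    return WellSeries(well_id, t, od)


def _seed_counts(
    rng: np.random.Generator, lam: float, size: int, poisson_seeding: bool
) -> np.ndarray:
    if poisson_seeding:
        return rng.poisson(lam, size=size)
    return np.full(size, int(round(lam)), dtype=int)


def simulate_dilution_series(
    params: SimParams,
    stock_cfu_per_ml: float,
    exponents: Sequence[int],
    replicates: int = 6,
    inoculum_volume_uL: float = 5.0,
    seed: int = 0,
    sample_id: str = "S",
    poisson_seeding: bool = True,
) -> tuple[PlateRun, PlateLayout, pd.DataFrame]:
    """A ten-fold dilution ladder with ground truth.

    Each well at exponent e is seeded with
    Poisson(stock * 10**e * inoculum_volume_uL / 1000) cells (or exactly the
    rounded expectation when ``poisson_seeding`` is off, for deterministic
    recovery tests).  Returns the run, a matching layout, and a truth table
    with one row per well (well, exponent, replicate, lambda, n0, stock)."""
    if any(e > 0 for e in exponents):
        raise DomainError("dilution exponents must be <= 0")
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    rng = _rng(seed)
    names = well_names(len(exponents) * replicates)
    wells, entries, truth_rows = {}, {}, []
    i = 0
    for exp in exponents:
        lam = stock_cfu_per_ml * 10.0**exp * inoculum_volume_uL / 1000.0
        n0s = _seed_counts(rng, lam, replicates, poisson_seeding)
        for rep in range(replicates):
            wid = names[i]
            i += 1
            wells[wid] = simulate_well(params, int(n0s[rep]), rng, wid)
            entries[wid] = LayoutEntry(
                well=wid,
                sample_id=sample_id,
                dilution_exponent=exp,
                replicate=rep,
                role="sample",
                inoculum_volume_uL=inoculum_volume_uL,
            )
            truth_rows.append(
                {
                    "well": wid,
                    "sample_id": sample_id,
                    "dilution_exponent": exp,
                    "replicate": rep,
                    "lambda_mean": lam,
                    "n0_cells": int(n0s[rep]),
                    "stock_cfu_per_ml": stock_cfu_per_ml,
                    "treatment": "none",
                }
            )
    run = PlateRun(wells, temperature_C=30.0)
    return run, PlateLayout(entries), pd.DataFrame(truth_rows)


def simulate_heat_treatment(
    params: SimParams,
    stock_cfu_per_ml: float,
    kill_fraction: float,
    lag_extension_min: float,
    replicates: int = 6,
    inoculum_volume_uL: float = 5.0,
    seed: int = 0,
    dilution_exponent: int = 0,
) -> tuple[PlateRun, PlateLayout, pd.DataFrame]:
    """Control and heat-treated wells side by side.

    Treated inocula are thinned binomially by (1 - kill_fraction) and the
    survivors' lag is extended by ``lag_extension_min`` (injury shows as
    both fewer founders and slower start).  Truth records pre- and
    post-treatment counts."""
    if not 0.0 <= kill_fraction <= 1.0:
        raise DomainError("kill_fraction must be in [0, 1]")
    rng = _rng(seed)
    lam = stock_cfu_per_ml * 10.0**dilution_exponent * inoculum_volume_uL / 1000.0
    names = well_names(2 * replicates)
    treated_params = replace(params, lag_min=params.lag_min + lag_extension_min)
    wells, entries, truth_rows = {}, {}, []
    for rep in range(replicates):
        for cond, p in (("control", params), ("treated", treated_params)):
            wid = names[len(truth_rows)]
            n_seeded = int(rng.poisson(lam))
            n0 = n_seeded
            if cond == "treated":
                n0 = int(rng.binomial(n_seeded, 1.0 - kill_fraction))
            wells[wid] = simulate_well(p, n0, rng, wid)
            entries[wid] = LayoutEntry(
                well=wid,
                sample_id=cond,
                dilution_exponent=dilution_exponent,
                replicate=rep,
                role="sample",
                inoculum_volume_uL=inoculum_volume_uL,
            )
            truth_rows.append(
                {
                    "well": wid,
                    "sample_id": cond,
                    "dilution_exponent": dilution_exponent,
                    "replicate": rep,
                    "lambda_mean": lam,
                    "n_seeded_cells": n_seeded,
                    "n0_cells": n0,
                    "stock_cfu_per_ml": stock_cfu_per_ml,
                    "treatment": cond,
                }
            )
    run = PlateRun(wells, temperature_C=30.0)
    return run, PlateLayout(entries), pd.DataFrame(truth_rows)
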