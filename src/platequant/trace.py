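"""Limiting-dilution and grid-occupancy statistics for trace samples.

When a dilution carries on the order of one cell per inoculum, the number of
cells per well (or colonies per grid sector) is governed by counting
statistics: placing n items independently and uniformly over s sectors gives
each sector a Binomial(n, 1/s) occupancy, well approximated by
Poisson(lambda = n/s) once s is large.  The classic limiting-dilution (MPN)
estimator inverts the sterile fraction: lambda = -ln P(0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError


@dataclass
class OccupancyModel:
    """Occupancy distribution of ``n_items`` over ``n_sectors``."""

    n_items: int
    n_sectors: int

    def __post_init__(self):
        if self.n_sectors < 1:
            raise DomainError("n_sectors must be >= 1")
        if self.n_items < 0:
            raise DomainError("n_items must be >= 0")

    @property
    def lambda_mean(self) -> float:
        return self.n_items / self.n_sectors

    def binomial_pmf(self, k) -> np.ndarray | float:
        """Exact probability that one sector holds exactly k items."""
        return stats.binom.pmf(k, self.n_items, 1.0 / self.n_sectors)

    def poisson_pmf(self, k) -> np.ndarray | float:
        return stats.poisson.pmf(k, self.lambda_mean)


@dataclass
class OccupancyFraction:
    binomial: float
    poisson: float


def occupancy_fraction(n_items: int, n_sectors: int, k: int) -> OccupancyFraction:
    """Probability that a given sector holds exactly ``k`` of ``n_items``
    placed independently and uniformly over ``n_sectors``.

    The exact model is Binomial(n_items, 1/n_sectors); the Poisson
    approximation at lambda = n_items/n_sectors is returned alongside.
    ``k > n_items`` yields probability 0 (not an error)."""
    model = OccupancyModel(n_items, n_sectors)
    if k < 0:
        raise DomainError("k must be >= 0")
    if k > n_items:
        return OccupancyFraction(0.0, float(model.poisson_pmf(k)))
    return OccupancyFraction(float(model.binomial_pmf(k)), float(model.poisson_pmf(k)))


def simulate_occupancy(
    n_items: int,
    n_sectors: int,
    reps: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Monte-Carlo occupancy pmf: drop ``n_items`` uniformly over
    ``n_sectors``, ``reps`` times, and return the empirical distribution of
    per-sector counts (index k = fraction of sectors holding k items).

    Reproducible under a fixed seed; agrees with :func:`occupancy_fraction`
    within sampling error."""
    if reps < 1:
        raise DomainError("reps must be >= 1")
    model = OccupancyModel(n_items, n_sectors)  # validates arguments
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_items == 0:
        pmf = np.zeros(1)
        pmf[0] = 1.0
        return pmf
    p = np.full(n_sectors, 1.0 / n_sectors)
    counts = rng.multinomial(n_items, p, size=reps)  # reps x sectors
    hist = np.bincount(counts.ravel(), minlength=n_items + 1)
    return hist / (reps * n_sectors)


def lambda_from_sterile_fraction(p0: float) -> float:
    """Limiting-dilution estimate of mean cells per well from the fraction
    of wells showing no growth: lambda = -ln(p0)."""
    if not 0.0 < p0 < 1.0:
        raise DomainError(
            "sterile fraction must lie strictly between 0 and 1: with all "
            "wells sterile (or none) the mean is unbounded — dilute less "
            "(or more) and repeat"
        )
    return -math.log(p0)


def detectable_decades(n_min_per_well: float, max_decades: int = 8) -> int:
    """Number of consecutive ten-fold dilutions, starting at the reference,
    whose expected cells per well stay >= 1; capped at ``max_decades``.

    This is the counting-statistics floor of the dynamic range: a decade
    whose wells expect less than one cell cannot be enumerated reliably."""
    if n_min_per_well < 1:
        return 0
    d = 0
    expected = float(n_min_per_well)
    while expected >= 1.0 and d < max_decades:
        d += 1
        expected /= 10.0
    return d
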