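"""Synthetic gridded population and baseline NCD+LRI mortality rates.

Emulates the statistical structure of gridded-population and burden-of-disease
inputs: 12 adult age groups (25–29 … 75–79, 80+), per-cell populations that
conserve the requested total, and baseline mortality rates that increase
strictly with age group everywhere (a common per-cell factor scales a fixed
age profile, so the ordering is preserved cell by cell).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DomainGrid

AGE_GROUPS: tuple[str, ...] = (
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)

#: Fraction of the adult population in each age group (sums to 1).
_AGE_FRACTIONS = np.array(
    [0.095, 0.095, 0.10, 0.105, 0.105, 0.10, 0.095, 0.085, 0.075, 0.06, 0.05, 0.035]
)
_AGE_FRACTIONS = _AGE_FRACTIONS / _AGE_FRACTIONS.sum()

#: Baseline NCD+LRI mortality rate per person per year by age group
#: (synthetic, monotone increasing with age).
_BASE_RATES = np.array(
    [0.0008, 0.0011, 0.0016, 0.0024, 0.0037, 0.0058,
     0.0092, 0.0146, 0.0235, 0.0385, 0.0650, 0.1400]
)


@dataclass
class AgeStructure:
    """Per-cell, per-age-group population counts and baseline mortality rates."""

    age_groups: tuple[str, ...]
    pop: np.ndarray        # (n_age, lat, lon), persons
    base_rate: np.ndarray  # (n_age, lat, lon), deaths per person per year

    def __post_init__(self) -> None:
        if np.any(self.pop < 0) or np.any(self.base_rate < 0):
            raise ValueError("population and baseline rates must be non-negative")
        if self.pop.shape != self.base_rate.shape:
            raise ValueError("pop and base_rate must share a shape")

    @property
    def n_age(self) -> int:
        return len(self.age_groups)

    @property
    def total_pop(self) -> float:
        return float(self.pop.sum())


def generate_population_mortality(
    grid: DomainGrid,
    total_pop: float = 4.5e8,
    seed: int = 0,
    spatial_sigma: float = 0.9,
    rate_sigma: float = 0.15,
) -> AgeStructure:
    """Synthesize an AgeStructure on the grid, conserving ``total_pop`` exactly."""
    if total_pop <= 0:
        raise ValueError("total_pop must be positive")
    rng = np.random.default_rng(seed)
    n_lat, n_lon = grid.shape

    density = rng.lognormal(mean=0.0, sigma=spatial_sigma, size=(n_lat, n_lon))
    density *= total_pop / density.sum()
    pop = _AGE_FRACTIONS[:, None, None] * density

    cell_factor = rng.lognormal(mean=-rate_sigma**2 / 2, sigma=rate_sigma, size=(n_lat, n_lon))
    base_rate = _BASE_RATES[:, None, None] * cell_factor

    return AgeStructure(age_groups=AGE_GROUPS, pop=pop, base_rate=base_rate)
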