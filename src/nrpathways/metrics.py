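"""Exposure metrics: Nr attribution share and WHO-guideline attainment.

Guideline values follow the updated WHO air-quality guidelines: annual mean
5 µg·m⁻³, daily mean 15 µg·m⁻³.  Achievement uses the strict inequality
(annual mean < guideline).  Daily values are synthesized as log-normal
fluctuations about monthly regional means with a configurable coefficient of
variation, which exercises the daily-exceedance logic without a transport
model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .grid import DomainGrid

ANNUAL_GUIDELINE = 5.0   # µg·m⁻³
DAILY_GUIDELINE = 15.0   # µg·m⁻³


@dataclass
class AttainmentReport:
    """Guideline attainment for one region and control scenario."""

    region: str
    annual_achieving_area_frac: float
    daily_exceedance_frac: float | None = None

    def __post_init__(self) -> None:
        for v in (self.annual_achieving_area_frac, self.daily_exceedance_frac):
            if v is not None and not 0 <= v <= 1:
                raise ValueError("fractions must lie in [0, 1]")


def n_share(pm_base: np.ndarray, pm_no_nr: np.ndarray) -> np.ndarray:
    """Per-cell fraction of PM2.5 attributable to anthropogenic Nr emissions.

    (base − without-Nr) / base; regional aggregates should use the grid's
    area-weighted mean.  Non-positive base concentrations are rejected.
    """
    pm_base = np.asarray(pm_base, float)
    pm_no_nr = np.asarray(pm_no_nr, float)
    if pm_base.shape != pm_no_nr.shape:
        raise ValueError("fields must share a grid")
    if np.any(pm_base <= 0):
        raise ValueError("base PM2.5 must be positive in every cell")
    return (pm_base - pm_no_nr) / pm_base


def annual_guideline_achievement(
    annual_field: np.ndarray,
    grid: DomainGrid,
    region: str | None = None,
    guideline: float = ANNUAL_GUIDELINE,
) -> float:
    """Area-weighted fraction of region cells strictly below the annual guideline."""
    annual_field = np.asarray(annual_field, float)
    cells = grid.region_cells(region)
    if not cells.any():
        raise ValueError(f"region {region!r} selects no cells")
    w = np.where(cells, grid.cell_area, 0.0)
    return float((w * (annual_field < guideline)).sum() / w.sum())


def synthesize_daily(
    monthly_means: np.ndarray,
    cv: float = 0.35,
    days_per_month: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Daily regional-mean series around monthly means (log-normal, mean-preserving)."""
    monthly_means = np.asarray(monthly_means, float)
    if np.any(monthly_means < 0):
        raise ValueError("monthly means must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    out = []
    for m in monthly_means:
        if m == 0:
            out.append(np.zeros(days_per_month))
            continue
        mu = np.log(m) - sigma**2 / 2
        out.append(rng.lognormal(mean=mu, sigma=sigma, size=days_per_month))
    return np.concatenate(out)


def daily_exceedance_fraction(
    daily_regional_means: np.ndarray, guideline: float = DAILY_GUIDELINE
) -> float:
    """Fraction of days with regional-mean PM2.5 above the daily guideline."""
    series = np.asarray(daily_regional_means, float)
    if series.size == 0:
        raise ValueError("daily series is empty")
    return float(np.mean(series > guideline))


def required_reduction_map(
    response: Callable[[np.ndarray], np.ndarray],
    guideline: float = ANNUAL_GUIDELINE,
    tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell minimal control fraction achieving annual mean < guideline.

    ``response`` maps a control fraction (scalar or per-cell array) to the
    annual-mean field and must be monotone non-increasing in the control
    fraction.  Returns ``(required, unreachable)``: required reductions
    (NaN where unreachable, 0 where the base already achieves) found by
    bisection to ``tol``; ties at the boundary resolve to the smaller value.
    """
    f0 = np.asarray(response(0.0), float)
    f1 = np.asarray(response(1.0), float)
    if np.any(f1 > f0 + 1e-9):
        raise ValueError("response is not monotone non-increasing in the control fraction")

    achieved_at_base = f0 < guideline
    unreachable = f1 >= guideline

    lo = np.zeros_like(f0)
    hi = np.ones_like(f0)
    n_iter = int(np.ceil(np.log2(1.0 / tol)))
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        fm = np.asarray(response(mid), float)
        below = fm < guideline
        hi = np.where(below, mid, hi)
        lo = np.where(below, lo, mid)

    required = np.where(achieved_at_base, 0.0, hi)
    required = np.where(unreachable, np.nan, required)
    return required, unreachable
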