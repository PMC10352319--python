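"""Synthetic NH3/NOx emission inventories.

Spatial patterns are log-normal with a handful of hotspots, denser in the
Western region; NH3 is spatially more concentrated than NOx so that clean
cells are relatively ammonia-poor.  Domain totals are exact by construction.
Monthly time factors put the NH3 peak in spring (April) and the NOx peak in
winter (January), averaging to 1 over the four represented months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import MONTHS, DomainGrid

#: Default monthly factors per species over (Jan, Apr, Jul, Oct); each averages to 1.
DEFAULT_MONTHLY_FACTORS = {
    "NH3": np.array([0.6, 1.6, 1.1, 0.7]),
    "NOx": np.array([1.4, 1.0, 0.6, 1.0]),
}


@dataclass
class EmissionInventory:
    """Gridded annual emissions (Tg N·yr⁻¹ per cell) with monthly factors."""

    e_nh3: np.ndarray
    e_nox: np.ndarray
    monthly_factor: dict[str, np.ndarray] = field(
        default_factory=lambda: {k: v.copy() for k, v in DEFAULT_MONTHLY_FACTORS.items()}
    )
    months: tuple[str, ...] = MONTHS

    def __post_init__(self) -> None:
        for name, e in (("e_nh3", self.e_nh3), ("e_nox", self.e_nox)):
            if np.any(e < 0):
                raise ValueError(f"{name} must be non-negative")
            if e.sum() <= 0:
                raise ValueError(f"{name} domain total must be positive")
        for sp, f in self.monthly_factor.items():
            if not np.isclose(f.mean(), 1.0):
                raise ValueError(f"monthly factors for {sp} must average to 1")

    @property
    def total_nh3(self) -> float:
        return float(self.e_nh3.sum())

    @property
    def total_nox(self) -> float:
        return float(self.e_nox.sum())


def generate_emissions(
    grid: DomainGrid,
    total_nh3: float = 4.4,
    total_nox: float = 3.7,
    seed: int = 0,
    west_boost_nh3: float = 2.0,
    west_boost_nox: float = 1.8,
    nh3_concentration_exp: float = 1.8,
    sigma: float = 0.55,
    n_hotspots: int = 3,
) -> EmissionInventory:
    """Generate a reproducible synthetic inventory summing to the given totals.

    Parameters
    ----------
    total_nh3, total_nox:
        Domain totals in Tg N·yr⁻¹ (defaults are the 2015 European anthropogenic
        totals used for calibration: 4.4 and 3.7 Tg N).
    west_boost_nh3, west_boost_nox:
        Western-to-Eastern mean emission-density ratios per species; both > 1
        so the Western mean density exceeds the Eastern one for each species.
    nh3_concentration_exp:
        Exponent (> 1) applied to the shared spatial pattern for NH3 only; it
        concentrates NH3 into hotspots so the NH3/NOx ratio falls toward clean
        cells (ammonia-poor rural background, ammonia-rich source regions).
    """
    if total_nh3 <= 0 or total_nox <= 0:
        raise ValueError("emission totals must be positive")
    rng = np.random.default_rng(seed)
    n_lat, n_lon = grid.shape

    base = rng.lognormal(mean=0.0, sigma=sigma, size=(n_lat, n_lon))
    # A few smooth hotspots shared by both species.
    ii, jj = np.meshgrid(np.arange(n_lat), np.arange(n_lon), indexing="ij")
    for _ in range(n_hotspots):
        ci = rng.uniform(0, n_lat - 1)
        cj = rng.uniform(0, n_lon - 1)
        width = max(1.0, 0.12 * max(n_lat, n_lon))
        base += 2.0 * np.exp(-((ii - ci) ** 2 + (jj - cj) ** 2) / (2 * width**2))

    # Fixed regional totals: the Western share is chosen so the Western mean
    # emission density exceeds the Eastern one by the requested boost
    # regardless of where the random hotspots land.
    west = grid.region_cells("West")
    area_w = grid.cell_area[west].sum()
    area_e = grid.cell_area[~west].sum()

    def allocate(pattern: np.ndarray, total: float, boost: float) -> np.ndarray:
        share_west = boost * area_w / (boost * area_w + area_e)
        out = np.zeros_like(pattern)
        out[west] = pattern[west] / pattern[west].sum() * share_west * total
        out[~west] = pattern[~west] / pattern[~west].sum() * (1 - share_west) * total
        return out

    e_nox = allocate(base, total_nox, west_boost_nox)
    e_nh3 = allocate(base**nh3_concentration_exp, total_nh3, west_boost_nh3)
    return EmissionInventory(e_nh3=e_nh3, e_nox=e_nox)
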