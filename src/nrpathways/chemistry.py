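"""Closed-form secondary-inorganic-aerosol (SIA) equilibrium surrogate.

A full chemistry-transport model resolves SIA formation through oxidant
chemistry and thermodynamic partitioning; here the same qualitative structure
is captured in closed form so that every control state (x, y) is cheaply and
exactly evaluable:

* total ammonia availability  A  = a_tot · E_NH3 · (1 − x)
* total nitrate availability  TN = n_tot · E_NOx · (1 − y)^p_ox
* ammonia neutralizes sulfate first:  NH4(sulfate) = min(A, 2·SO4)
* remaining free ammonia FA = max(0, A − 2·SO4) combines with HNO3 into
  ammonium-nitrate aerosol:  NO3⁻ = ε · smoothmin(FA, TN)
* PM2.5 = background + 96·SO4 + 62·NO3 + 18·NH4 (molar → mass, g·mol⁻¹)

The exponent p_ox ≥ 1 encodes the diminishing marginal HNO3 response to deep
NOx cuts (oxidant feedback); ε ∈ (0, 1] is the monthly ammonium-nitrate yield
(low in warm months where little aerosol nitrate survives); the smooth-min
sharpness keeps the response surface kink-free for spline and gradient work,
with exact min available for analytic limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import MONTHS, DomainGrid
from .emissions import EmissionInventory

#: Molecular weights (g·mol⁻¹) used in the molar → µg·m⁻³ conversion.
MW_SO4 = 96.0
MW_NO3 = 62.0
MW_NH4 = 18.0

#: Default monthly ammonium-nitrate yield: suppressed in July (warm, little
#: aerosol nitrate), high in winter.
DEFAULT_EPS = {"Jan": 0.9, "Apr": 0.8, "Jul": 0.3, "Oct": 0.8}


def smoothmin(a: np.ndarray, b: np.ndarray, sharpness: float | None) -> np.ndarray:
    """Smooth lower bound of two arrays; exact ``min`` when sharpness is None/inf.

    Uses the log-sum-exp soft minimum, which never exceeds min(a, b); callers
    clip at zero so concentrations stay non-negative.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if sharpness is None or np.isinf(sharpness):
        return np.minimum(a, b)
    if sharpness <= 0:
        raise ValueError("sharpness must be positive (or None for exact min)")
    m = np.minimum(a, b)
    return m - np.log1p(np.exp(-sharpness * np.abs(a - b))) / sharpness


@dataclass
class ChemParams:
    """Parameters of the SIA equilibrium surrogate.

    a_tot / n_tot convert cell emissions (Tg N·yr⁻¹) into availabilities
    (µmol·m⁻³); s_fix is the (uncontrolled) sulfate, scalar or per-cell field;
    eps maps month → ammonium-nitrate yield; sharpness None means exact min.
    background is the non-SIA PM2.5 mass (µg·m⁻³), broadcastable to
    (month, level, lat, lon).  level_decay_* are e-folding factors per layer
    for the synthetic vertical structure.
    """

    a_tot: float = 5.0
    n_tot: float = 1.4
    p_ox: float = 2.0
    s_fix: float | np.ndarray = 0.025
    eps: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EPS))
    sharpness: float | None = 25.0
    background: float | np.ndarray = 5.0
    level_decay_nr: float = 0.6
    level_decay_so4: float = 0.3

    def __post_init__(self) -> None:
        if self.p_ox < 1:
            raise ValueError("p_ox must be >= 1")
        if np.any(np.asarray(self.s_fix) < 0):
            raise ValueError("s_fix must be >= 0")
        for m, e in self.eps.items():
            if not 0 < e <= 1:
                raise ValueError(f"eps[{m!r}] must lie in (0, 1]")

    def eps_array(self, months: tuple[str, ...] = MONTHS) -> np.ndarray:
        return np.array([self.eps[m] for m in months])


@dataclass
class SpeciesState:
    """Per-cell/month(/level) species concentrations and assembled PM2.5.

    Gas and aerosol species are molar (µmol·m⁻³); background_mass and pm25 are
    µg·m⁻³.  Arrays have shape (month, level, lat, lon).
    """

    nh3: np.ndarray
    nh4: np.ndarray
    so4: np.ndarray
    hno3: np.ndarray
    no3: np.ndarray
    background_mass: np.ndarray
    pm25: np.ndarray
    months: tuple[str, ...] = MONTHS

    def annual_mean_pm25(self, level: int = 0) -> np.ndarray:
        """Annual (4-month arithmetic) mean surface PM2.5, shape (lat, lon)."""
        return self.pm25[:, level].mean(axis=0)


def equilibrium_fields(
    inv: EmissionInventory,
    params: ChemParams,
    x: float | np.ndarray,
    y: float | np.ndarray,
    n_level: int = 1,
) -> SpeciesState:
    """Evaluate the surrogate at control fractions x (NH3) and y (NOx).

    x and y may be scalars or per-cell arrays broadcastable to (lat, lon),
    which is what per-cell required-reduction searches rely on.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any((x < 0) | (x > 1)) or np.any((y < 0) | (y > 1)):
        raise ValueError("control fractions must lie in [0, 1]")

    mf_nh3 = inv.monthly_factor["NH3"][:, None, None, None]
    mf_nox = inv.monthly_factor["NOx"][:, None, None, None]
    lev = np.arange(n_level)[None, :, None, None]
    f_nr = np.exp(-params.level_decay_nr * lev)
    f_so4 = np.exp(-params.level_decay_so4 * lev)

    A = params.a_tot * inv.e_nh3 * (1.0 - x) * mf_nh3 * f_nr
    TN = params.n_tot * inv.e_nox * (1.0 - y) ** params.p_ox * mf_nox * f_nr
    so4 = np.broadcast_to(np.asarray(params.s_fix) * f_so4, A.shape).copy()

    nh4_sulfate = np.minimum(A, 2.0 * so4)
    fa = np.maximum(0.0, A - 2.0 * so4)
    eps = params.eps_array(inv.months)[:, None, None, None]
    no3 = eps * np.maximum(0.0, smoothmin(fa, TN, params.sharpness))
    nh4 = nh4_sulfate + no3
    nh3 = A - nh4
    hno3 = TN - no3

    background = np.broadcast_to(np.asarray(params.background, dtype=float), A.shape)
    pm25 = background + MW_SO4 * so4 + MW_NO3 * no3 + MW_NH4 * nh4
    return SpeciesState(
        nh3=nh3,
        nh4=nh4,
        so4=so4,
        hno3=hno3,
        no3=no3,
        background_mass=np.array(background),
        pm25=pm25,
        months=inv.months,
    )


def generate_background(
    grid: DomainGrid,
    seed: int = 0,
    west_components: dict[str, float] | None = None,
    east_components: dict[str, float] | None = None,
    spatial_sigma: float = 0.45,
) -> np.ndarray:
    """Synthetic non-SIA PM2.5 background, shape (month, level, lat, lon).

    Composed of BC, OC, dust and sea-salt contributions plus SOA taken as
    3×OC in July and 2×OC in the other months.  The Eastern region carries a
    heavier organic background (lower Nr share of total PM2.5), the Western a
    lighter one.  Log-normal spatial variation with the given sigma.
    """
    west_components = west_components or {"bc": 0.35, "oc": 0.55, "dust": 0.45, "seasalt": 0.7}
    east_components = east_components or {"bc": 0.7, "oc": 2.1, "dust": 0.7, "seasalt": 0.3}
    rng = np.random.default_rng(seed)
    n_lat, n_lon = grid.shape
    west = grid.region_cells("West")

    def total(components: dict[str, float], month: str) -> float:
        soa_mult = 3.0 if month == "Jul" else 2.0
        return (
            components["bc"]
            + components["oc"] * (1.0 + soa_mult)
            + components["dust"]
            + components["seasalt"]
        )

    spatial = rng.lognormal(mean=-spatial_sigma**2 / 2, sigma=spatial_sigma, size=(n_lat, n_lon))
    out = np.empty((len(grid.months), grid.n_level, n_lat, n_lon))
    for mi, month in enumerate(grid.months):
        flat = np.where(west, total(west_components, month), total(east_components, month))
        out[mi] = flat * spatial  # same profile at all levels
    return out
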