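"""Chemical-regime diagnostics: the G ratio and tipping points.

G = ([NH3] + [NH4⁺] − 2·[SO4²⁻]) / ([HNO3] + [NO3⁻]) on a molar basis: the
free ammonia remaining after sulfate neutralization relative to total nitrate.
G > 1 marks an HNO3-limited regime (SIA formation more sensitive to NOx),
G < 1 an NH3-limited one; at G = 1 equal molar perturbations of the two
precursors yield similar PM2.5 changes.  The diagnostic is unreliable where
little ammonium nitrate can exist (hot, dry months — flagged via the
ammonium-nitrate yield ε).

A tipping point is the control-reduction fraction at which NH3 abatement
becomes at least as effective as NOx abatement, located by linearly
interpolating the first sign change of β_NH3 − β_NOx (or G − 1) along the
11-level control grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import SpeciesState
from .efficiency import EfficiencySeries
from .grid import DomainGrid

G_DENOMINATOR_THRESHOLD = 1e-9  # µmol·m⁻³
G_EPS_RELIABILITY = 0.05


@dataclass
class GField:
    """G ratio per cell/month/level; NaN where total nitrate vanishes."""

    g: np.ndarray
    unreliable_months: tuple[str, ...] = ()

    def regional_stats(self, grid: DomainGrid, region: str | None = None):
        """Area-weighted (mean, sd) over cells, averaged first over month/level."""
        mean = grid.area_weighted_mean(self.g, region)
        sd = grid.area_weighted_std(self.g, region)
        return mean, sd


@dataclass
class TippingPoint:
    """Control fraction at which the criterion crosses zero, if reachable."""

    reduction_frac: float | None
    criterion: str
    reachable: bool

    def __post_init__(self) -> None:
        if self.reachable and not (0 <= self.reduction_frac <= 1):
            raise ValueError("reachable tipping point must lie in [0, 1]")


def g_ratio(
    state: SpeciesState,
    threshold: float = G_DENOMINATOR_THRESHOLD,
    eps: dict[str, float] | None = None,
) -> GField:
    """Elementwise G ratio of a species state; masked (NaN) for tiny nitrate.

    If the monthly ammonium-nitrate yields ``eps`` are supplied, months with a
    yield below 0.05 are flagged unreliable (hot/dry conditions hold too little
    ammonium nitrate for the regime diagnosis to be meaningful).
    """
    denom = state.hno3 + state.no3
    num = state.nh3 + state.nh4 - 2.0 * state.so4
    g = np.where(denom > threshold, num / np.where(denom > threshold, denom, 1.0), np.nan)
    unreliable: tuple[str, ...] = ()
    if eps is not None:
        unreliable = tuple(m for m in state.months if eps.get(m, 1.0) < G_EPS_RELIABILITY)
    return GField(g=g, unreliable_months=unreliable)


def tipping_point(levels: np.ndarray, diff: np.ndarray, criterion: str) -> TippingPoint:
    """First zero crossing of ``diff`` along ``levels`` from the 0% side.

    ``diff`` is β_NH3 − β_NOx (criterion "beta_equal") or G − 1
    ("g_equal_one").  Linear interpolation between the adjacent levels;
    unreachable if no sign change on [0, 100%].
    """
    levels = np.asarray(levels, float)
    diff = np.asarray(diff, float)
    if np.any(np.isnan(diff)):
        raise ValueError("tipping-point series contains NaN")
    if diff[0] == 0.0:
        return TippingPoint(float(levels[0]), criterion, True)
    for i in range(len(diff) - 1):
        d0, d1 = diff[i], diff[i + 1]
        if d1 == 0.0:
            return TippingPoint(float(levels[i + 1]), criterion, True)
        if d0 * d1 < 0:
            frac = levels[i] + (0.0 - d0) * (levels[i + 1] - levels[i]) / (d1 - d0)
            return TippingPoint(float(frac), criterion, True)
    return TippingPoint(None, criterion, False)


def tipping_from_betas(nh3: EfficiencySeries, nox: EfficiencySeries) -> TippingPoint:
    if not np.array_equal(nh3.levels, nox.levels):
        raise ValueError("β series must share the level grid")
    return tipping_point(nh3.levels, nh3.beta - nox.beta, "beta_equal")


def tipping_from_g(levels: np.ndarray, g_along_levels: np.ndarray) -> TippingPoint:
    return tipping_point(levels, np.asarray(g_along_levels, float) - 1.0, "g_equal_one")


def per_mole_equivalence_g(
    tn_base: float = 0.05,
    s_fix: float = 0.01,
    ratios: np.ndarray | None = None,
    h: float = 1e-6,
) -> float:
    """G value at which per-mole NH3 and NOx perturbations move PM2.5 equally.

    Single-cell surrogate with exact min, ammonium-nitrate yield 1 and fully
    neutralized sulfate: sweep base free-ammonia/total-nitrate molar ratios,
    compute central finite-difference sensitivities of PM2.5 mass to the total
    ammonia availability and to the total nitrate availability (per µmol·m⁻³,
    i.e. per mole at fixed volume), and return the G ratio at which the two
    sensitivities cross.  In the ammonium-nitrate equilibrium this crossing is
    the chemical-regime boundary between HNO3-limited and NH3-limited aerosol
    formation.
    """
    from .chemistry import ChemParams, equilibrium_fields
    from .emissions import EmissionInventory

    if ratios is None:
        ratios = np.round(np.arange(0.2, 5.0 + 1e-9, 0.05), 10)
    params = ChemParams(
        a_tot=1.0,
        n_tot=1.0,
        p_ox=1.0,
        s_fix=s_fix,
        eps={m: 1.0 for m in ("Jan", "Apr", "Jul", "Oct")},
        sharpness=None,
        background=0.0,
    )

    def pm(fa: float, tn: float) -> float:
        inv = EmissionInventory(
            e_nh3=np.full((1, 1), fa + 2.0 * s_fix),
            e_nox=np.full((1, 1), tn),
            monthly_factor={"NH3": np.ones(4), "NOx": np.ones(4)},
        )
        return float(equilibrium_fields(inv, params, 0.0, 0.0).pm25[0, 0, 0, 0])

    diffs = np.empty(ratios.size)
    gs = np.empty(ratios.size)
    for i, rho in enumerate(ratios):
        fa = rho * tn_base
        s_a = (pm(fa + h, tn_base) - pm(fa - h, tn_base)) / (2 * h)
        s_tn = (pm(fa, tn_base + h) - pm(fa, tn_base - h)) / (2 * h)
        diffs[i] = s_a - s_tn
        gs[i] = fa / tn_base  # sulfate fully neutralized: G = FA / TN

    def sens_diff(rho: float) -> float:
        fa = rho * tn_base
        s_a = (pm(fa + h, tn_base) - pm(fa - h, tn_base)) / (2 * h)
        s_tn = (pm(fa, tn_base + h) - pm(fa, tn_base - h)) / (2 * h)
        return s_a - s_tn

    if diffs[0] <= 0:
        raise RuntimeError("sweep must start in the NH3-limited regime (S_A > S_TN)")
    for i in range(diffs.size - 1):
        if diffs[i + 1] == 0.0:
            return float(gs[i + 1])
        if diffs[i] * diffs[i + 1] < 0:
            # refine the bracketed sign change of the sensitivity difference
            lo, hi = float(ratios[i]), float(ratios[i + 1])
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if sens_diff(mid) > 0:
                    lo = mid
                else:
                    hi = mid
            return float(0.5 * (lo + hi))
    raise RuntimeError("no sensitivity crossing found in the swept ratio range")
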