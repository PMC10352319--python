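"""Instant efficiency β of emission controls on the 10% control-level grid.

β_LN measures the instant response of total PM2.5 mass (in percent of the
base concentration) to a 1% mass reduction in emissions, evaluated at each of
the 11 control levels L1 = 0% … L11 = 100%.  Simulated scenarios exist only
at 0/30/60/80/100%, so the 10% grid is filled by shape-preserving piecewise
cubic (PCHIP) interpolation, which cannot overshoot between knots.  The β
stencils are one-sided at the ends and centred in the interior:

    N = 1:      (ΔPM_L1 − ΔPM_L2)   / ΔEmi over the same span
    N = 2..10:  (ΔPM_L(N−1) − ΔPM_L(N+1)) / ΔEmi over the same span
    N = 11:     (ΔPM_L10 − ΔPM_L11) / ΔEmi over the same span

with ΔPM in fractions of the base PM2.5 and ΔEmi in fractions of the base
emissions (emissions are linear in the control level, so each denominator is
the 10% or 20% level gap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

LEVEL_GRID = np.round(np.linspace(0.0, 1.0, 11), 10)


@dataclass
class ResponseCurve:
    """PM2.5 and emissions along the 11-level control grid for one species mode."""

    levels: np.ndarray       # control fractions, strictly increasing
    pm_at_level: np.ndarray  # µg·m⁻³ (regional mean or per cell at one point)
    base_emi: float          # Tg N
    mode: str = "Nr"

    def __post_init__(self) -> None:
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("level grid must be strictly increasing")
        if np.any(np.diff(self.pm_at_level) > 1e-9):
            raise ValueError("pm_at_level must be non-increasing along levels")
        if self.base_emi <= 0:
            raise ValueError("base emissions must be positive")

    @property
    def base_pm(self) -> float:
        return float(self.pm_at_level[0])

    @property
    def emi_at_level(self) -> np.ndarray:
        return self.base_emi * (1.0 - self.levels)


@dataclass
class EfficiencySeries:
    """β per control level, optionally with a spatial spread."""

    levels: np.ndarray
    beta: np.ndarray  # %/% (or per-mole after molar normalisation)
    mode: str = "Nr"
    spatial_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")


def interpolate_levels(
    sim_levels: np.ndarray,
    sim_pm: np.ndarray,
    base_emi: float,
    mode: str = "Nr",
    out_levels: np.ndarray = LEVEL_GRID,
) -> ResponseCurve:
    """Shape-preserving interpolation of simulated PM2.5 onto the 10% grid.

    Requires at least four distinct sorted levels including 0; knot values are
    reproduced exactly.
    """
    sim_levels = np.asarray(sim_levels, float)
    sim_pm = np.asarray(sim_pm, float)
    if sim_levels.size < 4:
        raise ValueError("need at least 4 simulated control levels")
    if np.any(np.diff(sim_levels) <= 0):
        raise ValueError("simulated levels must be sorted and distinct")
    if sim_levels[0] != 0.0:
        raise ValueError("simulated levels must include the base (0)")
    interp = PchipInterpolator(sim_levels, sim_pm)
    out_levels = np.asarray(out_levels, float)
    pm = interp(out_levels)
    # exact at knots (guard against round-off on the shared grid points)
    for l, v in zip(sim_levels, sim_pm):
        hit = np.isclose(out_levels, l)
        pm[hit] = v
    return ResponseCurve(levels=out_levels, pm_at_level=pm, base_emi=base_emi, mode=mode)


def instant_efficiency(curve: ResponseCurve) -> EfficiencySeries:
    """β per level from the forward/centred/backward stencils."""
    pm = curve.pm_at_level
    levels = curve.levels
    base_pm = curve.base_pm
    emi = curve.emi_at_level
    base_emi = curve.base_emi
    if base_pm <= 0:
        raise ValueError("base PM2.5 must be positive")

    n = levels.size
    beta = np.empty(n)
    for i in range(n):
        if i == 0:
            j, k = 0, 1
        elif i == n - 1:
            j, k = n - 2, n - 1
        else:
            j, k = i - 1, i + 1
        dpm = (pm[k] - pm[j]) / base_pm
        demi = (emi[k] - emi[j]) / base_emi
        if demi == 0:
            raise ValueError("zero emission denominator in β stencil")
        beta[i] = dpm / demi
    return EfficiencySeries(levels=levels, beta=beta, mode=curve.mode)


def molar_normalize(series: EfficiencySeries, emi_total_mol: float) -> EfficiencySeries:
    """Re-express β per mole of N removed: β_molar = β / (total emission in mol N).

    Cross-species comparison of the molar series locates the point where equal
    molar perturbations of the two precursors give equal PM2.5 changes.
    """
    if emi_total_mol <= 0:
        raise ValueError("molar emission total must be positive")
    return EfficiencySeries(
        levels=series.levels,
        beta=series.beta / emi_total_mol,
        mode=series.mode,
        spatial_sd=None if series.spatial_sd is None else series.spatial_sd / emi_total_mol,
    )
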