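"""National-level NH3/NOx abatement cost curves.

Each (species, region) curve interpolates a small set of anchor scenarios
(reduction fraction, annual cost in billion €·yr⁻¹) with a monotone
shape-preserving cubic (PCHIP) and extrapolates linearly at the last chord
slope up to the 50% cap — cost data beyond 50% reductions are not considered
reliable, so curves refuse evaluation there.

Default anchors are calibrated so that within each region NH3 abatement is far
cheaper than NOx at equal reduction, matching published European GAINS-style
estimates (10% / 30% NH3: 0.08 / 1.1 B€; 10% / 30% NOx: 1.1 / 12.7 B€ in the
Western region; Eastern anchors pinned to the 31% → 0.2 B€ and 32% → 1.9 B€
feasibility points with matching curvature).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

MAX_REDUCTION = 0.5

SPECIES = ("NH3", "NOx")
REGIONS = ("West", "East")


@dataclass(frozen=True)
class CostScenario:
    """One anchor: annual cost of reducing a species by a fraction in a region."""

    species: str
    region: str
    reduction: float
    annual_cost: float  # billion €·yr⁻¹

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")
        if not 0 <= self.reduction <= MAX_REDUCTION:
            raise ValueError(f"reduction must lie in [0, {MAX_REDUCTION}]")
        if self.annual_cost < 0:
            raise ValueError("annual_cost must be >= 0")


#: Default anchors per (species, region): (reduction, billion €·yr⁻¹).
DEFAULT_COST_ANCHORS: dict[tuple[str, str], tuple[tuple[float, float], ...]] = {
    ("NH3", "West"): ((0.0, 0.0), (0.10, 0.08), (0.30, 1.1)),
    ("NOx", "West"): ((0.0, 0.0), (0.10, 1.1), (0.30, 12.7)),
    ("NH3", "East"): ((0.0, 0.0), (0.10, 0.0134), (0.31, 0.2)),
    ("NOx", "East"): ((0.0, 0.0), (0.10, 0.1424), (0.32, 1.9)),
}


class CostCurve:
    """Monotone convex cost(reduction) on [0, 0.5] through anchor points."""

    def __init__(self, anchors):
        anchors = sorted((float(r), float(c)) for r, c in anchors)
        r = np.array([a[0] for a in anchors])
        c = np.array([a[1] for a in anchors])
        if r[0] != 0.0 or c[0] != 0.0:
            raise ValueError("anchors must include the zero-cost origin (0, 0)")
        if np.any(np.diff(r) <= 0):
            raise ValueError("anchor reductions must be strictly increasing")
        if np.any(np.diff(c) <= 0):
            raise ValueError("anchor costs must be strictly increasing")
        slopes = np.diff(c) / np.diff(r)
        if np.any(np.diff(slopes) < -1e-9):
            raise ValueError("anchor chords must be convex (non-decreasing slopes)")
        if r[-1] > MAX_REDUCTION:
            raise ValueError(f"anchors beyond the {MAX_REDUCTION:.0%} cap")
        self.anchors = anchors
        self._interp = PchipInterpolator(r, c)
        # C1 linear extension beyond the last anchor: continuing at the spline's
        # end derivative keeps the curve smooth and (for convex anchors) convex,
        # and stays deliberately mild — cost data beyond the anchors are an
        # extrapolation, not an estimate.
        self._r_last = float(r[-1])
        self._c_last = float(c[-1])
        self._end_slope = float(self._interp.derivative()(r[-1]))

    def __call__(self, reduction):
        reduction = np.asarray(reduction, dtype=float)
        if np.any(reduction < 0) or np.any(reduction > MAX_REDUCTION + 1e-12):
            raise ValueError(
                f"cost curves are defined on [0, {MAX_REDUCTION}]; got values outside"
            )
        inside = self._interp(np.minimum(reduction, self._r_last))
        out = np.where(
            reduction <= self._r_last,
            inside,
            self._c_last + self._end_slope * (reduction - self._r_last),
        )
        return float(out) if out.ndim == 0 else out


def generate_cost_curves(
    anchors: list[CostScenario] | None = None,
    n_scenarios: int = 5,
) -> dict[tuple[str, str], CostCurve]:
    """Build CostCurves per (species, region) from anchor scenarios.

    With ``anchors=None`` the default calibrated anchor table is used.  A
    zero-cost origin is implied per curve if not supplied.  ``n_scenarios``
    feasible scenarios are tabulated along each curve and attached as
    ``curve.scenarios`` for reporting.
    """
    table: dict[tuple[str, str], list[tuple[float, float]]] = {}
    if anchors is None:
        for key, pts in DEFAULT_COST_ANCHORS.items():
            table[key] = list(pts)
    else:
        for a in anchors:
            table.setdefault((a.species, a.region), []).append((a.reduction, a.annual_cost))
        for key, pts in table.items():
            if not any(r == 0.0 for r, _ in pts):
                pts.append((0.0, 0.0))

    curves: dict[tuple[str, str], CostCurve] = {}
    for key, pts in table.items():
        curve = CostCurve(pts)
        grid = np.linspace(0, MAX_REDUCTION, n_scenarios + 1)[1:]
        curve.scenarios = [
            CostScenario(key[0], key[1], float(r), float(curve(r))) for r in grid
        ]
        curves[key] = curve
    return curves
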