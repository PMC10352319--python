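"""Emission-control scenario specifications and the 13-member ensemble.

The ensemble mirrors the classic sensitivity design: a Base run plus joint
(Nr), NOx-only and NH3-only reductions at 30/60/80/100%, i.e. 1 + 3·4 = 13
members lying on the two axes and the diagonal of the (x, y) control plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemistry import ChemParams, SpeciesState, equilibrium_fields
from .emissions import EmissionInventory

DEFAULT_LEVELS: tuple[float, ...] = (0.3, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class ScenarioSpec:
    """A control state: fractions of NH3 (x) and NOx (y) emissions removed."""

    x: float
    y: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.x <= 1 and 0 <= self.y <= 1):
            raise ValueError(f"control fractions must lie in [0, 1]: {self}")

    # label is descriptive only; identity is the control coordinates
    def __eq__(self, other) -> bool:
        if not isinstance(other, ScenarioSpec):
            return NotImplemented
        return (self.x, self.y) == (other.x, other.y)

    def __hash__(self) -> int:
        return hash((self.x, self.y))


BASE = ScenarioSpec(0.0, 0.0, "Base")


def default_scenario_specs(levels: tuple[float, ...] = DEFAULT_LEVELS) -> list[ScenarioSpec]:
    """Base + joint / NOx-only / NH3-only members at each level."""
    specs = [BASE]
    for l in levels:
        pct = int(round(100 * l))
        specs.append(ScenarioSpec(l, l, f"S1R{pct}"))
    for l in levels:
        pct = int(round(100 * l))
        specs.append(ScenarioSpec(0.0, l, f"S2R{pct}"))
    for l in levels:
        pct = int(round(100 * l))
        specs.append(ScenarioSpec(l, 0.0, f"S3R{pct}"))
    return specs


def sia_equilibrium(
    inv: EmissionInventory, spec: ScenarioSpec, params: ChemParams, n_level: int = 1
) -> SpeciesState:
    """Species state of a single control scenario."""
    return equilibrium_fields(inv, params, spec.x, spec.y, n_level=n_level)


def generate_scenario_ensemble(
    inv: EmissionInventory,
    params: ChemParams,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    n_level: int = 1,
) -> dict[ScenarioSpec, SpeciesState]:
    """Evaluate the surrogate for the full scenario set (13 members by default)."""
    for l in levels:
        if not 0 < l <= 1:
            raise ValueError(f"levels must lie in (0, 1], got {l}")
    specs = default_scenario_specs(tuple(levels))
    if len(set(specs)) != len(specs):
        raise ValueError("duplicate scenario specs in level list")
    return {spec: sia_equilibrium(inv, spec, params, n_level=n_level) for spec in specs}


def control_response(
    inv: EmissionInventory,
    params: ChemParams,
    mode: str = "Nr",
):
    """Callable control-fraction → annual-mean surface PM2.5 field.

    ``mode`` selects which species the control applies to: "Nr" (joint),
    "NOx" or "NH3".  The returned callable accepts a scalar or a per-cell
    array of control fractions, which is what bisection searches exploit.
    """
    if mode not in ("Nr", "NOx", "NH3"):
        raise ValueError(f"mode must be Nr, NOx or NH3, got {mode!r}")

    def response(frac):
        frac = np.asarray(frac, dtype=float)
        x = frac if mode in ("Nr", "NH3") else 0.0
        y = frac if mode in ("Nr", "NOx") else 0.0
        return equilibrium_fields(inv, params, x, y).annual_mean_pm25()

    return response
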