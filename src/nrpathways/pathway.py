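"""The diagnostic diagram: response surfaces, gradients and optimal pathways.

The control plane has NH3 reduction on the x-axis and NOx reduction on the
y-axis.  Thirteen simulated scenarios lie on the two axes and the diagonal;
the full surface is reconstructed by shape-preserving 1-D splines along each
of the three rays combined with a transfinite between-ray interpolation: each
off-ray point lies in the triangle bounded by one axis and the diagonal, and
the surface blends linearly between the two enclosing rays at the dominant
control level,

    F(x, y) = (1 − y/x) · f_x(x) + (y/x) · f_d(x)    for x ≥ y
    F(x, y) = (1 − x/y) · f_y(y) + (x/y) · f_d(y)    for y ≥ x.

The scheme is exact on all three rays, continuous across the diagonal, and —
because the joint-control ray always lies at or below the single-species
rays — non-increasing along the blend direction; the result is additionally
clipped to be monotone non-increasing in both controls.

Pathways are greedy walks on the surface lattice: the PM2.5-optimal path
follows the steepest decline per control step (the discrete analogue of
following the isopleth gradient ∇PM2.5 = β_NH3·i + β_NOx·j), the
cost-optimal path picks the move with the lowest incremental cost per unit
PM2.5 abated, within the 50% cap where cost data exist.  Exhaustive
monotone-lattice-path enumeration is provided as an oracle: greedy descent is
not globally optimal for every monotone surface, and the gap against the
enumerated optimum is measured, not hidden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.interpolate import PchipInterpolator

from .costs import MAX_REDUCTION, CostCurve
from .scenarios import ScenarioSpec


@dataclass
class ResponseSurface:
    """A scalar field over the (x, y) control plane on a regular grid.

    ``value[ix, iy]`` pairs with ``x_grid[ix]`` and ``y_grid[iy]``.
    """

    x_grid: np.ndarray
    y_grid: np.ndarray
    value: np.ndarray
    kind: str = "pm25"  # or "cost", "cost_per_abatement"
    provenance: str = "interpolated_from_13"

    def __post_init__(self) -> None:
        if self.value.shape != (self.x_grid.size, self.y_grid.size):
            raise ValueError("value shape must be (len(x_grid), len(y_grid))")

    def at(self, x: float, y: float) -> float:
        ix = int(np.argmin(np.abs(self.x_grid - x)))
        iy = int(np.argmin(np.abs(self.y_grid - y)))
        if not (np.isclose(self.x_grid[ix], x) and np.isclose(self.y_grid[iy], y)):
            raise ValueError(f"({x}, {y}) is not a grid node")
        return float(self.value[ix, iy])


@dataclass
class GradientField:
    """∂/∂x and ∂/∂y of a surface at each node (β_NH3 and β_NOx components).

    Sign convention: derivatives of the raw surface, so both components are
    <= 0 for a monotone non-increasing PM2.5 surface.
    """

    gx: np.ndarray
    gy: np.ndarray


@dataclass
class Pathway:
    """Ordered control states from (0, 0) with cumulative abatement/cost."""

    nodes: list[tuple[float, float]]
    cumulative_abatement: list[float]
    cumulative_cost: list[float] | None = None

    def __post_init__(self) -> None:
        xs = [n[0] for n in self.nodes]
        ys = [n[1] for n in self.nodes]
        if self.nodes[0] != (0.0, 0.0):
            raise ValueError("pathways start at (0, 0)")
        if np.any(np.diff(xs) < 0) or np.any(np.diff(ys) < 0):
            raise ValueError("pathway coordinates must be monotone non-decreasing")


def _classify_specs(values: dict[ScenarioSpec, float]):
    base = None
    on_x, on_y, on_d = {}, {}, {}
    for spec, v in values.items():
        if spec.x == 0 and spec.y == 0:
            base = float(v)
        elif spec.y == 0:
            on_x[spec.x] = float(v)
        elif spec.x == 0:
            on_y[spec.y] = float(v)
        elif np.isclose(spec.x, spec.y):
            on_d[spec.x] = float(v)
        else:
            raise ValueError(
                f"scenario ({spec.x}, {spec.y}) lies off the two axes and the diagonal"
            )
    if base is None:
        raise ValueError("the Base scenario (0, 0) is required")
    return base, on_x, on_y, on_d


def fit_response_surface(
    values: dict[ScenarioSpec, float],
    grid_step: float = 0.1,
    monotone_clip: bool = True,
) -> ResponseSurface:
    """Reconstruct the regional-mean PM2.5 surface from the 13 scenario values."""
    base, on_x, on_y, on_d = _classify_specs(values)

    def ray_spline(points: dict[float, float]) -> PchipInterpolator:
        ls = np.array([0.0] + sorted(points))
        vs = np.array([base] + [points[l] for l in sorted(points)])
        return PchipInterpolator(ls, vs)

    fx, fy, fd = ray_spline(on_x), ray_spline(on_y), ray_spline(on_d)

    n = int(round(1.0 / grid_step)) + 1
    g = np.linspace(0.0, 1.0, n)
    X, Y = np.meshgrid(g, g, indexing="ij")
    t = np.maximum(X, Y)  # dominant control level
    w = np.divide(np.minimum(X, Y), t, out=np.zeros_like(X), where=t > 0)
    lower = (1.0 - w) * fx(t) + w * fd(t)  # x >= y: between NH3-only ray and diagonal
    upper = (1.0 - w) * fy(t) + w * fd(t)  # y >= x: between NOx-only ray and diagonal
    F = np.where(X >= Y, lower, upper)

    if monotone_clip:
        F = np.minimum.accumulate(F, axis=0)
        F = np.minimum.accumulate(F, axis=1)
    return ResponseSurface(x_grid=g, y_grid=g, value=F)


def gradient_field(surface: ResponseSurface) -> GradientField:
    """Centred differences in the interior, one-sided at the edges."""
    if surface.x_grid.size < 2 or surface.y_grid.size < 2:
        raise ValueError("surface grid is degenerate")
    gx, gy = np.gradient(surface.value, surface.x_grid, surface.y_grid)
    return GradientField(gx=gx, gy=gy)


def _step_stride(grid: np.ndarray, step: float) -> int:
    dx = grid[1] - grid[0]
    stride = step / dx
    if not np.isclose(stride, round(stride)):
        raise ValueError(f"step {step} is not a multiple of the grid spacing {dx}")
    return int(round(stride))


def steepest_descent_path(surface: ResponseSurface, step: float = 0.1) -> Pathway:
    """Greedy steepest-decline walk from (0, 0) toward (1, 1).

    At each node the admissible moves are one step in +x or +y; the move with
    the larger PM2.5 decrease is taken (equal effort per move), ties breaking
    toward NH3 (x).  The walk stops at the far corner or when no move lowers
    the surface.
    """
    sx = _step_stride(surface.x_grid, step)
    sy = _step_stride(surface.y_grid, step)
    V = surface.value
    ix = iy = 0
    nodes = [(0.0, 0.0)]
    abat = [0.0]
    base = V[0, 0]
    while True:
        options = []
        if ix + sx < V.shape[0]:
            options.append((V[ix + sx, iy], 0, (ix + sx, iy)))
        if iy + sy < V.shape[1]:
            options.append((V[ix, iy + sy], 1, (ix, iy + sy)))
        if not options:
            break
        options.sort(key=lambda o: (o[0], o[1]))  # lowest value; tie → x move
        best_val, _, (nix, niy) = options[0]
        if best_val >= V[ix, iy]:
            break
        ix, iy = nix, niy
        nodes.append((float(surface.x_grid[ix]), float(surface.y_grid[iy])))
        abat.append(float(base - V[ix, iy]))
    return Pathway(nodes=nodes, cumulative_abatement=abat)


def cost_surface(
    curve_nh3: CostCurve, curve_nox: CostCurve, step: float = 0.1
) -> ResponseSurface:
    """Additive cost surface on [0, 0.5]²: cost(x, y) = cost_NH3(x) + cost_NOx(y)."""
    n = int(round(MAX_REDUCTION / step)) + 1
    g = np.linspace(0.0, MAX_REDUCTION, n)
    cx = curve_nh3(g)
    cy = curve_nox(g)
    return ResponseSurface(
        x_grid=g, y_grid=g, value=cx[:, None] + cy[None, :], kind="cost",
        provenance="cost_curves",
    )


def cost_effectiveness_surface(
    pm_surface: ResponseSurface, cost_sfc: ResponseSurface
) -> ResponseSurface:
    """Cumulative cost per cumulative PM2.5 abatement from the base state.

    Defined on the cost grid ([0, 0.5]²); NaN at the origin and wherever the
    abatement is zero (warned when the cost there is nonzero).
    """
    g = cost_sfc.x_grid
    # restrict the PM surface to the cost grid
    xi = [int(np.argmin(np.abs(pm_surface.x_grid - v))) for v in g]
    yi = [int(np.argmin(np.abs(pm_surface.y_grid - v))) for v in g]
    if not np.allclose(pm_surface.x_grid[xi], g) or not np.allclose(pm_surface.y_grid[yi], g):
        raise ValueError("PM2.5 surface grid does not contain the cost grid nodes")
    pm = pm_surface.value[np.ix_(xi, yi)]
    abatement = pm[0, 0] - pm
    cost = cost_sfc.value
    undefined = abatement <= 0
    if np.any(undefined & (cost > 0) & ~((np.arange(len(g))[:, None] == 0) & (np.arange(len(g))[None, :] == 0))):
        warnings.warn("zero PM2.5 abatement with nonzero cost; ratio masked", stacklevel=2)
    ratio = np.where(undefined, np.nan, cost / np.where(undefined, 1.0, abatement))
    return ResponseSurface(
        x_grid=g, y_grid=g, value=ratio, kind="cost_per_abatement",
        provenance=pm_surface.provenance,
    )


def cost_optimal_path(
    pm_surface: ResponseSurface,
    cost_sfc: ResponseSurface,
    step: float = 0.1,
    budget: float = 0.5,
) -> Pathway:
    """Greedy cost-effectiveness walk: cheapest incremental cost per µg·m⁻³.

    The walk spends a total control budget (default 0.5, i.e. halving combined
    Nr controls in steps of ``step``), choosing at each step the species whose
    next increment has the lowest incremental cost per unit PM2.5 abated.
    Moves with no abatement are taken only if free; the walk never leaves the
    [0, 0.5]² cost domain.
    """
    g = cost_sfc.x_grid
    sx = _step_stride(g, step)
    xi = [int(np.argmin(np.abs(pm_surface.x_grid - v))) for v in g]
    yi = [int(np.argmin(np.abs(pm_surface.y_grid - v))) for v in g]
    if not np.allclose(pm_surface.x_grid[xi], g) or not np.allclose(pm_surface.y_grid[yi], g):
        raise ValueError("PM2.5 surface grid does not contain the cost grid nodes")
    pm = pm_surface.value[np.ix_(xi, yi)]
    cost = cost_sfc.value

    n_steps = int(round(budget / step))
    ix = iy = 0
    nodes = [(0.0, 0.0)]
    abat = [0.0]
    csum = [0.0]
    for _ in range(n_steps):
        options = []
        for axis, (nix, niy) in enumerate([(ix + sx, iy), (ix, iy + sx)]):
            if nix >= len(g) or niy >= len(g):
                continue
            dcost = cost[nix, niy] - cost[ix, iy]
            dabat = pm[ix, iy] - pm[nix, niy]
            if dabat <= 0 and dcost > 0:
                continue  # paying for nothing
            ratio = dcost / dabat if dabat > 0 else 0.0
            options.append((ratio, axis, nix, niy))
        if not options:
            break
        options.sort(key=lambda o: (o[0], o[1]))
        _, _, ix, iy = options[0]
        nodes.append((float(g[ix]), float(g[iy])))
        abat.append(float(pm[0, 0] - pm[ix, iy]))
        csum.append(float(cost[ix, iy]))
    return Pathway(nodes=nodes, cumulative_abatement=abat, cumulative_cost=csum)


# ---------------------------------------------------------------------------
# Exhaustive lattice-path oracle


def enumerate_monotone_paths(nx: int, ny: int):
    """All monotone lattice paths from (0, 0) to (nx, ny) as index tuples."""
    moves = nx + ny
    for x_positions in combinations(range(moves), nx):
        ix = iy = 0
        path = [(0, 0)]
        xset = set(x_positions)
        for m in range(moves):
            if m in xset:
                ix += 1
            else:
                iy += 1
            path.append((ix, iy))
        yield path


def best_abatement_by_steps(value: np.ndarray) -> np.ndarray:
    """Max abatement achievable after k steps, for k = 0 .. nx+ny−2.

    Abatement along a monotone path is path-independent (it is the scalar
    surface difference), so the per-step optimum is the best node on each
    anti-diagonal of the lattice.
    """
    nx, ny = value.shape
    base = value[0, 0]
    out = []
    for k in range(nx + ny - 1):
        best = -np.inf
        for i in range(max(0, k - ny + 1), min(nx - 1, k) + 1):
            best = max(best, base - value[i, k - i])
        out.append(best)
    return np.array(out)


def path_optimality_gap(surface: ResponseSurface, path: Pathway) -> float:
    """Largest shortfall of the greedy path vs the enumerated per-step optimum.

    0 means the greedy walk matched the exhaustive monotone-lattice optimum at
    every path length it reached; positive values quantify greedy myopia on
    increasing-returns surfaces.
    """
    best = best_abatement_by_steps(surface.value)
    gaps = [
        best[k] - path.cumulative_abatement[k]
        for k in range(len(path.cumulative_abatement))
    ]
    return float(max(gaps))
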