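import numpy as np
import pytest

from nrpathways import (
    ScenarioSpec,
    best_abatement_by_steps,
    cost_effectiveness_surface,
    cost_optimal_path,
    cost_surface,
    fit_response_surface,
    generate_cost_curves,
    gradient_field,
    instant_efficiency,
    path_optimality_gap,
    steepest_descent_path,
)
from nrpathways.costs import CostCurve
from nrpathways.efficiency import LEVEL_GRID, ResponseCurve
from nrpathways.pathway import ResponseSurface, enumerate_monotone_paths

LEVELS = (0.3, 0.6, 0.8, 1.0)


def spec_values_from_function(f):
    """Evaluate a function f(x, y) at the 13 scenario design points."""
    values = {ScenarioSpec(0.0, 0.0): f(0.0, 0.0)}
    for l in LEVELS:
        values[ScenarioSpec(l, l)] = f(l, l)
        values[ScenarioSpec(0.0, l)] = f(0.0, l)
        values[ScenarioSpec(l, 0.0)] = f(l, 0.0)
    return values


def regional_values(ensemble, grid, region="West"):
    return {
        spec: float(grid.area_weighted_mean(st.annual_mean_pm25(), region))
        for spec, st in ensemble.items()
    }


class TestFitResponseSurface:
    def test_reproduces_the_13_inputs_exactly(self, ensemble, domain):
        grid, _, _ = domain
        values = regional_values(ensemble, grid)
        surface = fit_response_surface(values)
        for spec, v in values.items():
            assert surface.at(spec.x, spec.y) == pytest.approx(v, rel=1e-12)

    def test_recovers_planar_surfaces_exactly(self):
        f = lambda x, y: 10.0 - 2.0 * x - 1.5 * y
        surface = fit_response_surface(spec_values_from_function(f))
        X, Y = np.meshgrid(surface.x_grid, surface.y_grid, indexing="ij")
        np.testing.assert_allclose(surface.value, f(X, Y), atol=1e-12)

    def test_smooth_separable_surfaces_within_ray_interpolation_error(self):
        f = lambda x, y: 10.0 - 2.0 * x**2 - 1.5 * np.sqrt(y)
        surface = fit_response_surface(spec_values_from_function(f))
        X, Y = np.meshgrid(surface.x_grid, surface.y_grid, indexing="ij")
        # the between-ray blend trades separable exactness for monotonicity;
        # accuracy statement: within 20% of the span for smooth separable input
        span = f(0, 0) - f(1.0, 1.0)
        assert np.max(np.abs(surface.value - f(X, Y))) < 0.20 * span

    def test_interior_error_against_surrogate(self, ensemble, domain):
        grid, inv, params = domain
        from nrpathways import equilibrium_fields

        values = regional_values(ensemble, grid)
        surface = fit_response_surface(values)
        direct = np.empty_like(surface.value)
        for i, x in enumerate(surface.x_grid):
            for j, y in enumerate(surface.y_grid):
                direct[i, j] = grid.area_weighted_mean(
                    equilibrium_fields(inv, params, x, y).annual_mean_pm25(), "West"
                )
        span = direct.max() - direct.min()
        # accuracy statement for a 13-point reconstruction of a min-structured
        # response: interior error within 25% of the response span
        assert np.max(np.abs(surface.value - direct)) < 0.25 * span

    def test_monotone_in_both_controls(self, ensemble, domain):
        grid, _, _ = domain
        surface = fit_response_surface(regional_values(ensemble, grid))
        assert np.all(np.diff(surface.value, axis=0) <= 1e-12)
        assert np.all(np.diff(surface.value, axis=1) <= 1e-12)

    def test_off_ray_specs_rejected(self):
        values = {ScenarioSpec(0.0, 0.0): 10.0, ScenarioSpec(0.3, 0.6): 8.0}
        with pytest.raises(ValueError):
            fit_response_surface(values)


class TestGradientField:
    def test_planar_surface_exact(self):
        g = np.linspace(0, 1, 11)
        X, Y = np.meshgrid(g, g, indexing="ij")
        surface = ResponseSurface(g, g, 5.0 - 1.2 * X - 0.7 * Y)
        grad = gradient_field(surface)
        np.testing.assert_allclose(grad.gx, -1.2, rtol=1e-12)
        np.testing.assert_allclose(grad.gy, -0.7, rtol=1e-12)

    def test_symmetric_surface_symmetric_gradient(self):
        g = np.linspace(0, 1, 11)
        X, Y = np.meshgrid(g, g, indexing="ij")
        surface = ResponseSurface(g, g, 10 - (X + Y) ** 2 - X * Y)
        grad = gradient_field(surface)
        np.testing.assert_allclose(grad.gx, grad.gy.T, atol=1e-12)

    def test_axis_restriction_reproduces_instant_efficiency(self, ensemble, domain):
        grid, _, _ = domain
        values = regional_values(ensemble, grid)
        surface = fit_response_surface(values, monotone_clip=False)
        grad = gradient_field(surface)
        base_pm = surface.value[0, 0]
        pm_axis = surface.value[:, 0]  # NH3-only ray
        beta = instant_efficiency(
            ResponseCurve(LEVEL_GRID, pm_axis, base_emi=4.4, mode="NH3")
        ).beta
        # β on the axis is the negated gradient normalized by the base PM2.5
        np.testing.assert_allclose(beta, -grad.gx[:, 0] / base_pm, rtol=1e-9)

    def test_degenerate_grid_rejected(self):
        surface = ResponseSurface(np.array([0.0]), np.array([0.0]), np.zeros((1, 1)))
        with pytest.raises(ValueError):
            gradient_field(surface)


def separable_surface(dx, dy):
    """Monotone surface from per-step abatement increments dx, dy."""
    ax = np.concatenate([[0.0], np.cumsum(dx)])
    ay = np.concatenate([[0.0], np.cumsum(dy)])
    g = np.linspace(0, 1, len(ax))
    return ResponseSurface(g, g, 10.0 - ax[:, None] - ay[None, :])


class TestSteepestDescent:
    def test_runs_up_the_steeper_axis_first(self):
        dx = np.full(5, 0.1)
        dy = np.array([1.0, 0.9, 0.8, 0.7, 0.6])
        path = steepest_descent_path(separable_surface(dx, dy), step=0.2)
        np.testing.assert_allclose(
            path.nodes[1:6], [(0.0, 0.2), (0.0, 0.4), (0.0, 0.6), (0.0, 0.8), (0.0, 1.0)]
        )
        np.testing.assert_allclose(path.nodes[-1], (1.0, 1.0))

    def test_tie_breaks_toward_nh3(self):
        path = steepest_descent_path(separable_surface(np.full(5, 0.5), np.full(5, 0.5)), step=0.2)
        assert path.nodes[1] == (0.2, 0.0)

    def test_stops_when_nothing_decreases(self):
        g = np.linspace(0, 1, 6)
        surface = ResponseSurface(g, g, np.full((6, 6), 4.0))
        path = steepest_descent_path(surface, step=0.2)
        assert path.nodes == [(0.0, 0.0)]

    def test_cumulative_abatement_is_path_independent_bookkeeping(self, ensemble, domain):
        grid, _, _ = domain
        surface = fit_response_surface(regional_values(ensemble, grid))
        path = steepest_descent_path(surface)
        for node, ab in zip(path.nodes, path.cumulative_abatement):
            assert ab == pytest.approx(surface.value[0, 0] - surface.at(*node))

    def test_matches_enumeration_on_concave_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            # diminishing returns: sorted decreasing increments => greedy optimal
            dx = np.sort(rng.uniform(0.05, 1.0, 5))[::-1]
            dy = np.sort(rng.uniform(0.05, 1.0, 5))[::-1]
            surface = separable_surface(dx, dy)
            path = steepest_descent_path(surface, step=0.2)
            assert path_optimality_gap(surface, path) == pytest.approx(0.0, abs=1e-12)

    def test_gap_reported_on_increasing_returns_fixture(self):
        # increasing returns along x: greedy is myopic, the gap is positive
        dx = np.array([0.01, 0.02, 0.05, 1.0, 1.5])
        dy = np.full(5, 0.1)
        surface = separable_surface(dx, dy)
        path = steepest_descent_path(surface, step=0.2)
        gap = path_optimality_gap(surface, path)
        assert np.isfinite(gap) and gap > 0


def test_enumerated_paths_agree_with_antidiagonal_optimum():
    rng = np.random.default_rng(1)
    vals = 10.0 - np.minimum.accumulate(
        np.minimum.accumulate(rng.uniform(0, 1, (4, 4)).cumsum(axis=0).cumsum(axis=1), 0), 1
    )
    vals = np.minimum.accumulate(np.minimum.accumulate(vals, axis=0), axis=1)
    base = vals[0, 0]
    best = best_abatement_by_steps(vals)
    brute = np.full(7, -np.inf)
    for path in enumerate_monotone_paths(3, 3):
        for k, (i, j) in enumerate(path):
            brute[k] = max(brute[k], base - vals[i, j])
    np.testing.assert_allclose(best, brute)


def published_anchor_west_fixture():
    """Abatement + costs pinned to the printed Western-Europe checkpoints.

    The abatement curves interpolate the published regional figures (NH3:
    0.11/0.40/1.03/2.51 ug m-3 at 10/30/60/100% cuts; NOx: 0.23/0.67 at
    10/30%), with the 10% checkpoints as knots so the anchor columns carry
    the printed values exactly; the PM2.5 surface is their additive field
    evaluated directly on the control grid.
    """
    from scipy.interpolate import PchipInterpolator

    ab_nh3 = PchipInterpolator([0, 0.1, 0.3, 0.6, 1.0], [0, 0.11, 0.40, 1.03, 2.51])
    ab_nox = PchipInterpolator([0, 0.1, 0.3, 0.6, 1.0], [0, 0.23, 0.67, 1.2, 1.55])
    base_pm = 8.5
    g = np.linspace(0.0, 1.0, 11)
    X, Y = np.meshgrid(g, g, indexing="ij")
    pm_surface = ResponseSurface(
        g, g, base_pm - ab_nh3(X) - ab_nox(Y), provenance="surrogate_exact"
    )
    curves = generate_cost_curves()
    csfc = cost_surface(curves[("NH3", "West")], curves[("NOx", "West")])
    return pm_surface, csfc


class TestCostSurfaces:
    def test_cost_surface_zero_at_origin_and_monotone(self):
        curves = generate_cost_curves()
        csfc = cost_surface(curves[("NH3", "West")], curves[("NOx", "West")])
        assert csfc.at(0.0, 0.0) == 0.0
        assert np.all(np.diff(csfc.value, axis=0) > 0)
        assert np.all(np.diff(csfc.value, axis=1) > 0)

    def test_cost_surface_checkpoint_values(self):
        curves = generate_cost_curves()
        csfc = cost_surface(curves[("NH3", "West")], curves[("NOx", "West")])
        assert csfc.at(0.1, 0.0) == pytest.approx(0.08)
        assert csfc.at(0.3, 0.0) == pytest.approx(1.1)
        assert csfc.at(0.0, 0.1) == pytest.approx(1.1)
        assert csfc.at(0.0, 0.3) == pytest.approx(12.7)

    def test_out_of_range_queries_rejected(self):
        with pytest.raises(ValueError):
            generate_cost_curves()[("NH3", "West")](0.51)

    def test_cost_effectiveness_checkpoint_ratios(self):
        pm_surface, csfc = published_anchor_west_fixture()
        ratio = cost_effectiveness_surface(pm_surface, csfc)
        assert ratio.at(0.1, 0.0) == pytest.approx(0.08 / 0.11, rel=1e-9)
        assert ratio.at(0.0, 0.1) == pytest.approx(1.1 / 0.23, rel=1e-9)
        assert np.isnan(ratio.at(0.0, 0.0))

    def test_doubling_costs_doubles_the_ratio(self):
        pm_surface, csfc = published_anchor_west_fixture()
        doubled = ResponseSurface(csfc.x_grid, csfc.y_grid, 2 * csfc.value, kind="cost")
        r1 = cost_effectiveness_surface(pm_surface, csfc)
        r2 = cost_effectiveness_surface(pm_surface, doubled)
        np.testing.assert_allclose(r2.value[1:, :], 2 * r1.value[1:, :], rtol=1e-12)


class TestCostOptimalPath:
    def test_published_anchor_fixture_moves_along_nh3_only(self):
        pm_surface, csfc = published_anchor_west_fixture()
        path = cost_optimal_path(pm_surface, csfc)
        assert all(y == 0.0 for _, y in path.nodes)
        assert path.nodes[-1] == (0.5, 0.0)
        assert path.cumulative_cost[-1] == pytest.approx(
            generate_cost_curves()[("NH3", "West")](0.5)
        )

    def test_counter_fixture_flips_to_nox(self):
        pm_surface, _ = published_anchor_west_fixture()
        cheap_nox = CostCurve([(0.0, 0.0), (0.1, 0.01), (0.3, 0.05)])
        dear_nh3 = CostCurve([(0.0, 0.0), (0.1, 5.0), (0.3, 60.0)])
        csfc = cost_surface(dear_nh3, cheap_nox)
        path = cost_optimal_path(pm_surface, csfc)
        assert all(x == 0.0 for x, _ in path.nodes)

    def test_budget_controls_path_length(self):
        pm_surface, csfc = published_anchor_west_fixture()
        path = cost_optimal_path(pm_surface, csfc, budget=0.3)
        assert len(path.nodes) == 4
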