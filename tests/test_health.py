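import inspect

import numpy as np
import pytest

from nrpathways import (
    AgeStructure,
    GemmParams,
    attributable_deaths,
    avoided_deaths,
    load_gemm_params,
    monte_carlo_ci,
    relative_risk,
)
from nrpathways.health import DEFAULT_N_DRAWS


def one_group_params(theta=0.143, theta_se=0.0, alpha=1.6, mu=15.5, upsilon=36.8):
    return GemmParams(
        age_groups=("25-29",),
        theta=np.array([theta]),
        theta_se=np.array([theta_se]),
        alpha=np.array([alpha]),
        mu=np.array([mu]),
        upsilon=np.array([upsilon]),
    )


def one_cell_ages(base=0.01, pop=1e5, n_cells=1):
    shape = (1, 1, n_cells)
    return AgeStructure(
        age_groups=("25-29",),
        pop=np.full(shape, pop),
        base_rate=np.full(shape, base),
    )


class TestRelativeRisk:
    def test_unity_at_and_below_threshold(self):
        for c in (0.0, 1.0, 2.4):
            assert relative_risk(c, 0.143, 1.6, 15.5, 36.8) == pytest.approx(1.0)

    def test_hand_computed_value_above_threshold(self):
        # z=7.6: exp(0.143 * log(7.6/1.6 + 1) * logistic((7.6-15.5)/36.8))
        z = 7.6
        expected = np.exp(0.143 * np.log1p(z / 1.6) / (1 + np.exp((15.5 - z) / 36.8)))
        assert relative_risk(10.0, 0.143, 1.6, 15.5, 36.8) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.118, abs=5e-4)

    def test_continuous_and_nondecreasing(self):
        c = np.linspace(0, 60, 2001)
        rr = relative_risk(c, 0.143, 1.6, 15.5, 36.8)
        assert np.all(rr >= 1.0)
        assert np.all(np.diff(rr) >= 0)
        assert np.max(np.abs(np.diff(rr))) < 5e-3  # no jumps at the threshold

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            relative_risk(-1.0, 0.143, 1.6, 15.5, 36.8)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            one_group_params(alpha=-0.5)
        with pytest.raises(ValueError):
            one_group_params(upsilon=0.0)


class TestAttributableDeaths:
    def test_zero_below_threshold(self):
        res = attributable_deaths(np.full((1, 3), 2.0), one_cell_ages(n_cells=3), one_group_params())
        assert res.deaths == 0.0

    def test_hand_example_rr_1_25_gives_200(self):
        # Base=0.01/yr, Pop=1e5, RR=1.25 -> 0.01*1e5*(1-1/1.25) = 200.
        # Pick theta so RR(c)=1.25 exactly at c=10.
        shape = np.log1p(7.6 / 1.6) / (1 + np.exp((15.5 - 7.6) / 36.8))
        theta = np.log(1.25) / shape
        res = attributable_deaths(np.full((1, 1), 10.0), one_cell_ages(), one_group_params(theta=theta))
        assert res.deaths == pytest.approx(200.0, rel=1e-12)

    def test_additive_over_cells_and_scale_invariance(self):
        params = one_group_params()
        whole = attributable_deaths(np.full((1, 1), 12.0), one_cell_ages(pop=2e5), params)
        split = attributable_deaths(np.full((1, 2), 12.0), one_cell_ages(pop=1e5, n_cells=2), params)
        assert whole.deaths == pytest.approx(split.deaths)
        double = attributable_deaths(np.full((1, 1), 12.0), one_cell_ages(pop=4e5), params)
        assert double.deaths == pytest.approx(2 * whole.deaths)

    def test_as_printed_form_gives_total_not_excess(self):
        params = one_group_params()
        res = attributable_deaths(np.full((1, 1), 10.0), one_cell_ages(), params, as_printed=True)
        rr = relative_risk(10.0, 0.143, 1.6, 15.5, 36.8)
        assert res.deaths == pytest.approx(0.01 * 1e5 / rr)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            attributable_deaths(np.full((2, 2), 10.0), one_cell_ages(), one_group_params())


class TestAvoidedDeaths:
    def test_identical_fields_avoid_nothing(self):
        f = np.full((1, 2), 9.0)
        res = avoided_deaths(f, f, one_cell_ages(n_cells=2), one_group_params())
        assert res.deaths == 0.0

    def test_scenario_below_threshold_recovers_full_burden(self):
        base = np.full((1, 1), 9.0)
        clean = np.full((1, 1), 1.0)
        params = one_group_params()
        ages = one_cell_ages()
        assert avoided_deaths(base, clean, ages, params).deaths == pytest.approx(
            attributable_deaths(base, ages, params).deaths
        )

    def test_two_cell_hand_difference(self):
        # cells at RR 1.25 and 1.10 cleaned to no impact:
        # avoided = B*P*[(1-1/1.25) + (1-1/1.10)]
        shape10 = np.log1p(7.6 / 1.6) / (1 + np.exp((15.5 - 7.6) / 36.8))
        theta = np.log(1.25) / shape10
        # find c where RR = 1.10 for this theta by bisection
        lo, hi = 2.4, 10.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if relative_risk(mid, theta, 1.6, 15.5, 36.8) < 1.10:
                lo = mid
            else:
                hi = mid
        base = np.array([[10.0, hi]])
        clean = np.full((1, 2), 0.0)
        res = avoided_deaths(base, clean, one_cell_ages(n_cells=2), one_group_params(theta=theta))
        expected = 0.01 * 1e5 * ((1 - 1 / 1.25) + (1 - 1 / 1.10))
        assert res.deaths == pytest.approx(expected, rel=1e-9)


class TestMonteCarlo:
    def test_default_draw_count_is_ten_thousand(self):
        assert DEFAULT_N_DRAWS == 10_000
        sig = inspect.signature(monte_carlo_ci)
        assert sig.parameters["n_draws"].default == 10_000

    def test_degenerate_when_theta_se_zero(self):
        res = monte_carlo_ci(
            np.full((1, 1), 10.0), one_cell_ages(), one_group_params(theta_se=0.0),
            n_draws=500, seed=1,
        )
        assert res.ci_low == pytest.approx(res.deaths, rel=1e-12)
        assert res.ci_high == pytest.approx(res.deaths, rel=1e-12)

    def test_reproducible_under_fixed_seed(self):
        args = (np.full((1, 1), 10.0), one_cell_ages(), one_group_params(theta_se=0.02))
        a = monte_carlo_ci(*args, n_draws=2000, seed=7)
        b = monte_carlo_ci(*args, n_draws=2000, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_ci_matches_lognormal_percentiles(self):
        # One group, one cell: deaths(theta) = B*P*(1-exp(-theta*s)) is monotone
        # in theta, so CI bounds equal the transform of the theta percentiles.
        theta, se = 0.143, 0.02
        params = one_group_params(theta=theta, theta_se=se)
        ages = one_cell_ages()
        field = np.full((1, 1), 10.0)
        s = np.log1p(7.6 / 1.6) / (1 + np.exp((15.5 - 7.6) / 36.8))
        expected_lo = 0.01 * 1e5 * (1 - np.exp(-(theta - 1.959964 * se) * s))
        expected_hi = 0.01 * 1e5 * (1 - np.exp(-(theta + 1.959964 * se) * s))
        res = monte_carlo_ci(field, ages, params, n_draws=100_000, seed=3)
        assert res.ci_low == pytest.approx(expected_lo, rel=5e-3)
        assert res.ci_high == pytest.approx(expected_hi, rel=5e-3)

    def test_ci_width_shrinks_with_se(self):
        field = np.full((1, 1), 10.0)
        widths = []
        for se in (0.04, 0.02, 0.005):
            res = monte_carlo_ci(
                field, one_cell_ages(), one_group_params(theta_se=se), n_draws=4000, seed=2
            )
            widths.append(res.ci_high - res.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_avoided_mode_brackets_point_estimate(self):
        base = np.full((1, 2), 12.0)
        scen = np.full((1, 2), 6.0)
        ages = one_cell_ages(n_cells=2)
        params = one_group_params(theta_se=0.02)
        res = monte_carlo_ci(base, ages, params, scenario_field=scen, n_draws=3000, seed=4)
        point = avoided_deaths(base, scen, ages, params).deaths
        assert res.deaths == pytest.approx(point)
        assert res.ci_low <= point <= res.ci_high


def test_bundled_fixture_loads_with_12_groups(tmp_path):
    params = load_gemm_params()
    assert len(params.age_groups) == 12
    assert params.cf == 2.4
    with pytest.raises(FileNotFoundError):
        load_gemm_params(tmp_path / "missing.csv")
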