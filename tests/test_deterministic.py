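"""Deterministic recursion: force, equilibria, trajectories, half-times."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lethalwf as lw


def params(u, h):
    return lw.PopulationParams(u=u, h=h)


class TestForce:
    def test_recessive_no_mutation_closed_form(self):
        # with h = u = 0 the force reduces to -x^2 / (1 + x)
        f = lw.deterministic_force(0.1, params(0.0, 0.0))
        assert f == pytest.approx(-0.01 / 1.1, rel=1e-14)

    @pytest.mark.parametrize("h,u", [
        (0.0, 1e-8), (0.3, 1e-3), (-0.01, 1e-5), (1.0, 0.1), (-2.0, 0.0),
    ])
    def test_force_at_zero_frequency(self, h, u):
        # symbolic substitution of x = 0: F(0) = (1-h)u / (1 + (1-2h)u)
        expected = (1 - h) * u / (1 + (1 - 2 * h) * u)
        assert lw.deterministic_force(0.0, params(u, h)) == pytest.approx(
            expected, rel=1e-14, abs=0.0
        )

    def test_force_at_zero_random_params(self, rng):
        for _ in range(100):
            h = float(rng.uniform(-1, 1))
            u = float(rng.uniform(0, 1))
            expected = (1 - h) * u / (1 + (1 - 2 * h) * u)
            assert lw.deterministic_force(0.0, params(u, h)) == pytest.approx(
                expected, rel=1e-13, abs=1e-300
            )

    def test_vanishes_at_equilibrium(self, random_valid_params):
        for p in random_valid_params:
            x_hat = lw.equilibrium_exact(p).x_hat
            assert abs(lw.deterministic_force(x_hat, p)) < 1e-12

    def test_domain_error_outside_half(self):
        with pytest.raises(ValueError):
            lw.deterministic_force(0.6, params(0.0, 0.0))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        x=st.floats(0.0, 0.5),
        h=st.floats(-50.0, 1.0),
        u=st.floats(0.0, 1.0),
    )
    def test_successor_bounded(self, x, h, u):
        """Structural bound: one deterministic step never leaves [0, 1/2]."""
        succ = x + lw.deterministic_force(x, params(u, h))
        assert -1e-12 <= succ <= 0.5 + 1e-12


class TestStep:
    def test_textbook_lethal_step(self):
        # h = u = 0: x' = x / (1 + x)
        assert lw.step_infinite(0.2, params(0.0, 0.0)) == pytest.approx(
            0.2 / 1.2, rel=1e-14
        )

    @pytest.mark.parametrize("h", [0.0, 0.5, -0.3, 1.0])
    def test_zero_absorbing_without_mutation(self, h):
        assert lw.step_infinite(0.0, params(0.0, h)) == 0.0

    def test_equilibrium_is_fixed_point_to_12_digits(self):
        p = params(1e-8, -0.01)
        x_hat = lw.equilibrium_exact(p).x_hat
        assert lw.step_infinite(x_hat, p) == pytest.approx(x_hat, rel=1e-12)

    def test_textbook_iterate_closed_form(self):
        # n-fold iterate of x' = x/(1+x) is x0 / (1 + n x0)
        p = params(0.0, 0.0)
        x = 0.5
        for n in range(1, 51):
            x = lw.step_infinite(x, p)
            assert x == pytest.approx(0.5 / (1 + 0.5 * n), rel=1e-12)


class TestTrajectory:
    def test_starts_at_equilibrium_stays_flat(self):
        p = params(1e-8, 0.0)
        x_hat = lw.equilibrium_exact(p).x_hat
        traj = lw.trajectory_infinite(
            x_hat, lw.DominanceSchedule.constant(0.0), 1e-8, 50
        )
        xs = [x for _, x in traj]
        assert max(abs(x - x_hat) for x in xs) < 1e-15

    def test_jump_rises_to_overdominant_equilibrium(self):
        p0 = params(1e-8, 0.0)
        x0 = lw.equilibrium_exact(p0).x_hat
        traj = lw.trajectory_infinite(
            x0, lw.DominanceSchedule.constant(-0.01), 1e-8, 3000
        )
        xs = np.array([x for _, x in traj])
        assert np.all(np.diff(xs) > 0)
        assert xs[-1] == pytest.approx(9.8e-3, rel=0.01)

    def test_monotone_convergence_from_both_sides(self):
        for h in (-0.5, -0.01, 0.0, 0.3, 0.99):
            for u in (0.0, 1e-6, 1e-3):
                p = params(u, h)
                x_hat = lw.equilibrium_exact(p).x_hat
                for x0 in (x_hat / 2 if x_hat > 0 else 0.0,
                           min(0.5, x_hat * 1.5 + 1e-3)):
                    xs = [x for _, x in lw.trajectory_infinite(
                        x0, lw.DominanceSchedule.constant(h), u, 200)]
                    diffs = np.diff(xs)
                    if x0 <= x_hat:
                        assert np.all(diffs >= -1e-15)
                    else:
                        assert np.all(diffs <= 1e-15)


class TestEquilibriumExact:
    @pytest.mark.parametrize("h,u,expected,rel", [
        (0.0, 1e-8, 1.0e-4, 0.005),
        (0.0, 1e-5, 3.2e-3, 0.02),
        (-0.01, 1e-8, 9.8e-3, 0.005),
        (-0.01, 1e-5, 1.071e-2, 0.005),   # 1071 x u
        (0.01, 1e-5, 9.1e-4, 0.005),      # 91 x u
    ])
    def test_printed_values(self, h, u, expected, rel):
        assert lw.equilibrium_exact(params(u, h)).x_hat == pytest.approx(
            expected, rel=rel
        )

    @pytest.mark.parametrize("h", [0.0, 0.01, 0.5, 1.0])
    def test_zero_mutation_nonnegative_h_gives_zero(self, h):
        assert lw.equilibrium_exact(params(0.0, h)).x_hat == 0.0

    @pytest.mark.parametrize("h", [-1e-6, -0.01, -0.05, -1.0, -100.0])
    def test_zero_mutation_overdominant_closed_form(self, h):
        expected = abs(h) / (1 + 2 * abs(h))
        assert lw.equilibrium_exact(params(0.0, h)).x_hat == pytest.approx(
            expected, rel=1e-15
        )

    @pytest.mark.parametrize("u", [1e-12, 1e-8, 1e-4, 1e-2, 0.5])
    def test_fully_recessive_closed_form(self, u):
        # at h = 0 the quadratic solves exactly to sqrt(u)/(1 + sqrt(u))
        expected = math.sqrt(u) / (1 + math.sqrt(u))
        assert lw.equilibrium_exact(params(u, 0.0)).x_hat == pytest.approx(
            expected, rel=1e-10
        )

    @pytest.mark.parametrize("h", [-0.01, -0.1])
    @pytest.mark.parametrize("u", [1e-12, 1e-10, 1e-8])
    def test_overdominant_small_u_is_cancellation_free(self, h, u):
        """The naive printed formula loses ~8 digits here; the stable
        branch must stay within the analytic small-u expansion."""
        x = lw.equilibrium_exact(params(u, h)).x_hat
        limit = abs(h) / (1 + 2 * abs(h))
        # the true small-u correction is O(u / h^2); a cancellation-prone
        # evaluation would leave ~1e-8 absolute noise instead
        assert abs(x - limit) / limit < u / h**2 * 10

    def test_fixed_point_residual_random_draws(self, random_valid_params):
        for p in random_valid_params:
            x_hat = lw.equilibrium_exact(p).x_hat
            assert 0.0 <= x_hat <= 0.5
            assert abs(lw.deterministic_force(x_hat, p)) < 1e-12

    def test_degenerate_linear_cases(self):
        # h = 1/2 and u = 1 collapse the quadratic to a linear equation
        assert lw.equilibrium_exact(params(1e-4, 0.5)).x_hat == pytest.approx(
            1e-4 / (1 + 1e-4), rel=1e-12
        )
        x = lw.equilibrium_exact(params(1.0, 0.0)).x_hat
        assert abs(lw.deterministic_force(x, params(1.0, 0.0))) < 1e-12


class TestEquilibriumApprox:
    @pytest.mark.parametrize("regime,h,u,expected", [
        ("recessive", 0.0, 1e-8, 1.0e-4),
        ("overdominant", -0.01, 1e-8, 0.01 / 1.02),
        ("zero-mutation-limit", -0.05, 1e-12, 0.05 / 1.10),
        ("small-positive-h", 0.01, 1e-5, 0.99 * 1e-3),
    ])
    def test_closed_forms(self, regime, h, u, expected):
        res = lw.equilibrium_approx(params(u, h), regime)
        assert res.method == regime
        assert res.x_hat == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("regime,h,u", [
        ("small-positive-h", 0.01, 1e-6),
        ("overdominant", -0.01, 1e-6),
        ("recessive", 0.0, 1e-6),
    ])
    def test_within_5pct_of_exact_when_regime_holds(self, regime, h, u):
        approx = lw.equilibrium_approx(params(u, h), regime).x_hat
        exact = lw.equilibrium_exact(params(u, h)).x_hat
        assert abs(approx - exact) / exact < 0.05

    def test_violated_regime_warns_not_fails(self):
        with pytest.warns(UserWarning):
            lw.equilibrium_approx(params(0.009, 0.01), "small-positive-h")

    def test_unknown_regime(self):
        with pytest.raises(ValueError):
            lw.equilibrium_approx(params(1e-8, 0.0), "weak-selection")

    def test_zero_mutation_limit_matches_exact_at_tiny_u(self):
        approx = lw.equilibrium_approx(params(1e-12, -0.05),
                                       "zero-mutation-limit").x_hat
        exact = lw.equilibrium_exact(params(1e-12, -0.05)).x_hat
        assert approx == pytest.approx(exact, rel=1e-4)


class TestHalfTimeInfinite:
    @pytest.mark.parametrize("u,h_pre,h_post,expected", [
        (1e-8, 0.0, -0.01, 461),
        (1e-5, 0.0, -0.01, 114),
        (1e-8, -0.01, 0.0, 100),
        (1e-5, -0.01, 0.0, 59),
    ])
    def test_printed_half_times(self, u, h_pre, h_post, expected):
        res = lw.half_time_exact_infinite(params(u, h_pre), params(u, h_post))
        assert res.t_half == expected
        assert res.x_mid == (res.x_start + res.x_final) / 2

    def test_crossing_brackets_the_midpoint(self):
        res = lw.half_time_exact_infinite(params(1e-8, 0.0),
                                          params(1e-8, -0.01))
        # the discrete trajectory crosses at t_cross, not before
        p_post = params(1e-8, -0.01)
        x = res.x_start
        for _ in range(res.t_cross - 1):
            x = lw.step_infinite(x, p_post)
        assert x < res.x_mid
        assert lw.step_infinite(x, p_post) >= res.x_mid

    def test_degenerate_jump_raises(self):
        with pytest.raises(ValueError):
            lw.half_time_exact_infinite(params(1e-8, 0.0), params(1e-8, 0.0))

    def test_mismatched_mutation_rates_raise(self):
        with pytest.raises(ValueError):
            lw.half_time_exact_infinite(params(1e-8, 0.0), params(1e-5, -0.01))


class TestHalfTimeApproximations:
    @pytest.mark.parametrize("u", [1e-8, 1e-5])
    def test_rise_within_2pct_of_exact(self, u):
        approx = lw.half_time_approx_rise(-0.01, u)
        exact = lw.half_time_exact_infinite(
            params(u, 0.0), params(u, -0.01)
        ).t_half
        assert abs(approx - exact) / exact < 0.02

    @pytest.mark.parametrize("u", [1e-8, 1e-5])
    def test_fall_within_5pct_of_exact(self, u):
        approx = lw.half_time_approx_fall(-0.01, u)
        exact = lw.half_time_exact_infinite(
            params(u, -0.01), params(u, 0.0)
        ).t_half
        assert abs(approx - exact) / exact < 0.05

    def test_rise_closed_form_value(self):
        # ln(9.8039e-3 * 1e4) / ln(1.01)
        assert lw.half_time_approx_rise(-0.01, 1e-8) == pytest.approx(
            math.log(0.01 / 1.02 * 1e4) / math.log(1.01), rel=1e-12
        )

    def test_fall_closed_form_value(self):
        # ln(1.0198) / 2e-4
        assert lw.half_time_approx_fall(-0.01, 1e-8) == pytest.approx(
            math.log(1 + 0.02 - 2e-4) / 2e-4, rel=1e-12
        )

    @pytest.mark.parametrize("fn", [lw.half_time_approx_rise,
                                    lw.half_time_approx_fall])
    def test_domain_errors(self, fn):
        with pytest.raises(ValueError):
            fn(0.01, 1e-8)
        with pytest.raises(ValueError):
            fn(-0.01, 0.0)
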