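"""Vector field, fixed-point analysis, and simulator contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.polynomial import polynomial as npoly
from scipy.integrate import solve_ivp

import wormdyn as w
from wormdyn.dynamics import DivergenceError, InvalidFieldError, lyapunov_energy


class TestEvalField:
    @pytest.mark.parametrize(
        "beta,x,expected",
        [
            (0.11, 1.0, 0.0),        # root
            (0.0, 0.0, 0.0),         # root at origin
            (0.11, 0.5, 0.2925),     # -(1.5)(0.39)(-0.5) by hand
        ],
    )
    def test_cubic_values(self, beta, x, expected):
        assert w.eval_field(w.cubic_field(beta), x) == pytest.approx(expected, abs=1e-12)

    def test_complex_pair_gives_real_values(self):
        field = w.PolynomialField(-1.0, (-1.0, 0.5 + 0.3j, 0.5 - 0.3j))
        vals = w.eval_field(field, np.linspace(-2, 2, 11))
        assert np.isrealobj(vals)
        # only one real root remains
        assert len(w.find_fixed_points(field, -1.5)) == 1

    def test_non_conjugate_roots_rejected(self):
        with pytest.raises(InvalidFieldError):
            w.PolynomialField(1.0, (1.0, 0.5 + 0.3j))

    def test_empty_roots_rejected(self):
        with pytest.raises(InvalidFieldError):
            w.PolynomialField(1.0, ())

    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=5),
           st.floats(-2, 2))
    @settings(max_examples=50, deadline=None)
    def test_real_roots_evaluate_to_zero(self, roots, a):
        field = w.PolynomialField(a if a != 0 else 1.0, tuple(roots))
        for r in roots:
            assert abs(w.eval_field(field, r)) < 1e-9 * max(1.0, abs(a)) * 6**5


class TestFixedPoints:
    def test_cubic_census(self):
        fps = w.find_fixed_points(w.cubic_field(0.11), gamma=-1.51)
        locs = {round(fp.location, 6): fp.classification for fp in fps}
        assert locs[-1.0].startswith("stable")
        assert locs[1.0].startswith("stable")
        assert locs[0.11] == "saddle"

    def test_equal_stability_at_beta_zero(self):
        field = w.cubic_field(0.0)
        assert field.derivative(1.0) == pytest.approx(-2.0)
        assert field.derivative(-1.0) == pytest.approx(-2.0)

    def test_eigenvalues_match_quadratic_formula(self):
        # independent oracle: roots of lambda^2 - gamma*lambda - f'(x*)
        beta, gamma = 0.11, -1.51
        fps = {round(fp.location, 4): fp for fp in w.find_fixed_points(w.cubic_field(beta), gamma)}
        fp1 = fps[1.0]
        fprime = -2 * (1 - beta)  # = -1.78
        disc = gamma**2 + 4 * fprime
        expected = np.sort_complex([(gamma + np.sqrt(complex(disc))) / 2,
                                    (gamma - np.sqrt(complex(disc))) / 2])
        got = np.sort_complex(np.asarray(fp1.eigenvalues))
        assert np.allclose(got, expected)
        assert fp1.classification == "stable-spiral"
        assert got[0] == pytest.approx(-0.755 - 1.1000j, abs=1e-3)

    @pytest.mark.parametrize("beta", [-0.5, 0.0, 0.11, 0.5, 0.9])
    def test_slope_law_against_finite_differences(self, beta):
        field = w.cubic_field(beta)
        h = 1e-6
        for x_star, analytic in ((1.0, -2 * (1 - beta)), (-1.0, -2 * (1 + beta))):
            fd = (w.eval_field(field, x_star + h) - w.eval_field(field, x_star - h)) / (2 * h)
            assert fd == pytest.approx(analytic, abs=1e-6)
            assert field.derivative(x_star) == pytest.approx(analytic, abs=1e-12)

    def test_repeated_root_reported_once_as_degenerate(self):
        field = w.PolynomialField(-1.0, (-1.0, 1.0, 1.0))
        fps = w.find_fixed_points(field, gamma=-1.0)
        assert len(fps) == 2
        by_loc = {round(fp.location, 6): fp for fp in fps}
        assert by_loc[1.0].classification == "degenerate"

    def test_odd_symmetry_at_beta_zero(self):
        field = w.cubic_field(0.0)
        xs = np.linspace(-2, 2, 41)
        assert np.allclose(w.eval_field(field, xs), -w.eval_field(field, -xs))


class TestSimulate:
    def test_constant_at_stable_fixed_point(self, worm5):
        p = w.ModelParams(beta=worm5.beta, gamma=worm5.gamma, sigma=0.0,
                          u34=0.0, u56=0.0, dt=worm5.dt)
        for x0 in (1.0, -1.0):
            traj = w.simulate(p, None, x0, 0.0, 300, seed=0)
            assert np.all(traj.x == x0)
            assert np.all(traj.y == 0.0)

    def test_deterministic_convergence_to_forward_well(self):
        p = w.ModelParams(beta=0.11, gamma=-1.51, sigma=0.0, u34=0, u56=0, dt=0.2929)
        traj = w.simulate(p, None, 0.5, 0.0, 200, seed=0)
        assert abs(traj.x[-1] - 1.0) < 1e-3

    def test_same_seed_bit_identical(self, worm5):
        a = w.simulate(worm5, None, 0.3, 0.0, 500, seed=123)
        b = w.simulate(worm5, None, 0.3, 0.0, 500, seed=123)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_different_seed_differs(self, worm5):
        a = w.simulate(worm5, None, 0.3, 0.0, 500, seed=1)
        b = w.simulate(worm5, None, 0.3, 0.0, 500, seed=2)
        assert not np.array_equal(a.x, b.x)

    def test_divergence_reports_step_index(self):
        p = w.ModelParams(beta=0.0, gamma=-1.0, sigma=0.0, u34=0, u56=0, dt=5.0)
        with pytest.raises(DivergenceError) as e:
            w.simulate(p, None, 2.0, 0.0, 1000, seed=0)
        assert 0 < e.value.step < 1000

    def test_short_control_rejected(self, worm5):
        with pytest.raises(ValueError, match="control length"):
            w.simulate(worm5, np.zeros(10), 0.0, 0.0, 20, seed=0)

    @pytest.mark.parametrize("x0", [0.5, -0.3, 0.9])
    def test_first_order_convergence_to_ode_oracle(self, x0):
        """sup-norm error vs a fine adaptive ODE solve shrinks ~linearly in dt."""
        beta, gamma = 0.11, -1.51
        f = w.cubic_field(beta)
        errs = {}
        for dt in (0.2, 0.1, 0.05):
            p = w.ModelParams(beta=beta, gamma=gamma, sigma=0.0, u34=0, u56=0, dt=dt)
            traj = w.simulate(p, None, x0, 0.0, 500, seed=0)
            sol = solve_ivp(
                lambda t, s: [s[1], w.eval_field(f, s[0]) + gamma * s[1]],
                (0, traj.times[-1]), [x0, 0.0], t_eval=traj.times,
                rtol=1e-10, atol=1e-12,
            )
            errs[dt] = float(np.max(np.abs(sol.y[0] - traj.x)))
        assert errs[0.05] < 1e-2
        assert errs[0.05] < errs[0.1] < errs[0.2]

    def test_lyapunov_descent(self):
        """V = y^2/2 - int f is non-increasing up to O(dt^2) per Euler step."""
        for beta, gamma, dt in ((0.11, -1.51, 0.2929), (0.0, -2.0, 0.1)):
            field = w.cubic_field(beta)
            p = w.ModelParams(beta=beta, gamma=gamma, sigma=0.0, u34=0, u56=0, dt=dt)
            for x0 in (0.5, -0.3, 1.2):
                traj = w.simulate(p, None, x0, 0.0, 500, seed=0)
                v = lyapunov_energy(field, traj.x, traj.y)
                assert np.max(np.diff(v)) <= 0.25 * dt**2


class TestModelParams:
    def test_json_round_trip(self, worm5):
        assert w.ModelParams.from_json(worm5.to_json()) == worm5

    @pytest.mark.parametrize("kw", [{"beta": 1.0}, {"beta": -1.5}, {"sigma": -0.1}, {"dt": 0.0}])
    def test_invalid_values_rejected(self, worm5, kw):
        base = {k: getattr(worm5, k) for k in w.ModelParams._ORDER}
        with pytest.raises(ValueError):
            w.ModelParams(**{**base, **kw})

    def test_induced_field_is_the_cubic(self, worm5):
        coeffs = worm5.field.coefficients
        # -(x+1)(x-beta)(x-1) = beta - x^2*beta ... expand independently
        expected = -npoly.polyfromroots([-1.0, worm5.beta, 1.0])
        assert np.allclose(coeffs, expected)
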