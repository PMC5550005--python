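"""Continuum solvers: velocity integral, colour equation, Fokker-Planck, characteristics."""

import numpy as np
import pytest

from cryptdrift.continuum import (DiffusionField, RateFunction, VelocityField,
                                  characteristic_curves, discrete_continuum_gap,
                                  solve_advection, solve_fokker_planck,
                                  velocity_from_rates)
from cryptdrift.synthetic import make_initial_condition


def _uniform_v(value, top=200.0):
    """Test override: spatially constant velocity (ignores v(0)=0)."""
    return VelocityField(knots=np.array([0.0, top]), v_knots=np.array([value, value]))


class TestVelocityFromRates:
    def test_zero_rates(self):
        k = RateFunction(breaks=np.array([0.0, 30.0]), values=np.array([0.0]))
        v = velocity_from_rates(k)
        assert np.allclose(v(np.linspace(0, 30, 7)), 0.0)

    def test_piecewise_integral_example(self):
        k = RateFunction(breaks=np.array([0.0, 20.0, 60.0]),
                         values=np.array([0.002, 0.0]))
        v = velocity_from_rates(k)
        assert v(10.0) == pytest.approx(0.02)
        assert v(25.0) == pytest.approx(0.04)
        assert v(0.0) == 0.0

    def test_matches_quadrature_oracle(self, rng):
        breaks = np.sort(np.concatenate([[0.0], rng.uniform(1, 59, 4), [60.0]]))
        vals = rng.uniform(-0.005, 0.01, 5)
        k = RateFunction(breaks=breaks, values=vals)
        v = velocity_from_rates(k)
        xs = rng.uniform(0, 60, 20)
        from scipy.integrate import quad
        for x in xs:
            expected, _ = quad(lambda u: float(k(np.array([u]))[0]), 0.0, x,
                               points=breaks[(breaks > 0) & (breaks < x)],
                               limit=200)
            assert v(x) == pytest.approx(expected, abs=1e-10)


class TestAdvection:
    def test_zero_velocity_freezes_field(self, rng):
        v = _uniform_v(0.0, top=59.0)
        L0 = rng.uniform(0, 1, 60)
        sol = solve_advection(L0, v, [500.0], refine=1)
        assert np.allclose(sol.values[0], L0, atol=1e-12)

    def test_constant_field_is_invariant(self):
        k = RateFunction(breaks=np.array([0.0, 30.0, 60.0]),
                         values=np.array([0.005, 0.0]))
        v = velocity_from_rates(k)
        sol = solve_advection(lambda x: np.full_like(x, 0.4), v, [100.0, 400.0],
                              domain_end=59.0, refine=2)
        assert np.allclose(sol.values, 0.4, atol=1e-12)

    def test_front_position_matches_characteristics(self):
        """Uniform k: x(t) = x0 exp(k t); front from 10 to 10 e^0.5 at t=100."""
        k = RateFunction(breaks=np.array([0.0, 60.0]), values=np.array([0.005]))
        v = velocity_from_rates(k)
        L0 = lambda x: np.where(x <= 10.0, 1.0, 0.0)
        sol = solve_advection(L0, v, [100.0], domain_end=59.0, refine=2)
        crossing = np.interp(0.5, sol.values[0][::-1], sol.x[::-1])
        assert abs(crossing - 10 * np.exp(0.5)) < 1.0

    def test_maximum_principle_and_tv(self, rng):
        k = RateFunction(breaks=np.array([0.0, 20.0, 40.0, 60.0]),
                         values=np.array([0.004, 0.008, 0.0]))
        v = velocity_from_rates(k)
        L0 = np.clip(rng.uniform(0, 1, 60), 0, 1)
        sol = solve_advection(L0, v, [200.0, 600.0], domain_end=59.0, refine=2)
        tv0 = np.sum(np.abs(np.diff(np.interp(sol.x, np.arange(60.0), L0))))
        for row in sol.values:
            assert row.min() >= L0.min() - 1e-9
            assert row.max() <= L0.max() + 1e-9
            assert np.sum(np.abs(np.diff(row))) <= tv0 + 1e-9

    def test_first_order_convergence(self):
        """Error against the characteristics closed form shrinks with refinement."""
        k = RateFunction(breaks=np.array([0.0, 60.0]), values=np.array([0.005]))
        v = velocity_from_rates(k)
        bump, _ = make_initial_condition(15.0, 20.0, 0.8, 60)
        t = 150.0
        errs = []
        for refine in (1, 2, 4):
            sol = solve_advection(bump, v, [t], domain_end=59.0, refine=refine)
            exact = bump(sol.x * np.exp(-0.005 * t))
            errs.append(np.max(np.abs(sol.values[0] - exact)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[0] / errs[2] > 2.0  # roughly first order over a 4x refinement

    def test_negative_velocity_pocket_handled(self):
        k = RateFunction(breaks=np.array([0.0, 10.0, 60.0]),
                         values=np.array([-0.003, 0.001]))
        v = velocity_from_rates(k)
        bump, _ = make_initial_condition(12.0, 10.0, 0.6, 60)
        sol = solve_advection(bump, v, [300.0], domain_end=59.0, refine=2)
        assert np.all(np.isfinite(sol.values))
        assert sol.values.min() >= -1e-9 and sol.values.max() <= 0.6 + 1e-9


class TestFokkerPlanck:
    def test_diffusion_field_formula(self):
        v = _uniform_v(0.04)
        D = DiffusionField(velocity=v, delta_x=1.0)
        assert np.allclose(D(np.linspace(0, 100, 11)), 0.02)

    def test_tiny_delta_x_recovers_advection(self):
        k = RateFunction(breaks=np.array([0.0, 30.0, 60.0]),
                         values=np.array([0.004, 0.0]))
        v = velocity_from_rates(k)
        bump, _ = make_initial_condition(12.0, 20.0, 0.8, 60)
        adv = solve_advection(bump, v, [400.0], domain_end=59.0, refine=2)
        fp = solve_fokker_planck(bump, v, 1e-6, [400.0], domain_end=59.0, refine=2)
        assert np.max(np.abs(adv.values - fp.values)) < 1e-4

    def test_invalid_delta_x_rejected(self):
        v = _uniform_v(0.01)
        with pytest.raises(ValueError, match="delta_x"):
            solve_fokker_planck(lambda x: np.zeros_like(x), v, 0.0, [10.0],
                                domain_end=59.0)

    def test_constant_coefficient_gaussian_oracle(self):
        """Constant v, D: translated-spreading Gaussian closed form."""
        vel = 0.04
        delta_x = 1.0
        D = 0.5 * delta_x * vel
        v = _uniform_v(vel, top=200.0)
        sig0 = 8.0
        c0 = 60.0
        L0 = lambda x: 0.5 * np.exp(-((x - c0) ** 2) / (2 * sig0**2))
        t = 400.0
        sol = solve_fokker_planck(L0, v, delta_x, [t], domain_end=200.0, refine=8)
        sig_t = np.sqrt(sig0**2 + 2 * D * t)
        exact = 0.5 * (sig0 / sig_t) * np.exp(
            -((sol.x - c0 - vel * t) ** 2) / (2 * sig_t**2))
        assert np.max(np.abs(sol.values[0] - exact)) < 1e-3


class TestCharacteristics:
    def test_zero_velocity_vertical_lines(self):
        v = _uniform_v(0.0, top=50.0)
        traj = characteristic_curves(v, [5.0, 20.0], [0.0, 100.0, 400.0])
        assert np.allclose(traj[0], 5.0)
        assert np.allclose(traj[1], 20.0)

    def test_linear_velocity_exponential(self):
        k = RateFunction(breaks=np.array([0.0, 200.0]), values=np.array([0.005]))
        v = velocity_from_rates(k)
        ts = np.array([0.0, 100.0, 200.0])
        traj = characteristic_curves(v, [4.0], ts)
        assert np.allclose(traj[0], 4.0 * np.exp(0.005 * ts), rtol=1e-6)

    def test_piecewise_linear_matches_fine_rk4_oracle(self):
        k = RateFunction(breaks=np.array([0.0, 15.0, 40.0, 80.0]),
                         values=np.array([0.002, 0.006, 0.0]))
        v = velocity_from_rates(k)
        t_end = 500.0
        traj = characteristic_curves(v, [8.0], [t_end])
        # independent fixed-step RK4 oracle
        x = 8.0
        h = 0.01
        for _ in range(int(t_end / h)):
            k1 = v(x); k2 = v(x + 0.5 * h * k1)
            k3 = v(x + 0.5 * h * k2); k4 = v(x + h * k3)
            x += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert traj[0, 0] == pytest.approx(x, abs=1e-6)

    def test_solution_constant_along_curves(self):
        k = RateFunction(breaks=np.array([0.0, 30.0, 60.0]),
                         values=np.array([0.004, 0.0]))
        v = velocity_from_rates(k)
        bump, _ = make_initial_condition(12.0, 24.0, 0.8, 60)
        times = [0.0, 300.0]
        x0 = 14.0
        traj = characteristic_curves(v, [x0], times)
        sol = solve_advection(bump, v, [300.0], domain_end=59.0, refine=8)
        val_end = np.interp(traj[0, 1], sol.x, sol.values[0])
        assert val_end == pytest.approx(bump(np.array([x0]))[0], abs=0.03)


class TestDiscreteContinuumGap:
    def test_zero_rates_all_gaps_zero(self):
        k = RateFunction(breaks=np.array([0.0, 30.0]), values=np.array([0.0]))
        bump, _ = make_initial_condition(10.0, 12.0, 0.5, 30)
        gap = discrete_continuum_gap(k, bump, [200.0], n_cells=30)
        assert gap["adv_vs_master"][0] < 1e-10
        assert gap["fp_vs_master"][0] < 1e-10

    def test_fokker_planck_closer_near_front(self):
        """Finite-cell-size correction beats pure advection against the master eq."""
        k = RateFunction(breaks=np.array([0.0, 30.0, 60.0]),
                         values=np.array([0.005, 0.0]))
        bump, _ = make_initial_condition(12.0, 20.0, 0.8, 60)
        gap = discrete_continuum_gap(k, bump, [400.0], n_cells=60, refine=2)
        assert gap["fp_vs_master"][0] <= gap["adv_vs_master"][0]

    def test_refinement_improves_each_continuum_solver(self):
        """Halving dx shrinks each solver's error against its own limit.

        The advection solver is checked against the characteristics closed
        form (backtrace oracle); the Fokker-Planck solver against the master
        equation it is the modified equation of.
        """
        k = RateFunction(breaks=np.array([0.0, 30.0, 60.0]),
                         values=np.array([0.004, 0.0]))
        bump, _ = make_initial_condition(12.0, 24.0, 0.8, 60)
        t = 400.0
        g2 = discrete_continuum_gap(k, bump, [t], n_cells=60, refine=2)
        g4 = discrete_continuum_gap(k, bump, [t], n_cells=60, refine=4)
        assert g4["fp_vs_master"][0] <= g2["fp_vs_master"][0] + 1e-3
        v = velocity_from_rates(k)
        # backtrace oracle: integrate characteristics with the sign of v flipped
        vneg = VelocityField(knots=v.knots, v_knots=-v.v_knots)
        errs = []
        for refine in (2, 4):
            sol = solve_advection(bump, v, [t], domain_end=59.0, refine=refine)
            back = characteristic_curves(vneg, sol.x, [t])
            errs.append(np.max(np.abs(sol.values[0] - bump(back[:, 0]))))
        assert errs[1] < errs[0]
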