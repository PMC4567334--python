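"""Ensemble solver: conservation, advection, steady states, equivalences."""

import numpy as np
import pytest
from dataclasses import replace

from xbgroup.kinetics import RateSystem
from xbgroup.params import MechanicsConstants
from xbgroup.solver import (
    EnsembleDensity,
    SolverConfig,
    XGrid,
    advect,
    equilibrium_density,
    init_density,
    integrate,
    integrate_isometric,
    reaction_step,
    steady_state,
)
from conftest import random_params


class TestGridAndInit:
    def test_grid_covers_one_period(self):
        g = XGrid(36, 36.0)
        assert g.dx == pytest.approx(1.0)
        assert g.x[0] == pytest.approx(-18.0 + g.dx / 2)
        assert g.x[-1] == pytest.approx(18.0 - g.dx / 2)
        assert np.allclose(g.x, -g.x[::-1])  # symmetric about the origin

    def test_too_coarse_grid_rejected(self):
        with pytest.raises(ValueError):
            XGrid(8, 36.0)

    def test_init_density_all_unbound(self, grid):
        n = init_density(grid, 3)
        np.testing.assert_allclose(n.column_sums(), 1.0)
        assert n.values[0].sum() == grid.n_points
        assert n.values[1:].sum() == 0.0


class TestReactionStep:
    def test_column_sums_of_derivative_vanish(self, params_q3, grid, rng):
        rs = RateSystem(params_q3, grid.x)
        vals = rng.random((rs.n_states, grid.n_points))
        vals /= vals.sum(axis=0, keepdims=True)
        dn = reaction_step(EnsembleDensity(vals, grid), rs, 25.0, 1.05)
        # exact pairwise cancellation up to roundoff on the largest fluxes
        scale = np.abs(rs.rates(25.0, 1.05)).max()
        np.testing.assert_allclose(dn.sum(axis=0), 0.0, atol=1e-13 * scale)

    def test_two_state_relaxation_to_closed_form(self, params_q1, grid):
        """One site with only Ca binding active relaxes toward the
        two-state equilibrium n_W = k+Ca/(k+Ca + k-)."""
        rs = RateSystem(params_q1, grid.x)
        n = init_density(grid, 1, rs.n_states)
        dn = reaction_step(n, rs, 30.0, 1.05)
        # at t = T_p the T->W flux is f_ca*p1*amplitude, T->S2 is tiny
        from xbgroup.kinetics import ca_transient, p_value

        k_on = rs.params.rates.f_ca * float(
            p_value(("T", "W_Ca"), 1.05, rs.params.lengths)
        ) * float(ca_transient(30.0, rs.params.ca))
        from xbgroup.states import state_energy

        g_w = rs.params.profiles.g_w
        from xbgroup.states import GroupState, transition_delta_tm

        h = np.exp(0.0)  # forward Ca binding carries no tropomyosin factor
        expected = k_on * np.exp(-0.5 * g_w) * h
        np.testing.assert_allclose(dn[1], expected, rtol=1e-10)


class TestAdvect:
    def test_zero_velocity_is_identity(self, params_q1, grid, rng):
        vals = rng.random((5, grid.n_points))
        n = EnsembleDensity(vals.copy(), grid)
        out = advect(n, 0.0, 1.0)
        np.testing.assert_array_equal(out.values, vals)

    def test_full_cell_shift_is_exact_roll(self, grid, rng):
        vals = rng.random((5, grid.n_points))
        n = EnsembleDensity(vals.copy(), grid)
        out = advect(n, grid.dx, 1.0)  # CFL = 1
        np.testing.assert_allclose(out.values, np.roll(vals, 1, axis=1), atol=1e-14)
        back = advect(out, -grid.dx, 1.0)
        np.testing.assert_allclose(back.values, vals, atol=1e-13)

    def test_mass_conservation_periodic(self, grid, rng):
        vals = rng.random((5, grid.n_points))
        n = EnsembleDensity(vals.copy(), grid)
        out = advect(n, 3.7, 1.0)  # fractional shift with substeps
        np.testing.assert_allclose(
            out.values.sum(axis=1), vals.sum(axis=1), rtol=1e-12
        )

    def test_reset_to_unbound_feeds_inflow(self, grid):
        vals = np.zeros((5, grid.n_points))
        vals[3, :] = 1.0  # all strong-binding
        n = EnsembleDensity(vals, grid)
        out = advect(n, grid.dx, 1.0, policy="reset-to-unbound")
        # inflow cell at the left boundary becomes unbound
        assert out.values[0, 0] == pytest.approx(1.0)
        assert out.values[3, 0] == pytest.approx(0.0)


class TestIntegrate:
    def test_pure_translation_with_zero_rates(self, params_q1, grid):
        """With all reactions off the solution is the method-of-characteristics
        translation of the initial profile."""
        from xbgroup.params import ReactionRates

        p = replace(
            params_q1,
            rates=ReactionRates(
                f_ca=0.0,
                f_nodes={
                    k: tuple(0.0 for _ in v)
                    for k, v in params_q1.rates.f_nodes.items()
                },
            ),
        )
        rs = RateSystem(p, grid.x)
        vals = np.zeros((rs.n_states, grid.n_points))
        vals[0] = 1.0
        vals[4] = np.exp(-0.5 * (grid.x / 4.0) ** 2)  # bump in S2
        vals /= vals.sum(axis=0, keepdims=True)
        n0 = EnsembleDensity(vals.copy(), grid)
        v = grid.dx  # one cell per ms, CFL = 1: upwind is exact
        times, dens = integrate(
            n0, (0.0, 5.0), lambda t: 1.0, lambda t: v, p, SolverConfig(), rs
        )
        target = np.roll(vals, 5, axis=1)
        # the split advection (half-CFL substeps) adds first-order numerical
        # diffusion, so the translated profile is matched only approximately,
        # while total mass per state is exact
        assert np.max(np.abs(dens[-1] - target)) < 0.05
        np.testing.assert_allclose(
            dens[-1].sum(axis=1), vals.sum(axis=1), rtol=1e-10
        )
        assert np.argmax(dens[-1][4]) == np.argmax(target[4])

    def test_isometric_normalization_and_positivity(self, params_q1, grid):
        rs = RateSystem(params_q1, grid.x)
        n0 = init_density(grid, 1, rs.n_states)
        times, dens = integrate_isometric(
            n0, (0.0, 120.0), 1.05, params_q1, SolverConfig(), rs
        )
        assert np.max(np.abs(dens.sum(axis=1) - 1.0)) < 1e-8
        assert dens.min() > -1e-10

    def test_integrate_matches_isometric_fast_path(self, params_q1, grid):
        rs = RateSystem(params_q1, grid.x)
        n0 = init_density(grid, 1, rs.n_states)
        cfg = SolverConfig(rtol=1e-9, atol=1e-13)
        t1, d1 = integrate(
            n0, (0.0, 40.0), lambda t: 1.05, lambda t: 0.0, params_q1, cfg, rs
        )
        t2, d2 = integrate_isometric(n0, (0.0, 40.0), 1.05, params_q1, cfg, rs)
        np.testing.assert_allclose(d1[-1], d2[-1], atol=1e-7)


class TestSteadyState:
    def test_two_state_closed_form(self, params_q1, grid):
        """With only the calcium on/off reaction active, the stationary
        T<->W pair satisfies the bimolecular equilibrium
        n_W/n_T = Ca * exp(-dG) exactly (no cycles, no net flux)."""
        from xbgroup.params import ReactionRates

        p = replace(
            params_q1,
            rates=ReactionRates(
                f_ca=params_q1.rates.f_ca,
                f_nodes={
                    k: tuple(1e-12 for _ in v)
                    for k, v in params_q1.rates.f_nodes.items()
                },
            ),
        )
        rs = RateSystem(p, grid.x)
        ca = 0.7
        ssd = steady_state(ca, 1.05, p, grid, rs)
        from xbgroup.states import GroupState, transition_delta_tm

        g_w = p.profiles.g_w
        dg_tm = transition_delta_tm(GroupState(("T",)), 0, "W_Ca", p.tm)
        expected = ca * np.exp(-(g_w + dg_tm))
        ratio = ssd.values[1] / ssd.values[0]
        np.testing.assert_allclose(ratio, expected, rtol=1e-8)

    def test_matches_boltzmann_oracle_when_undriven(self, grid, rng):
        """With the ATP drive off, the linear-solve stationary state equals
        the closed-form Boltzmann law with calcium fugacity."""
        p = random_params(rng, q=1)
        # strictly positive position factors keep the chain irreducible at
        # every grid point, so the stationary law is the unique equilibrium
        from xbgroup.params import ReactionRates

        p = replace(
            p,
            constants=MechanicsConstants(dg_atp=1e-300),
            rates=ReactionRates(
                f_ca=p.rates.f_ca,
                f_nodes={
                    k: tuple(max(x, 1e-9) for x in v)
                    for k, v in p.rates.f_nodes.items()
                },
            ),
        )
        rs = RateSystem(p, grid.x)
        for ca in (0.2, 1.0, 5.0):
            ssd = steady_state(ca, 1.05, p, grid, rs)
            eq = equilibrium_density(ca, 1.05, p, grid, rs)
            np.testing.assert_allclose(ssd.values, eq.values, atol=1e-9)

    def test_zero_ca_drains_to_unbound(self, params_q1, grid):
        ssd = steady_state(0.0, 1.05, params_q1, grid, params_q1 and None)
        assert np.all(ssd.values[0] > 0.99)

    def test_long_time_isometric_converges_to_steady_state(self, params_q1, grid):
        """Clamped-Ca dynamics relax onto the stationary solution."""
        from xbgroup.params import CaTransient, ReactionRates

        ca_level = 0.8
        moderate = ReactionRates(
            f_ca=0.2,
            f_nodes={
                k: tuple(0.2 for _ in v)
                for k, v in params_q1.rates.f_nodes.items()
            },
        )
        p = replace(
            params_q1,
            rates=moderate,
            ca=CaTransient(t_p=1e-3, t_d=1e9, amplitude=ca_level),
        )
        # after t_p the transient is ~constant at the amplitude for t << t_d
        rs = RateSystem(p, grid.x)
        n0 = init_density(grid, 1, rs.n_states)
        cfg = SolverConfig(rtol=1e-9, atol=1e-13)
        times, dens = integrate_isometric(n0, (0.0, 3000.0), 1.05, p, cfg, rs)
        ssd = steady_state(ca_level, 1.05, p, grid, rs)
        assert np.max(np.abs(dens[-1] - ssd.values)) < 1e-6


class TestCooperativityNull:
    def test_q3_marginals_equal_q1_without_coupling(self, grid, rng):
        """Zero tropomyosin energies decouple the sites: the q=3 per-site
        marginal dynamics equal the q=1 dynamics exactly."""
        p1 = random_params(rng, q=1, coupled=False)
        p3 = p1.with_q(3)
        cfg = SolverConfig(rtol=1e-10, atol=1e-14)
        rs1 = RateSystem(p1, grid.x)
        rs3 = RateSystem(p3, grid.x)
        n1 = init_density(grid, 1, rs1.n_states)
        n3 = init_density(grid, 3, rs3.n_states)
        t1, d1 = integrate_isometric(n1, (0.0, 60.0), 1.05, p1, cfg, rs1)
        t3, d3 = integrate_isometric(n3, (0.0, 60.0), 1.05, p3, cfg, rs3)
        # per-site marginal of the middle site
        marg = np.zeros_like(d1)
        digits = rs3.digits
        for s in range(5):
            marg[:, s, :] = d3[:, digits[:, 1] == s, :].sum(axis=1)
        assert np.max(np.abs(marg - d1)) < 1e-6


class TestGridConvergence:
    def test_stress_trace_converges_under_refinement(self, params_q1):
        """Doubling the position grid from 64 to 128 points changes the
        isometric stress trace by under 1% in sup norm (first-order scheme,
        but the reaction term is local in x and the profiles are smooth)."""
        from xbgroup.kinetics import RateSystem
        from xbgroup.protocols import ProtocolSpec, run_isometric

        traces = {}
        for n in (64, 128):
            g = XGrid(n, params_q1.tm.d)
            r = run_isometric(
                ProtocolSpec(l_ed=1.05, beat_period=200.0), params_q1, grid=g
            )
            traces[n] = r.sigma_a
        diff = np.max(np.abs(traces[64] - traces[128]))
        assert diff < 0.01 * np.max(np.abs(traces[128]))
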