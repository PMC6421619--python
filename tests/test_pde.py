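"""Spatial discretisation, boundary handling and stiff time integration."""

import numpy as np
import pytest

from chondrosim.kinetics import reaction_terms
from chondrosim.params import default_dimensionless
from chondrosim.pde import (
    FIELDS,
    Grid,
    State,
    assemble_rhs,
    integrate,
    richardson_order,
)

P = default_dimensionless()


def uniform_state(n_nodes, c_s=0.0, c_c=0.0, n=1.0, m=1e-4, g=0.0, b=0.0):
    return State(*(np.full(n_nodes, v) for v in (c_s, c_c, n, m, g, b)))


def zero_reactions(p):
    """Parameter set with every reaction constant switched off.

    Matrix production has unit coefficient in the dimensionless system, so
    tests using this must also keep the chondrocyte profile at zero.
    """
    return p.replace(skip_validation=True, p10=0.0, p2=0.0, p3=0.0, p40=0.0,
                     p400=0.0, p5=0.0, p6=0.0, p7=0.0, p9=0.0, p11=0.0,
                     p12=0.0, p13=0.0)


class TestGridAndState:
    def test_grid_geometry(self):
        g = Grid(101)
        assert g.x[0] == 0.0 and g.x[-1] == 1.0
        assert np.allclose(np.diff(g.x), g.h, atol=1e-14)
        with pytest.raises(ValueError):
            Grid(2)

    def test_state_vector_roundtrip(self):
        rng = np.random.default_rng(0)
        s = State(*(rng.uniform(size=11) for _ in FIELDS))
        s2 = State.from_vector(s.to_vector(), 11)
        for name in FIELDS:
            assert np.array_equal(getattr(s, name), getattr(s2, name))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            State(np.zeros(5), np.zeros(5), np.zeros(5),
                  np.zeros(4), np.zeros(5), np.zeros(5))


class TestAssembleRhs:
    def test_uniform_state_has_no_diffusion(self):
        grid = Grid(21)
        s = uniform_state(21, c_s=0.3, c_c=0.1, n=0.5, m=0.2, g=0.4, b=0.2)
        rhs = assemble_rhs(0.0, s.to_vector(), grid, P, bc_mode="all_no_flux")
        expected = np.concatenate([np.full(21, r) for r in
                                   reaction_terms(0.3, 0.1, 0.5, 0.2, 0.4, 0.2, P)])
        assert rhs == pytest.approx(expected, rel=1e-12, abs=1e-12)

    def test_no_cells_keeps_nutrient_at_reservoir(self):
        grid = Grid(21)
        s = uniform_state(21, n=1.0)
        rhs = assemble_rhs(0.0, s.to_vector(), grid, P, bc_mode="paper")
        dn = rhs.reshape(6, 21)[2]
        assert np.all(dn == 0.0)

    def test_matrix_spike_conserved_under_no_flux_diffusion(self):
        """The flux-form Laplacian conserves the trapezoidal integral."""
        n_nodes = 31
        grid = Grid(n_nodes)
        s = uniform_state(n_nodes, n=1.0, m=0.0)
        s.m[15] = 1.0  # interior spike; no cells, so no matrix production
        rhs = assemble_rhs(0.0, s.to_vector(), grid, P, bc_mode="all_no_flux")
        dm = rhs.reshape(6, n_nodes)[3]
        w = np.full(n_nodes, grid.h)
        w[0] = w[-1] = grid.h / 2
        assert float(w @ dm) == pytest.approx(0.0, abs=1e-14)

    def test_nonfinite_input_reports_field_and_node(self):
        grid = Grid(11)
        y = uniform_state(11).to_vector()
        y[2 * 11 + 4] = np.inf  # nutrient block, node 4
        with pytest.raises(FloatingPointError, match="'n' at node 4"):
            assemble_rhs(0.0, y, grid, P)

    def test_nonconforming_vector_rejected(self):
        with pytest.raises(ValueError, match="conform"):
            assemble_rhs(0.0, np.zeros(10), Grid(11), P)


class TestIntegrate:
    def test_pure_growth_factor_decay_closed_form(self):
        grid = Grid(11)
        s0 = uniform_state(11, g=P.g_init)
        traj = integrate(s0, [0.0, 0.5, 1.0], grid, P, bc_mode="all_no_flux",
                         rtol=1e-10, atol=1e-14)
        for i, t in enumerate(traj.times):
            expected = P.g_init * np.exp(-P.p11 * t)
            assert traj.states[i].g == pytest.approx(expected, rel=1e-6)

    def test_matches_zero_dimensional_rk4_oracle(self):
        """Uniform fields, no diffusion: the PDE solver must agree with an
        independent fixed-step RK4 integration of the reaction kinetics."""
        p = P.replace(DS0=0.0, DC0=0.0, Dn=0.0, Dm=0.0, Dg=0.0, Db=0.0)
        eps = 1e-3
        y = np.array([P.CS_init, P.CC_init, 1.0, P.m3, P.g_init, P.b_init])

        def f(y):
            return np.array(reaction_terms(*y, p, eps), dtype=float).ravel()

        h = 1e-4
        for _ in range(10_000):  # to t = 1
            k1 = f(y)
            k2 = f(y + 0.5 * h * k1)
            k3 = f(y + 0.5 * h * k2)
            k4 = f(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)

        grid = Grid(11)
        s0 = uniform_state(11, c_s=P.CS_init, c_c=P.CC_init, n=1.0,
                           m=P.m3, g=P.g_init, b=P.b_init)
        traj = integrate(s0, [0.0, 1.0], grid, p, eps=eps,
                         bc_mode="all_no_flux", rtol=1e-8, atol=1e-12)
        final = traj.states[-1]
        for i, name in enumerate(FIELDS):
            got = float(getattr(final, name)[5])
            denom = max(abs(y[i]), 1e-8)  # nutrient decays to ~0
            assert abs(got - y[i]) / denom < 1e-4, (name, got, y[i])

    def test_mass_conserved_with_reactions_off(self):
        n_nodes = 41
        grid = Grid(n_nodes)
        x = grid.x
        p = zero_reactions(P)
        s0 = State(
            c_s=0.2 + 0.1 * np.cos(np.pi * x),
            c_c=np.zeros(n_nodes),  # keeps matrix production inactive
            n=0.5 + 0.2 * np.cos(np.pi * x),
            m=0.3 + 0.1 * np.cos(3 * np.pi * x),
            g=0.4 + 0.2 * np.cos(np.pi * x),
            b=0.3 + 0.1 * np.cos(2 * np.pi * x),
        )
        traj = integrate(s0, [0.0, 0.5, 1.0], grid, p, bc_mode="all_no_flux",
                         rtol=1e-10, atol=1e-13)
        for name in FIELDS:
            mass0 = np.trapezoid(getattr(s0, name), x)
            for s in traj.states:
                assert np.trapezoid(getattr(s, name), x) == pytest.approx(
                    mass0, abs=1e-8)

    def test_time_stamps_must_increase_from_zero(self):
        grid = Grid(11)
        s0 = uniform_state(11)
        with pytest.raises(ValueError):
            integrate(s0, [0.0, 1.0, 1.0], grid, P)
        with pytest.raises(ValueError):
            integrate(s0, [0.5, 1.0], grid, P)


class TestScenarioSolutionProperties:
    def test_nutrient_maximum_principle(self, none_traj, both_traj):
        """No interior nutrient source and a unit reservoir: n never exceeds 1."""
        for traj in (none_traj, both_traj):
            assert float(np.max(traj.field_matrix("n"))) <= 1.0 + 1e-6

    def test_fields_remain_nonnegative_within_solver_tolerance(self, none_traj, both_traj):
        for traj in (none_traj, both_traj):
            atol = traj.solver_meta["atol"]
            for name in FIELDS:
                assert float(np.min(traj.field_matrix(name))) >= -10 * atol

    def test_mean_matrix_nondecreasing(self, none_traj, both_traj):
        for traj in (none_traj, both_traj):
            means = np.trapezoid(traj.field_matrix("m"), traj.grid.x, axis=1)
            assert np.all(np.diff(means) >= -1e-10)

    def test_matrix_bounded_by_capacity(self, none_traj, both_traj):
        # synthesis rate changes sign at m = 1/p81 = 1, an attracting bound
        for traj in (none_traj, both_traj):
            assert float(np.max(traj.field_matrix("m"))) <= 1.0 + 1e-3


class TestRichardsonOrder:
    def test_pure_diffusion_sinusoidal_decay_is_second_order(self):
        """Constant-coefficient diffusion of a cosine mode (no-flux
        compatible) must show the scheme's second-order accuracy."""
        p = zero_reactions(P)
        profiles = []
        for n_nodes in (21, 41, 81):
            grid = Grid(n_nodes)
            s0 = uniform_state(n_nodes, n=1.0)
            s0.m[:] = 0.5 + 0.4 * np.cos(np.pi * grid.x)
            traj = integrate(s0, [0.0, 1.0], grid, p, bc_mode="all_no_flux",
                             rtol=1e-11, atol=1e-14)
            profiles.append(traj.states[-1].m)
        order = richardson_order(*profiles)
        assert 1.8 < order < 2.2

    def test_uniform_profiles_raise_diagnostic(self):
        # identical (error-free) solutions cannot yield an order estimate
        with pytest.raises(ValueError, match="monotonically"):
            richardson_order(np.ones(11), np.ones(21), np.ones(41))

    def test_non_nested_grids_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            richardson_order(np.ones(11), np.ones(22), np.ones(41))
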