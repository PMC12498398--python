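"""Wertheim TPT1 engine: bond strengths, mass action, free energy, EOS,
Gibbs branches and coexistence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from azeopatch.graph import (
    MixtureDesign,
    SpeciesSpec,
    build_ideal_azeotrope_binary,
)
from azeopatch.wertheim import (
    BondStrengthMatrix,
    StatePoint,
    _Engine,
    chemical_potentials,
    compute_delta,
    coexistence,
    free_energy,
    gibbs_curve,
    hs_first_shell_g,
    ideal_azeotrope_X,
    pressure,
    solve_mass_action,
)


def _state(T, rho, x):
    return StatePoint(T=T, rho=rho, x=np.asarray(x, dtype=float))


class TestBondStrength:
    def test_nonbonding_pairs_have_zero_delta(self, n2c8_uniform):
        bs = compute_delta(n2c8_uniform, _state(0.1, 0.2, [0.5, 0.5]))
        adj = n2c8_uniform.bonding_adjacency()
        assert np.all(bs.delta_matrix[~adj] == 0.0)
        assert np.all(bs.delta_matrix[adj] > 0.0)
        assert np.allclose(bs.delta_matrix, bs.delta_matrix.T)

    def test_high_temperature_limit(self, n2c8_uniform):
        bs = compute_delta(n2c8_uniform, _state(1e6, 0.2, [0.5, 0.5]))
        assert np.max(bs.delta_matrix) < 1e-5

    @pytest.mark.parametrize("ghs", ["unity", "contact", "shell"])
    def test_delta_matches_quadrature_oracle(self, ideal_design, ghs):
        """Independent quadrature of (1/Vs) * angular^2 * 4 pi int g r^2 dr."""
        T, rho = 0.1, 0.2
        kf = ideal_design.kf
        Vs = np.pi / 6 * kf.sigma**3
        phi = rho * Vs

        def g(r):
            if ghs == "unity":
                return 1.0
            if ghs == "contact":
                return (1 - phi / 2) / (1 - phi) ** 3
            return float(hs_first_shell_g(np.array([r / kf.sigma]), phi)[0])

        shell, _ = integrate.quad(lambda r: g(r) * r**2, kf.sigma, kf.well_outer)
        expected = (
            (np.expm1(1.0 / T))
            * ((1 - kf.cos_theta_max) / 2) ** 2
            * 4 * np.pi * shell / Vs
        )
        bs = compute_delta(ideal_design, _state(T, rho, [0.5, 0.5]), ghs=ghs)
        got = bs.delta_matrix[0, 1]  # types 1-2 bond in the ideal design
        assert got == pytest.approx(expected, rel=2e-6)
        assert bs.details["ghs"] == ghs

    def test_py_shell_g_contact_value(self):
        # PY contact value g(sigma+) = (1 + eta/2) / (1 - eta)^2
        for eta in (0.05, 0.2, 0.4):
            got = hs_first_shell_g(np.array([1.0]), eta)[0]
            assert got == pytest.approx((1 + eta / 2) / (1 - eta) ** 2, rel=1e-10)


class TestMassAction:
    def test_no_bonding_gives_unity(self, hs_design):
        sol = solve_mass_action(hs_design, _state(0.1, 0.3, [0.4, 0.6]))
        assert np.allclose(sol.X, 1.0)
        assert sol.residual < 1e-12

    def test_closed_form_injected_delta(self, ideal_design):
        # phi * Delta = 2 for every bonding pair -> X = 0.5 at any x
        state = _state(0.1, 0.2, [0.3, 0.7])
        phi = 0.2 * np.pi / 6
        adj = ideal_design.bonding_adjacency()
        dm = np.where(adj, 2.0 / phi, 0.0)
        sol = solve_mass_action(ideal_design, state, delta=BondStrengthMatrix(dm))
        assert np.allclose(sol.X, 0.5, atol=1e-12)

    @pytest.mark.parametrize("x", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_ideal_design_matches_quadratic_root(self, ideal_design, x):
        state = _state(0.11, 0.3, [x, 1 - x])
        eng = _Engine(ideal_design, 0.11)
        phi = 0.3 * eng.Vs
        delta = eng.delta(phi)[0, 1]
        sol = solve_mass_action(ideal_design, state)
        assert np.allclose(sol.X, ideal_azeotrope_X(phi, delta), atol=1e-12)

    def test_bond_exclusive_equimolar_ns2(self, n2c8_uniform):
        state = _state(0.1, 0.25, [0.5, 0.5])
        sol = solve_mass_action(n2c8_uniform, state)
        assert np.ptp(sol.X) < 1e-12
        eng = _Engine(n2c8_uniform, 0.1)
        phi = 0.25 * eng.Vs
        delta = eng.delta(phi)[0, 4]  # 1-5 bonding pair
        X = sol.X[0]
        assert X + (phi / 2) * delta * X**2 - 1 == pytest.approx(0.0, abs=1e-12)

    def test_bond_exclusive_equimolar_ns3(self):
        # three species, two patches each, one exclusive partner per patch
        vec = np.array([[0, 0, 1.0], [0, 0, -1.0]])
        species = [
            SpeciesSpec(1, (1, 2), vec),
            SpeciesSpec(2, (3, 4), vec),
            SpeciesSpec(3, (5, 6), vec),
        ]
        order = (1, 2, 3, 4, 5, 6)
        idx = {t: i for i, t in enumerate(order)}
        mat = np.zeros((6, 6))
        for a, b in [(1, 3), (2, 5), (4, 6)]:
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = 1.0
        d3 = MixtureDesign(species=species, energy_matrix=mat)
        state = _state(0.1, 0.3, [1 / 3, 1 / 3, 1 / 3])
        sol = solve_mass_action(d3, state)
        assert np.ptp(sol.X) < 1e-12
        eng = _Engine(d3, 0.1)
        phi = 0.3 * eng.Vs
        delta = eng.delta(phi)[idx[1], idx[3]]
        X = sol.X[0]
        assert X + (phi / 3) * delta * X**2 - 1 == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(
        T=st.floats(0.08, 1.0),
        rho=st.floats(1e-4, 1.0),
        x=st.floats(0.0, 1.0),
    )
    def test_fixed_point_property(self, T, rho, x):
        """Any solved state satisfies the mass-action equation to 1e-12 with
        X in (0, 1]."""
        design = build_ideal_azeotrope_binary()
        sol = solve_mass_action(design, _state(T, rho, [x, 1 - x]))
        assert sol.residual < 1e-12
        assert np.all(sol.X > 0) and np.all(sol.X <= 1.0)


class TestFreeEnergy:
    def test_no_bonding_term_without_bonds(self, hs_design):
        fb = free_energy(hs_design, _state(0.2, 0.3, [0.5, 0.5]))
        assert fb.f_bonding == 0.0
        assert fb.f_total == fb.f_ideal + fb.f_hs

    def test_hs_term_vanishes_at_zero_density(self, hs_design):
        fb = free_energy(hs_design, _state(0.2, 1e-9, [0.5, 0.5]))
        assert abs(fb.f_hs) < 1e-7

    def test_bonding_term_direct_substitution(self, ideal_design):
        # four patches per particle at X = 1/2:
        # f_b = 4 (ln 1/2 - 1/4) + 2 = 4 ln 1/2 + 1
        eng = _Engine(ideal_design, 0.1)
        X = np.full(8, 0.5)
        _, _, f_b = eng.f_pieces(0.3, np.array([0.5, 0.5]), X)
        assert f_b == pytest.approx(4 * np.log(0.5) + 1.0, abs=1e-12)
        assert f_b == pytest.approx(-1.7726, abs=1e-4)

    def test_bonding_is_attractive(self, ideal_design, n2c8_uniform):
        for d in (ideal_design, n2c8_uniform):
            fb = free_energy(d, _state(0.09, 0.4, [0.5, 0.5]))
            assert fb.f_bonding < 0.0

    def test_unphysical_packing_rejected(self, hs_design):
        with pytest.raises(ValueError, match="packing"):
            free_energy(hs_design, _state(0.2, 2.0, [0.5, 0.5]))

    def test_azeotropic_reduction_to_single_component(self, ideal_design):
        """At an azeotropic solution X_alpha = X the bonding free energy
        equals the single-component expression with valence-weighted x."""
        state = _state(0.1, 0.3, [0.3, 0.7])
        sol = solve_mass_action(ideal_design, state)
        X = sol.X[0]
        fb = free_energy(ideal_design, state)
        gam = ideal_design.valences
        expected = float(np.sum(state.x * gam) * (np.log(X) - X / 2 + 0.5))
        assert fb.f_bonding == pytest.approx(expected, abs=1e-12)


def _richardson(f, x0, h0):
    """Richardson-extrapolated central difference."""
    d1 = (f(x0 + h0) - f(x0 - h0)) / (2 * h0)
    h = h0 / 2
    d2 = (f(x0 + h) - f(x0 - h)) / (2 * h)
    return (4 * d2 - d1) / 3


class TestDerivatives:
    @pytest.mark.parametrize("ghs", ["unity", "contact", "shell"])
    def test_pressure_matches_numerical_derivative(self, n2c8_tuned, ghs):
        T, rho, x = 0.1, 0.35, np.array([0.45, 0.55])

        def f(r):
            return free_energy(n2c8_tuned, _state(T, r, x), ghs=ghs).f_total

        P_num = T * rho**2 * _richardson(f, rho, 1e-4)
        P_ana = pressure(n2c8_tuned, _state(T, rho, x), ghs=ghs)
        assert P_ana == pytest.approx(P_num, abs=1e-6)

    def test_mu_matches_numerical_derivative(self, n2c8_tuned):
        T, rho, xx = 0.1, 0.35, 0.45

        def f(r, x1):
            return free_energy(n2c8_tuned, _state(T, r, [x1, 1 - x1])).f_total

        dfdr = _richardson(lambda r: f(r, xx), rho, 1e-4)
        dfdx = _richardson(lambda x1: f(rho, x1), xx, 1e-5)
        a = f(rho, xx)
        mu_num = T * np.array(
            [a + rho * dfdr + (1 - xx) * dfdx, a + rho * dfdr - xx * dfdx]
        )
        mu_ana = chemical_potentials(n2c8_tuned, _state(T, rho, [xx, 1 - xx]))
        assert np.allclose(mu_ana, mu_num, atol=1e-6)

    def test_gibbs_duhem_random_states(self, n2c8_tuned):
        rng = np.random.default_rng(7)
        for _ in range(20):
            T = rng.uniform(0.09, 0.5)
            rho = rng.uniform(0.01, 0.8)
            xx = rng.uniform(0.05, 0.95)
            state = _state(T, rho, [xx, 1 - xx])
            f = free_energy(n2c8_tuned, state).f_total
            P = pressure(n2c8_tuned, state)
            mu = chemical_potentials(n2c8_tuned, state)
            lhs = P / (rho * T) + f
            rhs = float(np.dot(state.x, mu)) / T
            assert abs(lhs - rhs) < 1e-8

    def test_hard_sphere_virial_limit(self, hs_design):
        rho = 1e-3
        phi = rho * np.pi / 6
        P = pressure(hs_design, _state(1.0, rho, [0.5, 0.5]))
        assert P / rho == pytest.approx(1 + 4 * phi, abs=1e-5)

    def test_species_exchange_symmetry_of_mu(self, n2c8_uniform, ideal_design):
        for d in (n2c8_uniform, ideal_design):
            mu = chemical_potentials(d, _state(0.1, 0.3, [0.5, 0.5]))
            assert mu[0] == pytest.approx(mu[1], abs=1e-10)


class TestGibbsCurveAndCoexistence:
    def test_supercritical_single_branch(self, n2c8_uniform):
        c = gibbs_curve(n2c8_uniform, 0.3, 0.05, np.linspace(0.1, 0.9, 9))
        assert c.n_branches == 1
        assert np.allclose(c.rho_vapor, c.rho_liquid)

    def test_subcritical_two_branches_cross(self, n2c8_uniform):
        c = gibbs_curve(n2c8_uniform, 0.08, 3.5e-4, np.linspace(0.05, 0.95, 41))
        assert c.n_branches == 2
        assert np.all(c.rho_vapor <= c.rho_liquid + 1e-12)
        dg = c.g_liquid - c.g_vapor
        assert np.nanmin(dg) < 0 < np.nanmax(dg)  # branches cross

    def test_ideal_design_flat_branches(self, ideal_design):
        """Composition independence of the azeotropic solution: both
        branches are flat in x once the ideal mixing entropy is removed,
        and their difference is flat outright."""
        xs = np.linspace(0.05, 0.95, 19)
        c = gibbs_curve(ideal_design, 0.08, 2e-5, xs)
        assert c.n_branches == 2
        mix = xs * np.log(xs) + (1 - xs) * np.log(1 - xs)
        assert np.ptp(c.g_vapor - mix) < 1e-8
        assert np.ptp(c.g_liquid - mix) < 1e-8
        assert np.ptp(c.g_liquid - c.g_vapor) < 1e-8

    def test_coexistence_equal_chemical_potentials(self, n2c8_tuned):
        cp = coexistence(n2c8_tuned, 0.08, 5.0e-5)
        mu_v = chemical_potentials(
            n2c8_tuned, _state(0.08, cp.rho_vapor, [cp.x_vapor, 1 - cp.x_vapor])
        )
        mu_l = chemical_potentials(
            n2c8_tuned, _state(0.08, cp.rho_liquid, [cp.x_liquid, 1 - cp.x_liquid])
        )
        assert np.allclose(mu_v, mu_l, atol=1e-7)
        assert cp.rho_vapor < cp.rho_liquid
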