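"""Kern-Frenkel Monte Carlo engine: pair energy, moves, ensembles,
conservation laws and two-particle analytics."""

import numpy as np
import pytest

from azeopatch.fixtures import bonded_dimer, hard_sphere_design
from azeopatch.graph import build_ideal_azeotrope_binary
from azeopatch.mc_engine import (
    GibbsState,
    MoveSchedule,
    avb_acceptance_factor,
    block_average,
    make_initial_config,
    pair_energy,
    run_gcmc,
    run_gibbs,
    run_npt,
    run_nvt,
)
from azeopatch.wertheim import StatePoint, chemical_potentials, pressure


def _quat_about(axis, angle):
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    return np.array([np.cos(angle / 2), *(np.sin(angle / 2) * axis)])


def _quat_mul(a, b):
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ]
    )


class TestPairEnergy:
    def test_hard_core_overlap(self, ideal_design):
        st = bonded_dimer(ideal_design)
        e = pair_energy(
            st.positions[0], st.positions[0] + [0.9, 0, 0],
            st.orientations[0], st.orientations[1], 0, 0, ideal_design,
        )
        assert e == np.inf

    def test_aligned_bond_energy(self, ideal_design, n2c8_tuned):
        assert bonded_dimer(ideal_design).energy == -1.0
        # pair_index 1 of tuned N2c8 is the 2-2 self-loop at eps'
        assert bonded_dimer(n2c8_tuned, pair_index=1).energy == -1.35

    def test_outside_well_no_energy(self, ideal_design):
        st = bonded_dimer(ideal_design)
        r1 = st.positions[0] + [1.25, 0, 0]  # beyond sigma + delta
        e = pair_energy(
            st.positions[0], r1, st.orientations[0], st.orientations[1],
            0, 0, ideal_design,
        )
        assert e == 0.0

    def test_patch_tilt_beyond_cone_kills_bond(self, ideal_design):
        st = bonded_dimer(ideal_design)
        # tilt particle 1 so its patch-axis cosine drops to ~0.9696 < 0.98
        tilt = _quat_about([0, 1, 0], np.arccos(0.9696))
        q1 = _quat_mul(tilt, st.orientations[1])
        e = pair_energy(
            st.positions[0], st.positions[1], st.orientations[0], q1,
            0, 0, ideal_design,
        )
        assert e == 0.0

    def test_symmetry_under_particle_exchange(self, ideal_design):
        rng = np.random.default_rng(3)
        for _ in range(20):
            r0 = rng.random(3) * 3
            r1 = r0 + rng.normal(size=3) * 0.6
            q = rng.normal(size=(2, 4))
            q /= np.linalg.norm(q, axis=1, keepdims=True)
            s0, s1 = rng.integers(0, 2, size=2)
            e01 = pair_energy(r0, r1, q[0], q[1], s0, s1, ideal_design)
            e10 = pair_energy(r1, r0, q[1], q[0], s1, s0, ideal_design)
            assert e01 == e10


class TestInitialConfig:
    def test_counts_and_no_overlap(self, ideal_design):
        st = make_initial_config([40, 10], 0.2, ideal_design, seed=5)
        assert st.n == 50
        assert np.bincount(st.species).tolist() == [40, 10]
        st.validate(ideal_design)  # raises on overlap / bad quaternions

    def test_determinism(self, ideal_design):
        a = make_initial_config([20, 20], 0.25, ideal_design, seed=9)
        b = make_initial_config([20, 20], 0.25, ideal_design, seed=9)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.orientations, b.orientations)
        assert np.array_equal(a.species, b.species)

    def test_too_dense_rejected(self, ideal_design):
        with pytest.raises(ValueError, match="packing"):
            make_initial_config([200, 200], 0.9, ideal_design, seed=1)


class TestEnergyBookkeeping:
    def test_incremental_energy_audit(self, ideal_design):
        st = make_initial_config([32, 32], 0.3, ideal_design, seed=2)
        res = run_nvt(
            st, ideal_design, T=0.12, sweeps=2000, stride=500,
            schedule=MoveSchedule(seed=3, avb=0.3, translate=0.35, rotate=0.35),
        )
        assert res.max_energy_drift <= 1e-9 * max(1.0, abs(res.state.energy))

    def test_state_energy_cache_validation(self, ideal_design):
        st = bonded_dimer(ideal_design)
        st.energy = st.energy + 1.0  # corrupt the cache
        with pytest.raises(ValueError, match="cached energy"):
            st.validate(ideal_design)


class TestAVB:
    def test_detailed_balance_identity(self):
        """Forced in<->out acceptance ratios multiply to exactly 1."""
        V, vin, dE, T = 512.0, 0.122, -1.0, 0.1
        for n_in, n_out, cnt in [(0, 120, 1), (3, 60, 2), (10, 5, 1)]:
            r_in = avb_acceptance_factor(
                n_in, n_out, V, vin, True, dE, T, aligned_count=cnt
            )
            r_out = avb_acceptance_factor(
                n_in + 1, n_out - 1, V, vin, False, -dE, T, aligned_count=cnt
            )
            assert r_in * r_out == pytest.approx(1.0, rel=1e-12)

    def test_null_interaction_invariance(self, hs_design):
        """With all eps = 0 the AVB move must not bias sampling: NPT mean
        density with and without AVB agrees within statistics."""
        P, T = 0.3, 1.0
        means = []
        for avb, seed in ((0.0, 11), (0.3, 12)):
            st = make_initial_config([32, 32], 0.2, hs_design, seed=seed)
            sched = MoveSchedule(
                seed=seed, avb=avb, translate=0.5 - avb / 2, rotate=0.5 - avb / 2,
                volume=0.04,
            )
            res = run_npt(st, hs_design, T, P, sched, sweeps=6000, stride=100)
            obs = res.observables
            means.append(block_average(obs.rho[obs.sweep > 1500].to_numpy()))
        (m1, s1), (m2, s2) = means
        assert abs(m1 - m2) < 3.5 * np.hypot(s1, s2) + 1e-9

    def test_dimer_bond_probability_matches_integration_oracle(self, ideal_design):
        """Equilibrium bond probability of an isolated pair vs Monte Carlo
        integration of the two-particle configurational integral over the
        Kern-Frenkel bond volume."""
        T, L = 0.12, 2.6
        kf = ideal_design.kf
        V = L**3

        # oracle: sample relative positions uniformly in the well shell and
        # orientations uniformly; outside the shell the weight is exactly 1
        rng = np.random.default_rng(42)
        m = 4_000_000
        r3 = rng.uniform(kf.sigma**3, kf.well_outer**3, m)
        r = np.cbrt(r3)
        u = rng.normal(size=(m, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)

        def rand_quat(k):
            v = rng.random((k, 3))
            a, b = np.sqrt(1 - v[:, 0]), np.sqrt(v[:, 0])
            return np.column_stack(
                [a * np.sin(2 * np.pi * v[:, 1]), a * np.cos(2 * np.pi * v[:, 1]),
                 b * np.sin(2 * np.pi * v[:, 2]), b * np.cos(2 * np.pi * v[:, 2])]
            )

        def rotate(q, vec):
            w, x, y, z = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
            t = 2 * np.cross(q[:, 1:], vec[None, :])
            return vec[None, :] + w[:, None] * t + np.cross(q[:, 1:], t)

        q1, q2 = rand_quat(m), rand_quat(m)
        # both particles species A: compatible ordered patch pairs of the
        # ideal design are (1,2), (2,1), (3,4), (4,3) = local (0,1),(1,0),(2,3),(3,2)
        pv = ideal_design.species[0].patch_vectors
        aligned = np.zeros(m, dtype=bool)
        cos1 = {a: np.einsum("ij,ij->i", rotate(q1, pv[a]), u) for a in range(4)}
        cos2 = {b: -np.einsum("ij,ij->i", rotate(q2, pv[b]), u) for b in range(4)}
        for a, b in [(0, 1), (1, 0), (2, 3), (3, 2)]:
            aligned |= (cos1[a] > kf.cos_theta_max) & (cos2[b] > kf.cos_theta_max)
        v_shell = 4 * np.pi / 3 * (kf.well_outer**3 - kf.sigma**3)
        v_core = 4 * np.pi / 3 * kf.sigma**3
        w_shell = np.where(aligned, np.exp(1.0 / T), 1.0)
        z_shell = v_shell * w_shell.mean()
        z_bond = v_shell * (w_shell * aligned).mean()
        p_oracle = z_bond / (V - v_core - v_shell + z_shell)
        se_oracle = (
            v_shell * (w_shell * aligned).std() / np.sqrt(m)
            / (V - v_core - v_shell + z_shell)
        )

        # simulation: fraction of time the isolated pair is bonded
        st = bonded_dimer(ideal_design)
        st.box = L
        st.positions = np.mod(st.positions, L)
        st.energy = st.compute_energy(ideal_design)
        res = run_nvt(
            st, ideal_design, T, sweeps=60000, stride=20,
            schedule=MoveSchedule(
                seed=77, avb=0.4, translate=0.3, rotate=0.3,
                max_disp=0.8, max_rot=1.5,
            ),
        )
        e_series = res.observables.E.to_numpy()
        p_sim, se_sim = block_average((e_series < -0.5).astype(float), n_blocks=10)
        assert p_sim == pytest.approx(
            p_oracle, abs=max(4 * np.hypot(se_sim, se_oracle), 0.05 * p_oracle + 0.01)
        )


class TestEnsembles:
    def test_npt_hard_sphere_eos(self, hs_design):
        """eps = 0 NPT density agrees with the theory-side hard-sphere EOS
        (the same f_hs used by the Wertheim module) within 2%."""
        phi_target = 0.1
        rho_t = phi_target * 6 / np.pi
        P = pressure(hs_design, StatePoint(T=1.0, rho=rho_t, x=np.array([0.5, 0.5])))
        st = make_initial_config([32, 32], 0.6 * rho_t, hs_design, seed=4)
        res = run_npt(
            st, hs_design, 1.0, P,
            MoveSchedule(seed=5, avb=0.0, translate=0.5, rotate=0.46, volume=0.04),
            sweeps=8000, stride=100,
        )
        obs = res.observables
        m, se = block_average(obs.phi[obs.sweep > 2000].to_numpy())
        assert m == pytest.approx(phi_target, rel=0.02)

    def test_gibbs_conservation_laws(self, ideal_design):
        sa = make_initial_config([26, 6], 0.2, ideal_design, seed=6)
        sb = make_initial_config([26, 6], 0.2, ideal_design, seed=7)
        g = GibbsState(box_a=sa, box_b=sb)
        n0, v0 = g.n_total, g.v_total
        tot0 = g.species_totals()
        res = run_gibbs(
            g, ideal_design, T=0.12, sweeps=3000, stride=300,
            schedule=MoveSchedule(seed=8),
        )
        obs = res.observables
        assert np.all(obs.N_a + obs.N_b == n0)
        assert np.allclose(obs.V_a + obs.V_b, v0, rtol=1e-12)
        assert res.state.species_totals().tolist() == tot0.tolist()
        assert res.max_energy_drift <= 1e-9 * max(
            1.0, abs(res.state.box_a.energy), abs(res.state.box_b.energy)
        )

    def test_gcmc_empty_limit_and_hs_density(self, hs_design):
        # mu -> -inf: box empties
        st = make_initial_config([8, 8], 0.1, hs_design, seed=9)
        res = run_gcmc(
            st, hs_design, T=1.0, mu=-12.0,
            schedule=MoveSchedule(seed=10, exchange=0.5), sweeps=3000, stride=100,
        )
        assert res.observables.rho.iloc[-1] < 0.01
        # moderate mu: density matches the theory-side EOS inversion
        rho_t = 0.15
        mu_t = chemical_potentials(
            hs_design, StatePoint(T=1.0, rho=rho_t, x=np.array([0.5, 0.5]))
        )
        st = make_initial_config([12, 12], 0.1, hs_design, seed=11)
        res = run_gcmc(
            st, hs_design, T=1.0, mu=np.array(mu_t),
            schedule=MoveSchedule(seed=12, exchange=0.3), sweeps=12000, stride=100,
        )
        obs = res.observables
        m, se = block_average(obs.rho[obs.sweep > 3000].to_numpy())
        assert m == pytest.approx(rho_t, rel=0.05)
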