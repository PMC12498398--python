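"""Structure factors, Ornstein-Zernike extrapolation and the
Kirkwood-Buff chemical-potential integral."""

import numpy as np
import pytest

from azeopatch.fixtures import oz_curve
from azeopatch.mc_engine import Frame
from azeopatch.s0 import (
    ChemicalPotentialCurve,
    StructureFactorData,
    excess_mu,
    oz_fit,
    partial_structure_factors,
    total_mu,
)


def _gas_frames(n_frames, n, L, x=1.0, seed=0, pair_fraction=0.0, pair_sep=0.3):
    """Ideal-gas frames, optionally with a fraction of particles placed as
    tight pairs (a known pair-correlated process)."""
    rng = np.random.default_rng(seed)
    frames = []
    na = int(round(x * n))
    species = np.array([0] * na + [1] * (n - na), dtype=np.int64)
    for i in range(n_frames):
        if pair_fraction > 0:
            n_pairs = int(n * pair_fraction / 2)
            seeds_pos = rng.random((n - n_pairs, 3)) * L
            partners = seeds_pos[:n_pairs] + rng.normal(scale=pair_sep, size=(n_pairs, 3))
            pos = np.vstack([seeds_pos, np.mod(partners, L)])
        else:
            pos = rng.random((n, 3)) * L
        frames.append(Frame(sweep=i, box=L, positions=pos, species=species))
    return frames


class TestPartialStructureFactors:
    def test_ideal_gas_single_species_is_unity(self):
        frames = _gas_frames(150, 200, 8.0, x=1.0, seed=1)
        sf = partial_structure_factors(frames, n_max=5)
        assert np.allclose(sf.S_AA, 1.0, atol=0.15)
        assert np.mean(sf.S_AA) == pytest.approx(1.0, abs=0.03)
        assert np.allclose(sf.S_BB, 0.0, atol=1e-12)  # no B particles

    def test_ideal_gas_binary_cross_term_vanishes(self):
        frames = _gas_frames(150, 200, 8.0, x=0.5, seed=2)
        sf = partial_structure_factors(frames, n_max=5)
        assert np.allclose(sf.S_AB, 0.0, atol=0.12)
        assert np.allclose(sf.S_AA, 0.5, atol=0.12)
        assert np.allclose(sf.S_BB, 0.5, atol=0.12)

    def test_matches_brute_force_double_sum(self):
        """Shell-averaged S(k) equals the direct O(N^2) pair-sum estimate on
        pair-correlated configurations."""
        frames = _gas_frames(10, 60, 6.0, x=0.5, seed=3, pair_fraction=0.6)
        n_max = 4
        sf = partial_structure_factors(frames, n_max=n_max)
        # brute force: S_ab(k) = (1/N) sum_{i in a, j in b} cos(k.(ri - rj))
        shells = {}
        for nx in range(0, n_max + 1):
            for ny in range(-n_max, n_max + 1):
                for nz in range(-n_max, n_max + 1):
                    if nx == 0 and (ny < 0 or (ny == 0 and nz <= 0)):
                        continue
                    n2 = nx * nx + ny * ny + nz * nz
                    if 1 <= n2 <= n_max * n_max:
                        shells.setdefault(n2, []).append((nx, ny, nz))
        for key, idx in (("AA", (0, 0)), ("BB", (1, 1)), ("AB", (0, 1))):
            got = getattr(sf, f"S_{key}")
            for si, n2 in enumerate(sorted(shells)):
                acc = 0.0
                for fr in frames:
                    ra = fr.positions[fr.species == idx[0]]
                    rb = fr.positions[fr.species == idx[1]]
                    for nv in shells[n2]:
                        k = 2 * np.pi / fr.box * np.array(nv)
                        pa = np.exp(1j * ra @ k).sum()
                        pb = np.exp(1j * rb @ k).sum()
                        acc += np.real(pa * np.conj(pb))
                acc /= len(frames) * len(shells[n2]) * len(frames[0].positions)
                assert got[si] == pytest.approx(acc, abs=1e-10)

    def test_too_few_frames_rejected(self):
        frames = _gas_frames(3, 20, 5.0)
        with pytest.raises(ValueError, match="frames"):
            partial_structure_factors(frames)

    def test_stride_doubling_consistency(self):
        """Estimates from all frames and from every second frame agree
        within sampling error (decorrelation check on ideal-gas frames)."""
        frames = _gas_frames(200, 150, 8.0, x=0.5, seed=4)
        s_all = partial_structure_factors(frames, n_max=4)
        s_half = partial_structure_factors(frames[::2], n_max=4)
        assert np.allclose(s_all.S_AA, s_half.S_AA, atol=0.1)


class TestOZFit:
    def test_exact_model_recovery(self):
        k, s = oz_curve(s0=0.7, xi_prod=2.25)
        sf = StructureFactorData(k_grid=k, S_AA=s, S_BB=s, S_AB=s)
        sf = oz_fit(sf)
        assert sf.S0_AA == pytest.approx(0.7, abs=1e-10)
        assert sf.xi_A**2 == pytest.approx(2.25, abs=1e-8)
        assert sf.S0_AB == pytest.approx(0.7, abs=1e-10)

    def test_noisy_recovery_within_fit_errors(self):
        k = np.linspace(0.2, 2.0, 24)
        rng_noise = 0.01
        k, s = oz_curve(s0=0.7, xi_prod=2.25, k_grid=k, noise=rng_noise, seed=11)
        sf = oz_fit(StructureFactorData(k_grid=k, S_AA=s, S_BB=s, S_AB=s))
        err = sf.metadata["fit_errors"]["AA"][0]
        assert abs(sf.S0_AA - 0.7) < 3 * err

    def test_flat_data_degenerate_limit(self):
        k = np.linspace(0.2, 2.0, 8)
        s = np.full_like(k, 0.42)
        sf = oz_fit(StructureFactorData(k_grid=k, S_AA=s, S_BB=s, S_AB=s))
        assert sf.S0_AA == pytest.approx(0.42, abs=1e-12)
        assert sf.xi_A == 0.0

    def test_too_few_points_rejected(self):
        k = np.linspace(0.2, 2.0, 3)
        s = 0.7 / (1 + k**2)
        with pytest.raises(ValueError, match="k-points"):
            oz_fit(StructureFactorData(k_grid=k, S_AA=s, S_BB=s, S_AB=s))


class TestExcessMu:
    def test_ideal_mixture_null(self):
        """Species-blind mixing has S_cc(0) = x(1-x) exactly, so the
        integrand and mu_ex vanish identically."""
        x = np.linspace(0.1, 1.0, 10)
        with np.errstate(divide="ignore", invalid="ignore"):
            s_aa = x * (1 - x) / (1 - x) ** 2  # S_cc = (1-x)^2 * S_AA
        s_aa[-1] = 1.0  # unused: the x=1 integrand is extrapolated
        curve = excess_mu(x, s_aa, np.zeros_like(x), np.zeros_like(x), T=0.17)
        assert np.allclose(curve.mu_ex, 0.0, atol=1e-10)

    def test_analytic_integrand_oracle(self):
        """Inputs crafted so the integrand is f(x) = x; the integral from 1
        to x is (x^2 - 1)/2, recovered within the trapezoid error bound."""
        x = np.linspace(0.2, 1.0, 41)
        scc = x * (1 - x) / (1 + x**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            s_aa = scc / (1 - x) ** 2
        s_aa[-1] = 1.0  # unused: the x=1 integrand is extrapolated
        T = 0.5
        curve = excess_mu(x, s_aa, np.zeros_like(x), np.zeros_like(x), T=T)
        expected = T * (x**2 - 1) / 2
        h = x[1] - x[0]
        bound = T * h**2 / 12 * 1.0 * (1 - x.min()) + 1e-12  # |f''| <= ~1
        assert np.max(np.abs(curve.mu_ex - expected)) < max(bound * 5, 1e-4)

    def test_reference_point_is_zero(self):
        x = np.linspace(0.3, 1.0, 8)
        curve = excess_mu(x, np.ones_like(x), np.ones_like(x), np.zeros_like(x), T=0.2)
        assert curve.mu_ex[-1] == 0.0

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="reach"):
            excess_mu(np.array([0.2, 0.5, 0.9]), np.ones(3), np.ones(3), np.zeros(3), T=1.0)
        with pytest.raises(ValueError, match="increasing"):
            excess_mu(np.array([0.9, 0.5, 1.0]), np.ones(3), np.ones(3), np.zeros(3), T=1.0)


class TestTotalMu:
    def test_identity_assembly(self):
        x = np.linspace(0.25, 1.0, 4)
        curve = ChemicalPotentialCurve(
            x_grid=x, mu_ex=np.zeros_like(x), mu_ex_err=np.zeros_like(x), T=0.17
        )
        curve = total_mu(curve, mu0=0.152)
        # at x = x0 = 1 the total equals the reference exactly
        assert curve.mu_total[-1] == 0.152
        # with mu_ex = 0 the curve is the ideal-solution law mu0 + T ln x
        assert np.allclose(curve.mu_total, 0.152 + 0.17 * np.log(x))

    def test_nonzero_excess_added_pointwise(self):
        x = np.array([0.5, 1.0])
        mu_ex = np.array([0.03, 0.0])
        curve = ChemicalPotentialCurve(x_grid=x, mu_ex=mu_ex, mu_ex_err=0 * x, T=0.2)
        curve = total_mu(curve, mu0=0.1)
        assert curve.mu_total[0] == pytest.approx(0.1 + 0.2 * np.log(0.5) + 0.03)
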