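"""The S0 route to chemical potentials in binary mixtures.

Partial structure factors are computed from simulation frames in the
N-normalized convention

.. math::

    S_{ab}(k) = \\langle \\hat\\rho_a(\\mathbf k)\\hat\\rho_b(-\\mathbf k)
    \\rangle / N, \\qquad
    \\hat\\rho_a(\\mathbf k) = \\sum_{j \\in a} e^{i\\mathbf k\\cdot
    \\mathbf r_j},

averaged over frames and over all integer wavevectors sharing the same
modulus.  Their k -> 0 limits are obtained by fitting the Ornstein-Zernike
form ``S(k) = S0 / (1 + k^2 xi_a xi_b)``.

The excess chemical potential of species A then follows from a
Kirkwood-Buff integral over composition at fixed (T, P).  With the
concentration-concentration structure factor

.. math::

    S_{cc}(0) = x_B^2 S_{AA}^0 + x_A^2 S_{BB}^0 - 2 x_A x_B S_{AB}^0,

the thermodynamic identity ``(d beta mu_A / d x_A)_{T,P} = x_B / S_cc(0)``
gives

.. math::

    \\beta\\mu_A^{ex}(x_A) = \\int_1^{x_A} \\frac{dx}{x}
    \\Big[\\frac{x (1-x)}{S_{cc}(0)} - 1\\Big],

where the ``-1`` removes the ideal-mixing part.  For an ideal (species-
blind) mixture ``S_cc(0) = x_A x_B`` exactly and the integrand vanishes
identically; this null test fixes the pairing of the normalization
convention and the integrand.  The total chemical potential is assembled
as ``mu_A = mu0 + T ln(x_A / x0) + mu_ex`` with the pure state x0 = 1 as
reference and mu0 measured by matching grand-canonical to isobaric
densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from azeopatch.graph import MixtureDesign
from azeopatch.mc_engine import (
    Frame,
    MoveSchedule,
    block_average,
    make_initial_config,
    run_gcmc,
    run_npt,
)

__all__ = [
    "StructureFactorData",
    "ChemicalPotentialCurve",
    "partial_structure_factors",
    "oz_fit",
    "excess_mu",
    "total_mu",
    "s0_mu_curve",
    "match_mu0",
]


@dataclass
class StructureFactorData:
    k_grid: np.ndarray
    S_AA: np.ndarray
    S_BB: np.ndarray
    S_AB: np.ndarray
    S0_AA: float = np.nan
    S0_BB: float = np.nan
    S0_AB: float = np.nan
    xi_A: float = np.nan
    xi_B: float = np.nan
    metadata: dict = field(default_factory=dict)


@dataclass
class ChemicalPotentialCurve:
    x_grid: np.ndarray
    mu_ex: np.ndarray
    mu_ex_err: np.ndarray
    T: float
    mu_total: np.ndarray | None = None
    mu0: float = np.nan
    x0: float = 1.0


def partial_structure_factors(
    frames: list[Frame],
    n_species: int = 2,
    n_max: int = 6,
    min_frames: int = 10,
) -> StructureFactorData:
    """Partial structure factors from trajectory frames (cubic box).

    Averages over all integer wavevectors ``(2 pi / L) n`` with
    ``1 <= |n|^2 <= n_max^2``, shell-averaged by ``|n|^2`` and over frames.
    """
    if len(frames) < min_frames:
        raise ValueError(f"need >= {min_frames} frames, got {len(frames)}")
    # integer wavevectors, one hemisphere (S(k) = S(-k) for real densities)
    rng = range(-n_max, n_max + 1)
    nvecs = []
    for nx in range(0, n_max + 1):
        for ny in rng:
            for nz in rng:
                if nx == 0 and (ny < 0 or (ny == 0 and nz <= 0)):
                    continue
                n2 = nx * nx + ny * ny + nz * nz
                if 1 <= n2 <= n_max * n_max:
                    nvecs.append((nx, ny, nz, n2))
    nvecs = np.array(nvecs, dtype=float)
    shells = np.unique(nvecs[:, 3].astype(int))
    acc = {
        "AA": np.zeros(len(nvecs)),
        "BB": np.zeros(len(nvecs)),
        "AB": np.zeros(len(nvecs)),
    }
    L_ref = frames[0].box
    n_part = len(frames[0].positions)
    for fr in frames:
        phase = np.exp(2j * np.pi / fr.box * (fr.positions @ nvecs[:, :3].T))
        rho_a = phase[fr.species == 0].sum(axis=0)
        rho_b = phase[fr.species == 1].sum(axis=0)
        acc["AA"] += np.real(rho_a * np.conj(rho_a))
        acc["BB"] += np.real(rho_b * np.conj(rho_b))
        acc["AB"] += np.real(rho_a * np.conj(rho_b))
    for key in acc:
        acc[key] /= len(frames) * n_part
    k_shell = 2.0 * np.pi / L_ref * np.sqrt(shells)
    out = {"AA": [], "BB": [], "AB": []}
    for s in shells:
        m = nvecs[:, 3].astype(int) == s
        for key in out:
            out[key].append(acc[key][m].mean())
    return StructureFactorData(
        k_grid=k_shell,
        S_AA=np.array(out["AA"]),
        S_BB=np.array(out["BB"]),
        S_AB=np.array(out["AB"]),
        metadata={
            "convention": "S_ab(k) = <rho_a(k) rho_b(-k)> / N",
            "n_frames": len(frames),
            "box": L_ref,
            "n_max": n_max,
        },
    )


def _oz_form(k, s0, xiprod):
    return s0 / (1.0 + k * k * xiprod)


def oz_fit(sf: StructureFactorData, k_fit_max: float | None = None) -> StructureFactorData:
    """Least-squares Ornstein-Zernike extrapolation of each channel to k=0.

    Fits ``S(k) = S0 / (1 + k^2 xi^2_prod)`` on k <= k_fit_max (default:
    all provided shells); correlation lengths are reported as
    ``xi_A = sqrt(max(xi2_AA, 0))`` etc.  Fit standard errors go into
    ``metadata['fit_errors']``.
    """
    k = sf.k_grid
    if k_fit_max is None:
        k_fit_max = float(k.max()) * (1 + 1e-12)
    m = k <= k_fit_max
    if m.sum() < 4:
        raise ValueError("need >= 4 k-points below k_fit_max for the OZ fit")
    errs = {}
    vals = {}
    for key, S in (("AA", sf.S_AA), ("BB", sf.S_BB), ("AB", sf.S_AB)):
        y = S[m]
        if np.allclose(y, y[0], rtol=0, atol=0):
            # degenerate: exactly flat data
            vals[key] = (float(y[0]), 0.0)
            errs[key] = (0.0, 0.0)
            continue
        s0_guess = float(y[0]) if abs(y[0]) > 1e-12 else 1e-12
        try:
            popt, pcov = curve_fit(
                _oz_form, k[m], y, p0=[s0_guess, 0.5], maxfev=20000
            )
        except RuntimeError as err:
            raise ValueError(f"OZ fit failed for channel {key}: {err}") from err
        perr = np.sqrt(np.abs(np.diag(pcov)))
        if not np.all(np.isfinite(popt)):
            raise ValueError(f"OZ fit singular for channel {key}")
        vals[key] = (float(popt[0]), float(popt[1]))
        errs[key] = (float(perr[0]), float(perr[1]))
    sf.S0_AA, xi2_aa = vals["AA"]
    sf.S0_BB, xi2_bb = vals["BB"]
    sf.S0_AB, _ = vals["AB"]
    sf.xi_A = float(np.sqrt(max(xi2_aa, 0.0)))
    sf.xi_B = float(np.sqrt(max(xi2_bb, 0.0)))
    sf.metadata["fit_errors"] = errs
    sf.metadata["k_fit_max"] = k_fit_max
    return sf


def _scc(x, s_aa, s_bb, s_ab):
    return (1 - x) ** 2 * s_aa + x**2 * s_bb - 2 * x * (1 - x) * s_ab


def excess_mu(
    x_grid: np.ndarray,
    S0_AA: np.ndarray,
    S0_BB: np.ndarray,
    S0_AB: np.ndarray,
    T: float,
    S0_err: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> ChemicalPotentialCurve:
    """Kirkwood-Buff composition integral for the excess chemical potential
    of species A, referenced to the pure state x_A = 1.

    ``x_grid`` must be increasing and include x = 1 as its last point; the
    integrand at x = 1 (a 0/0 limit) is linearly extrapolated from the two
    nearest interior points.  Trapezoidal integration; uncertainties are
    propagated from the S0 fit errors when given.
    """
    x = np.asarray(x_grid, dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("x_grid must be strictly increasing")
    if abs(x[-1] - 1.0) > 1e-9:
        raise ValueError("x_grid must reach the reference state x = 1")

    def integrand(saa, sbb, sab):
        g = np.empty_like(x)
        interior = slice(0, len(x) - 1)
        xi = x[interior]
        scc = _scc(xi, saa[interior], sbb[interior], sab[interior])
        g[interior] = (xi * (1 - xi) / scc - 1.0) / xi
        # 0/0 limit at the pure end: linear extrapolation
        g[-1] = g[-2] + (g[-2] - g[-3]) * (x[-1] - x[-2]) / (x[-2] - x[-3])
        return g

    g0 = integrand(np.asarray(S0_AA), np.asarray(S0_BB), np.asarray(S0_AB))

    def cumint(g):
        # integral from 1 down to each grid point (trapezoid)
        out = np.zeros_like(x)
        for i in range(len(x) - 2, -1, -1):
            out[i] = out[i + 1] - 0.5 * (g[i] + g[i + 1]) * (x[i + 1] - x[i])
        return out

    mu_ex = T * cumint(g0)
    if S0_err is not None:
        var = np.zeros_like(x)
        base = cumint(g0)
        arrs = [np.asarray(S0_AA, float), np.asarray(S0_BB, float), np.asarray(S0_AB, float)]
        for idx, err in enumerate(S0_err):
            pert = [a.copy() for a in arrs]
            pert[idx] = pert[idx] + np.asarray(err)
            var += (cumint(integrand(*pert)) - base) ** 2
        mu_err = T * np.sqrt(var)
    else:
        mu_err = np.zeros_like(x)
    return ChemicalPotentialCurve(x_grid=x, mu_ex=mu_ex, mu_ex_err=mu_err, T=T)


def total_mu(curve: ChemicalPotentialCurve, mu0: float) -> ChemicalPotentialCurve:
    """Assemble the total chemical potential mu = mu0 + T ln(x/x0) + mu_ex."""
    with np.errstate(divide="ignore"):
        curve.mu_total = mu0 + curve.T * np.log(curve.x_grid / curve.x0) + curve.mu_ex
    curve.mu0 = mu0
    return curve


# ---------------------------------------------------------------------------
# high-level drivers


def match_mu0(
    design: MixtureDesign,
    T: float,
    rho_target: float,
    N: int = 128,
    mu_bracket: tuple[float, float] = (-0.5, 0.8),
    sweeps: int = 20_000,
    equil: int = 5_000,
    seed: int = 0,
    n_grid: int = 7,
) -> tuple[float, float]:
    """Reference chemical potential mu0 of the pure species-A fluid.

    Runs grand-canonical simulations on a grid of chemical potentials and
    interpolates mu at which <rho> equals ``rho_target`` (the
    density-matching protocol, automated).  Returns (mu0, standard error).
    """
    rho0 = min(rho_target, 0.4)
    mus = np.linspace(mu_bracket[0], mu_bracket[1], n_grid)
    means = []
    errs = []
    for i, mu in enumerate(mus):
        st = make_initial_config([N, 0], rho0, design, seed=seed + 100 + i)
        # the reference is the pure species-A fluid: forbid B insertions
        mu_vec = np.full(design.n_species, -1e30)
        mu_vec[0] = mu
        res = run_gcmc(
            st, design, T, mu_vec,
            schedule=MoveSchedule(seed=seed + 200 + i, exchange=0.2),
            sweeps=sweeps, stride=max(1, sweeps // 100),
            capacity=max(4 * N, 512),
        )
        obs = res.observables
        keep = obs.sweep > equil
        m, se = block_average(obs.rho[keep].to_numpy())
        means.append(m)
        errs.append(se)
    means = np.asarray(means)
    if not (means.min() <= rho_target <= means.max()):
        raise RuntimeError(
            f"rho_target {rho_target} not bracketed by GCMC scan (rho in "
            f"[{means.min():.3f}, {means.max():.3f}])"
        )
    mu0 = float(np.interp(rho_target, means, mus))
    # propagate density error through the local slope
    i = int(np.clip(np.searchsorted(means, rho_target), 1, len(mus) - 1))
    slope = (mus[i] - mus[i - 1]) / max(means[i] - means[i - 1], 1e-12)
    mu0_err = float(abs(slope) * np.mean(errs))
    return mu0, mu0_err


def s0_mu_curve(
    design: MixtureDesign,
    T: float,
    P: float,
    x_grid: np.ndarray,
    N: int = 128,
    sweeps: int = 15_000,
    equil: int = 5_000,
    frame_stride: int = 100,
    n_max: int = 5,
    seed: int = 0,
    mu0: float | None = None,
) -> tuple[ChemicalPotentialCurve, list[StructureFactorData], dict]:
    """Full S0 pipeline: NPT runs across compositions, OZ extrapolation,
    Kirkwood-Buff integration, and (optionally) total-mu assembly.

    Returns the chemical-potential curve, the per-composition structure
    factors, and a dict of auxiliary results (mean densities etc.).
    """
    x_grid = np.asarray(x_grid, dtype=float)
    s0aa, s0bb, s0ab = [], [], []
    eaa, ebb, eab = [], [], []
    sfs = []
    rhos = []
    for i, xx in enumerate(x_grid):
        na = int(round(xx * N))
        nb = N - na
        st = make_initial_config([na, nb], min(0.9 * 0.45 * 6 / np.pi, 0.35), design, seed=seed + i)
        res = run_npt(
            st, design, T, P,
            schedule=MoveSchedule(seed=seed + 50 + i),
            sweeps=sweeps, stride=frame_stride, frame_stride=frame_stride,
        )
        obs = res.observables
        keep = obs.sweep > equil
        rho_m, rho_se = block_average(obs.rho[keep].to_numpy())
        rhos.append((rho_m, rho_se))
        frames = [f for f in res.frames if f.sweep > equil]
        sf = partial_structure_factors(frames, n_species=2, n_max=n_max)
        sf = oz_fit(sf)
        sfs.append(sf)
        fe = sf.metadata["fit_errors"]
        s0aa.append(sf.S0_AA)
        s0bb.append(sf.S0_BB)
        s0ab.append(sf.S0_AB)
        eaa.append(fe["AA"][0])
        ebb.append(fe["BB"][0])
        eab.append(fe["AB"][0])
    curve = excess_mu(
        x_grid,
        np.array(s0aa), np.array(s0bb), np.array(s0ab), T,
        S0_err=(np.array(eaa), np.array(ebb), np.array(eab)),
    )
    if mu0 is not None:
        curve = total_mu(curve, mu0)
    aux = {
        "rho": np.array([r[0] for r in rhos]),
        "rho_err": np.array([r[1] for r in rhos]),
        "S0_AA": np.array(s0aa),
        "S0_BB": np.array(s0bb),
        "S0_AB": np.array(s0ab),
    }
    return curve, sfs, aux
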