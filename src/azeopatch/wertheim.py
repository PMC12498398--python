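"""Wertheim first-order thermodynamic perturbation theory (TPT1) engine.

The Helmholtz free energy per particle (in units of :math:`k_BT`) of an
associating patchy-particle mixture is written as

.. math::

    \\beta f = \\beta f_{ideal} + \\beta f_{HS} + \\beta f_{bonding},

with a hard-sphere reference (Carnahan-Starling-type compressibility term)
and a bonding term built from the probabilities :math:`X_\\alpha^{(i)}` that
a patch of type :math:`\\alpha` on species :math:`i` is *not* bonded.  The
:math:`X` solve the law of mass action

.. math::

    X_\\alpha = \\Big[1 + \\phi \\sum_\\gamma x^{s(\\gamma)}
                X_\\gamma \\Delta_{\\alpha\\gamma}\\Big]^{-1},

where :math:`\\phi` is the packing fraction, :math:`x^{s(\\gamma)}` the
molar fraction of the species carrying patch type :math:`\\gamma`, and
:math:`\\Delta_{\\alpha\\gamma}` the dimensionless bond strength obtained by
integrating the Mayer function of the Kern-Frenkel well over the bond
volume, weighted by the hard-sphere pair correlation.

Pressure and chemical potentials are evaluated analytically.  Because the
bonding free energy is stationary with respect to :math:`X` at the
mass-action solution, the density and composition derivatives reduce to
closed forms:

.. math::

    \\beta P_{bond}/\\rho = -\\tfrac{Q}{2}\\Big(1 + \\phi \\frac{h'}{h}\\Big),
    \\qquad
    \\beta\\mu_{bond}^{(i)} = \\sum_{\\alpha\\in\\Gamma(i)} \\ln X_\\alpha
        - \\frac{\\phi h'}{2h} Q,

with :math:`Q = \\sum_\\alpha x^{s(\\alpha)} (1 - X_\\alpha)` (the mean
number of bonded patches per particle) and :math:`h(\\phi)` the
packing-fraction dependence of :math:`\\Delta` (the hard-sphere contact
value by default).  These are cross-checked against Richardson-extrapolated
finite differences in the test suite.

All quantities are in reduced units: lengths in :math:`\\sigma`, energies
in the reference bond energy :math:`\\epsilon`, temperature in
:math:`\\epsilon/k_B`, pressure in :math:`\\epsilon/\\sigma^3`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from azeopatch.graph import MixtureDesign

__all__ = [
    "StatePoint",
    "BondStrengthMatrix",
    "MassActionSolution",
    "FreeEnergyBreakdown",
    "GibbsCurve",
    "CoexistencePoint",
    "AzeotropePoint",
    "compute_delta",
    "solve_mass_action",
    "free_energy",
    "pressure",
    "chemical_potentials",
    "density_roots",
    "gibbs_curve",
    "coexistence",
    "find_azeotrope",
    "ideal_azeotrope_X",
    "ConvergenceError",
    "NoRootError",
]

MASS_ACTION_TOL = 1e-13
_MAX_FP_ITER = 20_000
_RHO_GRID_SIZE = 201


class ConvergenceError(RuntimeError):
    """A self-consistent solve failed to reach its tolerance."""


class NoRootError(RuntimeError):
    """The equation of state has no density root at the requested state."""


@dataclass(frozen=True)
class StatePoint:
    """Thermodynamic state: temperature, number density, composition."""

    T: float
    rho: float
    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x, dtype=float))
        object.__setattr__(self, "x", x)
        if not self.T > 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if self.rho < 0:
            raise ValueError(f"rho must be >= 0, got {self.rho}")
        if np.any(x < 0) or abs(x.sum() - 1.0) > 1e-12:
            raise ValueError(f"composition must be nonnegative and sum to 1, got {x}")


@dataclass
class BondStrengthMatrix:
    delta_matrix: np.ndarray
    details: dict = field(default_factory=dict)


@dataclass
class MassActionSolution:
    """Per-patch-type not-bonded probabilities (ordered as design.patch_type_order)."""

    X: np.ndarray
    residual: float

    def per_species(self, design: MixtureDesign) -> list[np.ndarray]:
        owner = design.species_of_type
        return [self.X[owner == si] for si in range(design.n_species)]


@dataclass
class FreeEnergyBreakdown:
    f_ideal: float
    f_hs: float
    f_bonding: float

    @property
    def f_total(self) -> float:
        return self.f_ideal + self.f_hs + self.f_bonding


@dataclass
class GibbsCurve:
    """Gibbs free energy per particle g(x) at fixed (T, P), per branch."""

    T: float
    P: float
    x_grid: np.ndarray
    g_vapor: np.ndarray
    g_liquid: np.ndarray
    rho_vapor: np.ndarray
    rho_liquid: np.ndarray

    @property
    def n_branches(self) -> int:
        two = np.isfinite(self.g_vapor) & np.isfinite(self.g_liquid)
        return 2 if bool(np.any(two & (self.rho_vapor < self.rho_liquid))) else 1


@dataclass
class CoexistencePoint:
    T: float
    P: float
    x_vapor: float
    x_liquid: float
    rho_vapor: float
    rho_liquid: float


@dataclass
class AzeotropePoint:
    T: float
    P: float
    x_azeo: float
    width_at_detection: float


def ideal_azeotrope_X(phi: float, delta: float) -> float:
    """Not-bonded probability of the composition-independent azeotropic
    solution, i.e. the positive root of ``X + phi*delta*X**2 - 1 = 0``."""
    pd = phi * delta
    if pd == 0.0:
        return 1.0
    return (-1.0 + np.sqrt(1.0 + 4.0 * pd)) / (2.0 * pd)


# ---------------------------------------------------------------------------
# hard-sphere pair correlation over the square-well shell


def hs_first_shell_g(x: np.ndarray, eta: float) -> np.ndarray:
    """Percus-Yevick hard-sphere g(r) in the first shell, 1 <= r/sigma <= 2.

    Analytic Laplace inversion of the PY solution (Wertheim's closed form):
    the cubic ``S(t)`` supplies three poles and the shell g(r) is a sum of
    their exponential residues.  Reduces to g = 1 at zero density.
    """
    x = np.asarray(x, dtype=float)
    if eta < 1e-10:
        return np.ones_like(x)
    S = np.array(
        [(1 - eta) ** 2, 6 * eta * (1 - eta), 18 * eta**2, -12 * eta * (1 + 2 * eta)]
    )
    t = np.roots(S)
    L = 12 * eta * ((1 + eta / 2) * t + 1 + 2 * eta)
    Sp = 3 * (1 - eta) ** 2 * t**2 + 12 * eta * (1 - eta) * t + 18 * eta**2
    co = t * L / Sp
    return np.real(np.sum(co[None, :] * np.exp(np.outer(x - 1, t)), axis=1)) / (
        12 * eta * x
    )


def _shell_average_g(eta: float, delta: float) -> float:
    """r^2-weighted average of the PY g(r) over [sigma, sigma + delta]."""
    nodes, weights = np.polynomial.legendre.leggauss(24)
    x = 1.0 + 0.5 * delta * (nodes + 1.0)
    w = 0.5 * delta * weights
    norm = ((1.0 + delta) ** 3 - 1.0) / 3.0
    return float(np.sum(w * hs_first_shell_g(x, eta) * x**2) / norm)


_SHELL_SPLINE_CACHE: dict[float, object] = {}


def _shell_lnh_spline(delta: float):
    """Cubic spline of ln <g_PY> over packing fraction, cached per delta."""
    key = round(delta, 12)
    if key not in _SHELL_SPLINE_CACHE:
        from scipy.interpolate import CubicSpline

        phis = np.linspace(0.0, 0.62, 125)
        lnh = np.log([_shell_average_g(p, delta) for p in phis])
        _SHELL_SPLINE_CACHE[key] = CubicSpline(phis, lnh)
    return _SHELL_SPLINE_CACHE[key]


# ---------------------------------------------------------------------------
# internal engine: design + temperature compiled to arrays


class _Engine:
    """Caches the temperature-dependent pieces of the theory for one design."""

    def __init__(self, design: MixtureDesign, T: float, ghs: str = "shell"):
        if ghs not in ("shell", "contact", "unity"):
            raise ValueError(f"unknown g_HS approximation '{ghs}'")
        self.design = design
        self.T = float(T)
        self.ghs = ghs
        kf = design.kf
        self.Vs = np.pi / 6.0 * kf.sigma**3
        # Mayer factor per patch-type pair; exactly 0 for non-bonding pairs
        self.mayer = np.expm1(design.energy_matrix / T)
        # geometric prefactor: (1/Vs) * [(1-cos θmax)/2]^2 * 4π ∫ r^2 dr
        shell = (kf.well_outer**3 - kf.sigma**3) / 3.0
        self.kgeom0 = (1.0 / self.Vs) * ((1.0 - kf.cos_theta_max) / 2.0) ** 2 * 4.0 * np.pi * shell
        self.owner = design.species_of_type
        self.n_types = design.n_patch_types
        if ghs == "shell":
            self._shell_spline = _shell_lnh_spline(kf.delta / kf.sigma)

    # -- packing-fraction dependence of Delta -------------------------------

    def gfac(self, phi):
        if self.ghs == "unity":
            return np.ones_like(np.asarray(phi, dtype=float))
        if self.ghs == "shell":
            return np.exp(self._shell_spline(phi))
        return (1.0 - phi / 2.0) / (1.0 - phi) ** 3

    def dlnh(self, phi):
        """phi * d ln h / d phi for the chosen g_HS treatment."""
        if self.ghs == "unity":
            return np.zeros_like(np.asarray(phi, dtype=float))
        if self.ghs == "shell":
            return phi * self._shell_spline(phi, 1)
        return phi * (3.0 / (1.0 - phi) - 1.0 / (2.0 - phi))

    def delta(self, phi: float) -> np.ndarray:
        return self.mayer * (self.kgeom0 * float(self.gfac(phi)))

    # -- mass action --------------------------------------------------------

    def solve_X(self, phi: float, x: np.ndarray, X0: np.ndarray | None = None) -> np.ndarray:
        w = x[self.owner]
        A = phi * self.delta(phi) * w[None, :]  # c_alpha = A @ X
        if X0 is None:
            # seed from the uniform-approximation closed form
            a = max(float(A.sum(axis=1).max()), 0.0)
            X0 = np.full(self.n_types, ideal_azeotrope_X(1.0, a))
        X = X0.copy()
        for _ in range(30):  # damped warmup, then Newton
            Xn = 1.0 / (1.0 + A @ X)
            X = 0.5 * (X + Xn)
            if np.max(np.abs(Xn - X)) < 0.25 * MASS_ACTION_TOL:
                break
        X = self._newton_X(A, np.clip(X, 1e-300, 1.0))
        res = self._residual(A, X)
        if res > MASS_ACTION_TOL:
            raise ConvergenceError(
                f"mass action failed to converge (residual {res:.2e})"
            )
        return X

    @staticmethod
    def _residual(A, X):
        return float(np.max(np.abs(X - 1.0 / (1.0 + A @ X))))

    @staticmethod
    def _newton_X(A, X):
        n = len(X)
        eye = np.eye(n)
        for _ in range(100):
            c = A @ X
            F = X - 1.0 / (1.0 + c)
            if np.max(np.abs(F)) < 0.25 * MASS_ACTION_TOL:
                break
            J = eye + A / (1.0 + c[:, None]) ** 2
            X = np.clip(X - np.linalg.solve(J, F), 1e-300, 1.0)
        return X

    def solve_X_grid(self, phis: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Vectorized mass-action solve over a packing-fraction grid."""
        w = x[self.owner]
        base = self.mayer * w[None, :]
        scale = (phis * self.gfac(phis) * self.kgeom0)[:, None, None]
        A = scale * base[None, :, :]  # (n, m, m)
        n, m = len(phis), self.n_types
        X = np.full((n, m), 0.5)
        for _ in range(40):
            Xn = 1.0 / (1.0 + np.einsum("nab,nb->na", A, X))
            X = 0.5 * (X + Xn)
            if np.max(np.abs(Xn - X)) < 0.25 * MASS_ACTION_TOL:
                break
        # batched Newton polish
        eye = np.eye(m)[None, :, :]
        for _ in range(100):
            c = np.einsum("nab,nb->na", A, X)
            F = X - 1.0 / (1.0 + c)
            J = eye + A / (1.0 + c[:, :, None]) ** 2
            X = np.clip(X - np.linalg.solve(J, F[:, :, None])[:, :, 0], 1e-300, 1.0)
            if np.max(np.abs(F)) < 0.25 * MASS_ACTION_TOL:
                break
        return X

    # -- free energy and derivatives ----------------------------------------

    def f_pieces(self, rho: float, x: np.ndarray, X: np.ndarray):
        phi = rho * self.Vs
        xs = x[x > 0]
        f_id = np.log(rho) - 1.0 + float(np.sum(xs * np.log(xs)))
        f_hs = (4.0 * phi - 3.0 * phi**2) / (1.0 - phi) ** 2
        w = x[self.owner]
        gam = self.design.valences
        f_b = float(np.sum(w * (np.log(X) - X / 2.0)) + 0.5 * np.sum(x * gam))
        return f_id, f_hs, f_b

    def betaP(self, rho, x: np.ndarray, X: np.ndarray):
        """beta * P given the mass-action solution at (rho, x)."""
        phi = rho * self.Vs
        w = x[self.owner]
        Q = np.sum(w * (1.0 - X), axis=-1)
        z_hs = phi * (4.0 - 2.0 * phi) / (1.0 - phi) ** 3
        return rho * (1.0 + z_hs - 0.5 * Q * (1.0 + self.dlnh(phi)))

    def betaP_grid(self, rhos: np.ndarray, x: np.ndarray) -> np.ndarray:
        X = self.solve_X_grid(rhos * self.Vs, x)
        phis = rhos * self.Vs
        w = x[self.owner]
        Q = (w[None, :] * (1.0 - X)).sum(axis=1)
        z_hs = phis * (4.0 - 2.0 * phis) / (1.0 - phis) ** 3
        return rhos * (1.0 + z_hs - 0.5 * Q * (1.0 + self.dlnh(phis)))

    def betamu(self, rho: float, x: np.ndarray, X: np.ndarray) -> np.ndarray:
        """beta * mu per species (thermal volumes set to 1)."""
        phi = rho * self.Vs
        w = x[self.owner]
        Q = float(np.sum(w * (1.0 - X)))
        mu_hs = (4.0 * phi - 3.0 * phi**2) / (1.0 - phi) ** 2 + phi * (
            4.0 - 2.0 * phi
        ) / (1.0 - phi) ** 3
        lnX = np.log(X)
        mu_b = np.array(
            [float(lnX[self.owner == si].sum()) for si in range(self.design.n_species)]
        )
        mu_b -= 0.5 * float(self.dlnh(phi)) * Q
        with np.errstate(divide="ignore"):
            mu_id = np.log(rho * x)
        return mu_id + mu_hs + mu_b

    # -- density roots at fixed pressure -------------------------------------

    def density_roots(
        self, P: float, x: np.ndarray, phi_max: float = 0.55, refine: bool = True
    ) -> np.ndarray:
        betaP_target = P / self.T
        rhos = np.geomspace(1e-12, phi_max / self.Vs, _RHO_GRID_SIZE)
        f = self.betaP_grid(rhos, x) - betaP_target
        roots = []

        def fun(r):
            X = self.solve_X(r * self.Vs, x)
            return float(self.betaP(r, x, X)) - betaP_target

        sign = np.sign(f)
        for i in np.flatnonzero(sign[:-1] * sign[1:] < 0):
            if refine:
                r = optimize.brentq(fun, rhos[i], rhos[i + 1], xtol=1e-15, rtol=1e-14)
            else:
                # inverse linear interpolation; g(rho) is stationary at the
                # root so this is plenty for branch classification/scanning
                r = rhos[i] - f[i] * (rhos[i + 1] - rhos[i]) / (f[i + 1] - f[i])
            roots.append(r)
        for i in np.flatnonzero(f == 0.0):
            roots.append(rhos[i])
        return np.array(sorted(roots))


# ---------------------------------------------------------------------------
# public API


def compute_delta(
    design: MixtureDesign, state: StatePoint, ghs: str = "shell"
) -> BondStrengthMatrix:
    """Bond-strength matrix Delta_ag at a state point.

    ``Delta = (exp(eps/T) - 1) * K_geom(phi)`` with ``K_geom`` the bond-volume
    integral of the hard-sphere pair correlation over the square-well shell
    (angular factor ``[(1 - cos θmax)/2]^2``), divided by the particle
    volume.  ``ghs='contact'`` (default) uses the Carnahan-Starling contact
    value, constant across the thin shell; ``ghs='unity'`` sets g_HS = 1.
    """
    eng = _Engine(design, state.T, ghs)
    phi = state.rho * eng.Vs
    return BondStrengthMatrix(
        delta_matrix=eng.delta(phi),
        details={
            "ghs": ghs,
            "g_contact": float(eng.gfac(phi)),
            "kgeom": eng.kgeom0 * float(eng.gfac(phi)),
            "phi": phi,
        },
    )


def solve_mass_action(
    design: MixtureDesign,
    state: StatePoint,
    delta: BondStrengthMatrix | None = None,
    ghs: str = "shell",
) -> MassActionSolution:
    """Solve the law of mass action for the not-bonded probabilities.

    Damped fixed-point iteration from a closed-form seed, with a Newton
    fallback; the returned residual is the maximum violation of the
    mass-action equation.
    """
    eng = _Engine(design, state.T, ghs)
    phi = state.rho * eng.Vs
    if delta is not None:
        w = state.x[eng.owner]
        A = phi * delta.delta_matrix * w[None, :]
        X = np.full(eng.n_types, 0.5)
        for _ in range(_MAX_FP_ITER):
            Xn = 1.0 / (1.0 + A @ X)
            X = 0.5 * (X + Xn)
            if np.max(np.abs(Xn - X)) < 0.25 * MASS_ACTION_TOL:
                break
        X = 1.0 / (1.0 + A @ X)
        res = eng._residual(A, X)
        if res > MASS_ACTION_TOL:
            X = eng._newton_X(A, X)
            res = eng._residual(A, X)
    else:
        X = eng.solve_X(phi, state.x)
        w = state.x[eng.owner]
        A = phi * eng.delta(phi) * w[None, :]
        res = eng._residual(A, X)
    return MassActionSolution(X=X, residual=res)


def free_energy(
    design: MixtureDesign, state: StatePoint, ghs: str = "shell"
) -> FreeEnergyBreakdown:
    """Helmholtz free energy per particle, split into ideal, hard-sphere and
    bonding contributions (all in units of k_B T)."""
    eng = _Engine(design, state.T, ghs)
    phi = state.rho * eng.Vs
    if phi >= 1.0:
        raise ValueError(f"packing fraction {phi:.3f} >= 1 is unphysical")
    X = eng.solve_X(phi, state.x)
    f_id, f_hs, f_b = eng.f_pieces(state.rho, state.x, X)
    return FreeEnergyBreakdown(f_ideal=f_id, f_hs=f_hs, f_bonding=f_b)


def pressure(design: MixtureDesign, state: StatePoint, ghs: str = "shell") -> float:
    """Pressure (reduced units, epsilon/sigma^3)."""
    eng = _Engine(design, state.T, ghs)
    phi = state.rho * eng.Vs
    if phi >= 1.0:
        raise ValueError(f"packing fraction {phi:.3f} >= 1 is unphysical")
    X = eng.solve_X(phi, state.x)
    return float(eng.betaP(state.rho, state.x, X)) * state.T


def chemical_potentials(
    design: MixtureDesign, state: StatePoint, ghs: str = "shell"
) -> np.ndarray:
    """Chemical potential per species, in units of epsilon (beta*mu*T)."""
    eng = _Engine(design, state.T, ghs)
    phi = state.rho * eng.Vs
    X = eng.solve_X(phi, state.x)
    return eng.betamu(state.rho, state.x, X) * state.T


def density_roots(
    design: MixtureDesign, T: float, P: float, x: np.ndarray, ghs: str = "shell"
) -> np.ndarray:
    """All density roots of P(rho; T, x) = P, sorted ascending."""
    eng = _Engine(design, T, ghs)
    return eng.density_roots(P, np.asarray(x, dtype=float))


def _binary_x(x: float) -> np.ndarray:
    return np.array([x, 1.0 - x])


def _g_at(eng: _Engine, rho: float, x: np.ndarray, P: float) -> float:
    X = eng.solve_X(rho * eng.Vs, x)
    f_id, f_hs, f_b = eng.f_pieces(rho, x, X)
    return f_id + f_hs + f_b + (P / eng.T) / rho


def gibbs_curve(
    design: MixtureDesign,
    T: float,
    P: float,
    x_grid: np.ndarray | int = 201,
    ghs: str = "shell",
) -> GibbsCurve:
    """Two-branch Gibbs free energy per particle g(x) at fixed (T, P).

    For each composition, every density root of the equation of state is
    located by bracketing on a log-density grid; ``g = beta*f + beta*P/rho``
    is evaluated on the lowest-density (vapor) and highest-density (liquid)
    roots.  Where only one root exists both branches coincide.
    """
    if design.n_species != 2:
        raise ValueError("gibbs_curve supports binary mixtures")
    if isinstance(x_grid, int):
        x_grid = np.linspace(0.0, 1.0, x_grid)
    x_grid = np.asarray(x_grid, dtype=float)
    eng = _Engine(design, T, ghs)
    n = len(x_grid)
    gv = np.full(n, np.nan)
    gl = np.full(n, np.nan)
    rv = np.full(n, np.nan)
    rl = np.full(n, np.nan)
    for i, xx in enumerate(x_grid):
        x = _binary_x(xx)
        roots = eng.density_roots(P, x)
        if len(roots) == 0:
            raise NoRootError(f"no density root at T={T}, P={P}, x={xx}")
        rv[i], rl[i] = roots[0], roots[-1]
        gv[i] = _g_at(eng, roots[0], x, P)
        gl[i] = _g_at(eng, roots[-1], x, P)
    return GibbsCurve(T=T, P=P, x_grid=x_grid, g_vapor=gv, g_liquid=gl, rho_vapor=rv, rho_liquid=rl)


def _branch_mu(eng: _Engine, P: float, xx: float, branch: str) -> tuple[np.ndarray, float]:
    x = _binary_x(xx)
    roots = eng.density_roots(P, x)
    if len(roots) == 0:
        raise NoRootError(f"no density root at T={eng.T}, P={P}, x={xx}")
    rho = roots[0] if branch == "vapor" else roots[-1]
    X = eng.solve_X(rho * eng.Vs, x)
    return eng.betamu(rho, x, X) * eng.T, rho


def coexistence(
    design: MixtureDesign,
    T: float,
    P: float,
    ghs: str = "shell",
    seed: tuple[float, float] | None = None,
    mu_tol: float = 1e-9,
) -> CoexistencePoint:
    """Vapor-liquid coexistence compositions at (T, P) by common tangent.

    Solves the 2x2 system ``mu_i(vapor, x') = mu_i(liquid, x'')`` seeded
    from the crossing of the two Gibbs free-energy branches.
    """
    eng = _Engine(design, T, ghs)
    if seed is None:
        curve = gibbs_curve(design, T, P, 201, ghs)
        dg = curve.g_liquid - curve.g_vapor
        two = np.isfinite(dg) & (curve.rho_liquid > curve.rho_vapor * (1 + 1e-6))
        sign = np.sign(dg)
        cross = [
            i
            for i in range(len(dg) - 1)
            if two[i] and two[i + 1] and sign[i] * sign[i + 1] < 0
        ]
        if not cross:
            raise NoRootError(f"no two-phase coexistence found at T={T}, P={P}")
        i = cross[0]
        x0 = float(curve.x_grid[i])
        seed = (x0 - 0.01, x0 + 0.01)

    def resid(v):
        xv, xl = float(np.clip(v[0], 1e-8, 1 - 1e-8)), float(np.clip(v[1], 1e-8, 1 - 1e-8))
        mu_v, _ = _branch_mu(eng, P, xv, "vapor")
        mu_l, _ = _branch_mu(eng, P, xl, "liquid")
        return mu_v - mu_l

    sol = optimize.root(resid, np.array(seed), method="hybr", options={"xtol": 1e-13})
    xv, xl = float(np.clip(sol.x[0], 1e-8, 1 - 1e-8)), float(np.clip(sol.x[1], 1e-8, 1 - 1e-8))
    res = resid([xv, xl])
    if np.max(np.abs(res)) > mu_tol * max(1.0, abs(T)):
        raise ConvergenceError(
            f"common-tangent solve stalled at T={T}, P={P} (mu residual {res})"
        )
    mu_v, rho_v = _branch_mu(eng, P, xv, "vapor")
    _, rho_l = _branch_mu(eng, P, xl, "liquid")
    return CoexistencePoint(T=T, P=P, x_vapor=xv, x_liquid=xl, rho_vapor=rho_v, rho_liquid=rho_l)


def _tangency_gap(eng: _Engine, P: float, x_scan: np.ndarray):
    """min over x of g_liquid - g_vapor, and the arg min (coarse grid)."""
    best = np.inf
    xbest = np.nan
    for xx in x_scan:
        x = _binary_x(xx)
        roots = eng.density_roots(P, x, refine=False)
        if len(roots) < 2 or roots[-1] < roots[0] * (1 + 1e-6):
            continue
        dg = _g_at(eng, roots[-1], x, P) - _g_at(eng, roots[0], x, P)
        if dg < best:
            best = dg
            xbest = xx
    return best, xbest


def find_azeotrope(
    design: MixtureDesign,
    T: float,
    ghs: str = "shell",
    P_bounds: tuple[float, float] = (1e-12, 0.5),
    x_window: tuple[float, float] = (0.02, 0.98),
    detection_tol: float = 1e-3,
) -> AzeotropePoint:
    """Locate the azeotropic point at temperature T.

    At the azeotropic pressure the vapor and liquid Gibbs branches become
    tangent at a single composition: ``g_l(x) - g_v(x)`` has a double root.
    Since ``d(g_l - g_v)/dP = 1/rho_l - 1/rho_v < 0`` pointwise, the minimum
    gap is monotone in P, so the tangency pressure is bracketed by a log-P
    scan and polished by a two-dimensional root solve on

    ``[g_l(x) - g_v(x),  (mu_A - mu_B)|_l - (mu_A - mu_B)|_v] = 0``

    in (x, ln P) — the second residual is the slope-matching condition,
    using dg/dx = mu_A - mu_B at fixed (T, P).
    """
    eng = _Engine(design, T, ghs)
    x_scan = np.linspace(x_window[0], x_window[1], 41)
    Ps = np.geomspace(P_bounds[0], P_bounds[1], 40)
    gaps = []
    for P in Ps:
        m, xb = _tangency_gap(eng, P, x_scan)
        gaps.append((P, m, xb))
    bracket = None
    for (P1, m1, x1), (P2, m2, x2) in zip(gaps[:-1], gaps[1:]):
        if np.isfinite(m1) and np.isfinite(m2) and m1 > 0 >= m2:
            bracket = (P1, P2, x2 if np.isfinite(x2) else x1)
            break
    if bracket is None:
        raise NoRootError(f"no azeotrope bracketed in P ∈ {P_bounds} at T={T}")
    P_lo, P_hi, x_seed = bracket

    # a few bisection steps to tighten the bracket before polishing
    for _ in range(12):
        P_mid = np.sqrt(P_lo * P_hi)
        m, xb = _tangency_gap(eng, P_mid, x_scan)
        if m > 0:
            P_lo = P_mid
        else:
            P_hi = P_mid
            if np.isfinite(xb):
                x_seed = xb

    def resid(v):
        xx = float(np.clip(v[0], 1e-6, 1 - 1e-6))
        P = float(np.exp(v[1]))
        x = _binary_x(xx)
        roots = eng.density_roots(P, x)
        if len(roots) < 2:
            return np.array([1.0, 1.0])
        Xv = eng.solve_X(roots[0] * eng.Vs, x)
        Xl = eng.solve_X(roots[-1] * eng.Vs, x)
        dg = _g_at(eng, roots[-1], x, P) - _g_at(eng, roots[0], x, P)
        mu_v = eng.betamu(roots[0], x, Xv)
        mu_l = eng.betamu(roots[-1], x, Xl)
        slope = (mu_l[0] - mu_l[1]) - (mu_v[0] - mu_v[1])
        return np.array([dg, slope])

    v0 = np.array([x_seed, np.log(np.sqrt(P_lo * P_hi))])
    sol = optimize.root(resid, v0, method="hybr", options={"xtol": 1e-12})
    x_azeo = float(np.clip(sol.x[0], 0.0, 1.0))
    P_azeo = float(np.exp(sol.x[1]))

    # verify: the coexistence gap collapses at the detected point
    try:
        cp = coexistence(
            design, T, P_azeo, ghs, seed=(x_azeo - 5e-4, x_azeo + 5e-4), mu_tol=1e-6
        )
        width = abs(cp.x_vapor - cp.x_liquid)
    except (NoRootError, ConvergenceError):
        width = float(np.max(np.abs(resid(sol.x))))
    if width > detection_tol:
        raise ConvergenceError(
            f"azeotrope detection did not collapse the coexistence gap "
            f"(width {width:.3g} at T={T}, P={P_azeo:.3g})"
        )
    return AzeotropePoint(T=T, P=P_azeo, x_azeo=x_azeo, width_at_detection=width)
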