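"""Iterative bond-energy tuning: relocate an azeotrope to a target composition.

Starting from a design with a known azeotrope, a single scalar energy
``eps_prime`` applied to a chosen set of bondable patch-type pairs (by
default the self-complementary pairs) is adjusted by secant iteration on
the azeotropic composition ``x_azeo(eps_prime)`` at fixed temperature.
Each trial energy re-solves the full azeotrope location (pressure scan +
tangency polish) through :func:`azeopatch.wertheim.find_azeotrope`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from azeopatch.graph import MixtureDesign
from azeopatch.wertheim import AzeotropePoint, ConvergenceError, NoRootError, find_azeotrope

__all__ = ["DesignIterationTrace", "shift_azeotrope", "self_complementary_pairs"]


@dataclass
class DesignIterationTrace:
    """History of the azeotrope-shifting loop.

    ``iterations`` holds (eps_prime, T_azeo, P_azeo, x_azeo) per accepted
    azeotrope solve, in order.
    """

    target_x: float
    iterations: list[tuple[float, float, float, float]] = field(default_factory=list)
    converged: bool = False

    @property
    def final_eps(self) -> float:
        return self.iterations[-1][0]

    @property
    def final_x(self) -> float:
        return self.iterations[-1][3]

    @property
    def final_design_energy(self) -> float:
        return self.final_eps


def self_complementary_pairs(design: MixtureDesign) -> list[tuple[int, int]]:
    """All patch-type self-loops (diagonal bonding entries) of a design."""
    order = design.patch_type_order
    return [
        (order[i], order[i])
        for i in range(design.n_patch_types)
        if design.energy_matrix[i, i] > 0
    ]


def shift_azeotrope(
    design: MixtureDesign,
    target_x: float,
    T: float,
    tunable_pairs: list[tuple[int, int]] | None = None,
    start: AzeotropePoint | None = None,
    tol: float = 0.01,
    max_iter: int = 20,
    initial_step: float = 0.1,
    ghs: str = "shell",
) -> DesignIterationTrace:
    """Tune ``eps_prime`` on ``tunable_pairs`` until the azeotrope sits at
    ``target_x``.

    Returns the iteration trace; raises if the azeotrope is lost or the
    secant loop does not converge within ``max_iter`` iterations.
    """
    if not 0.0 < target_x < 1.0:
        raise ValueError(f"target_x must lie in (0, 1), got {target_x}")
    if tunable_pairs is None:
        tunable_pairs = self_complementary_pairs(design)
    if not tunable_pairs:
        raise ValueError("design has no tunable pairs (no self-complementary patches)")
    for a, b in tunable_pairs:
        if design.energy(a, b) <= 0:
            raise ValueError(f"pair {(a, b)} is not a bonding pair of the design")

    eps0 = design.energy(*tunable_pairs[0])
    trace = DesignIterationTrace(target_x=target_x)

    def solve(eps_prime: float) -> AzeotropePoint:
        d = design.with_energy(tunable_pairs, eps_prime)
        return find_azeotrope(d, T, ghs=ghs)

    az = start if start is not None else solve(eps0)
    trace.iterations.append((eps0, az.T, az.P, az.x_azeo))
    if abs(az.x_azeo - target_x) < tol:
        trace.converged = True
        return trace

    # secant iteration on x_azeo(eps'); first step is a fixed perturbation
    # in the direction suggested by the target
    e_prev, x_prev = eps0, az.x_azeo
    e_cur = eps0 + (initial_step if target_x > az.x_azeo else -initial_step)
    for _ in range(max_iter):
        try:
            az = solve(e_cur)
        except (NoRootError, ConvergenceError) as err:
            raise ConvergenceError(
                f"azeotrope lost at eps'={e_cur:.4f}; last good state "
                f"eps'={e_prev:.4f}, x={x_prev:.4f}"
            ) from err
        trace.iterations.append((e_cur, az.T, az.P, az.x_azeo))
        if abs(az.x_azeo - target_x) < tol:
            trace.converged = True
            return trace
        denom = az.x_azeo - x_prev
        if denom == 0.0:
            raise ConvergenceError(
                f"azeotropic composition insensitive to eps' near {e_cur:.4f}"
            )
        e_next = e_cur + (target_x - az.x_azeo) * (e_cur - e_prev) / denom
        e_next = float(np.clip(e_next, 0.25 * e_cur, 4.0 * e_cur))  # guard wild steps
        e_prev, x_prev, e_cur = e_cur, az.x_azeo, e_next
    raise ConvergenceError(
        f"azeotrope shift did not converge in {max_iter} iterations "
        f"(last x_azeo={x_prev:.4f}, target {target_x})"
    )
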