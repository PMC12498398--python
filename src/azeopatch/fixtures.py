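"""Deterministic test fixtures: bonded dimers, random gases, synthetic
Ornstein-Zernike curves, and factory designs.

Every fixture is reproducible from (kind, parameters, seed); nothing is
read from disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from azeopatch.graph import (
    MixtureDesign,
    build_ideal_azeotrope_binary,
    build_n2c8,
    write_design,
)
from azeopatch.mc_engine import SimulationState, make_initial_config

__all__ = ["FixtureSpec", "generate_fixture", "bonded_dimer", "oz_curve", "hard_sphere_design"]


@dataclass
class FixtureSpec:
    kind: str  # dimer | random-gas | oz-curve | design
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def hard_sphere_design() -> MixtureDesign:
    """The binary tetrahedral mixture with all bonding energies zero."""
    base = build_ideal_azeotrope_binary()
    return MixtureDesign(
        species=list(base.species),
        energy_matrix=np.zeros_like(base.energy_matrix),
        kf=base.kf,
    )


def bonded_dimer(design: MixtureDesign, pair_index: int = 0, gap: float = 0.5) -> SimulationState:
    """Two particles with exactly one satisfied Kern-Frenkel bond.

    Particle 0 is placed at the box center with its first bondable patch
    pointing at particle 1, whose complementary patch points back; the
    separation sits mid-well (``sigma + gap * delta``).
    """
    adj = design.bonding_adjacency()
    owner = design.species_of_type
    pairs = [
        (i, j)
        for i in range(design.n_patch_types)
        for j in range(i, design.n_patch_types)
        if adj[i, j]
    ]
    ti, tj = pairs[pair_index]
    si, sj = int(owner[ti]), int(owner[tj])
    # local patch indices
    off = np.cumsum([0] + [sp.valence for sp in design.species])
    ai = ti - off[si]
    aj = tj - off[sj]
    vi = design.species[si].patch_vectors[ai]
    vj = design.species[sj].patch_vectors[aj]
    r = design.kf.sigma + gap * design.kf.delta
    L = 6.0 * design.kf.well_outer
    c = L / 2.0

    def quat_align(v_from, v_to):
        # shortest-arc quaternion rotating v_from onto v_to
        v_from = v_from / np.linalg.norm(v_from)
        v_to = v_to / np.linalg.norm(v_to)
        d = float(np.dot(v_from, v_to))
        if d > 1 - 1e-12:
            return np.array([1.0, 0.0, 0.0, 0.0])
        if d < -1 + 1e-12:
            axis = np.cross(v_from, [1.0, 0.0, 0.0])
            if np.linalg.norm(axis) < 1e-9:
                axis = np.cross(v_from, [0.0, 1.0, 0.0])
            axis /= np.linalg.norm(axis)
            return np.array([0.0, *axis])
        axis = np.cross(v_from, v_to)
        q = np.array([1.0 + d, *axis])
        return q / np.linalg.norm(q)

    e = np.array([1.0, 0.0, 0.0])
    q0 = quat_align(vi, e)  # patch of particle 0 points along +x
    q1 = quat_align(vj, -e)  # patch of particle 1 points along -x
    pos = np.array([[c, c, c], [c + r, c, c]])
    state = SimulationState(
        box=L,
        positions=pos,
        orientations=np.vstack([q0, q1]),
        species=np.array([si, sj], dtype=np.int64),
    )
    state.energy = state.compute_energy(design)
    return state


def oz_curve(
    s0: float = 0.7,
    xi_prod: float = 2.25,
    k_grid: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic structure-factor curve S(k) = s0 / (1 + k^2 xi_prod)."""
    if k_grid is None:
        k_grid = np.linspace(0.2, 2.0, 12)
    k_grid = np.asarray(k_grid, dtype=float)
    s = s0 / (1.0 + k_grid**2 * xi_prod)
    if noise > 0:
        s = s + np.random.default_rng(seed).normal(0.0, noise, size=len(k_grid))
    return k_grid, s


def generate_fixture(spec: FixtureSpec, out_dir: str | Path | None = None):
    """Build a fixture; if ``out_dir`` is given, also write it to disk.

    Kinds: ``dimer`` (bonded two-particle state), ``random-gas``
    (overlap-free random configuration), ``oz-curve`` (synthetic S(k)
    table), ``design`` (factory design file).
    """
    p = spec.parameters
    if spec.kind == "dimer":
        design = p.get("design") or build_ideal_azeotrope_binary()
        result = bonded_dimer(design, pair_index=p.get("pair_index", 0), gap=p.get("gap", 0.5))
    elif spec.kind == "random-gas":
        design = p.get("design") or hard_sphere_design()
        result = make_initial_config(
            p.get("n_per_species", [32, 32]), p.get("rho", 0.2), design, seed=spec.seed
        )
    elif spec.kind == "oz-curve":
        result = oz_curve(
            s0=p.get("s0", 0.7),
            xi_prod=p.get("xi_prod", 2.25),
            noise=p.get("noise", 0.0),
            seed=spec.seed,
        )
    elif spec.kind == "design":
        name = p.get("name", "n2c8")
        if name == "n2c8":
            result = build_n2c8(p.get("eps_prime", 1.0), p.get("eps", 1.0))
        elif name == "ideal":
            result = build_ideal_azeotrope_binary()
        elif name == "hard-sphere":
            result = hard_sphere_design()
        else:
            raise ValueError(f"unknown design fixture '{name}'")
    else:
        raise ValueError(f"unknown fixture kind '{spec.kind}'")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if spec.kind == "design":
            write_design(result, out_dir / "design.json")
        elif spec.kind == "oz-curve":
            k, s = result
            np.savetxt(out_dir / "oz_curve.csv", np.column_stack([k, s]),
                       delimiter=",", header="k,S", comments="")
        else:
            _write_xyz(result, out_dir / f"{spec.kind}.xyz")
    return result


def _write_xyz(state: SimulationState, path: Path) -> None:
    """Extended XYZ with species, position and quaternion per particle."""
    lines = [str(state.n), f'Lattice="{state.box} 0 0 0 {state.box} 0 0 0 {state.box}"']
    for i in range(state.n):
        x, y, z = state.positions[i]
        q = state.orientations[i]
        lines.append(
            f"S{state.species[i]} {x:.12f} {y:.12f} {z:.12f} "
            f"{q[0]:.12f} {q[1]:.12f} {q[2]:.12f} {q[3]:.12f}"
        )
    path.write_text("\n".join(lines) + "\n")
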