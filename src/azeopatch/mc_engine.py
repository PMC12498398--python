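"""Kern-Frenkel Monte Carlo: NVT, NPT, Gibbs-ensemble and grand-canonical
sampling of patchy-particle mixtures.

The pair interaction is a square well of depth ``eps_ag`` and width
``delta`` modulated by an orientational switch: two patches bond only if
each patch vector points at the partner within the angular width of the
patch (``cos θ > cos θmax`` for both) and the centers lie inside the well.

Move set: single-particle translations and small-angle quaternion
rotations, aggregation-volume-bias (AVB) in/out moves on bonding shells,
log-volume moves (NPT), volume exchange and species-preserving particle
transfers (Gibbs ensemble), identity swaps between boxes (Gibbs;
equivalent to paired counter-transfers), and insertions/deletions (GCMC).
Energies are tracked incrementally and audited against full recomputation
at every observable stride.

Reduced units throughout: sigma = 1, reference bond energy = 1, k_B = 1.
Boxes are cubic and periodic; neighbor search is a plain O(N) loop, which
is the right trade-off at the particle counts this package targets
(N <~ 10^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from azeopatch import _kernels as K
from azeopatch.graph import MixtureDesign

__all__ = [
    "SimulationState",
    "GibbsState",
    "MoveSchedule",
    "SimResult",
    "GibbsResult",
    "Frame",
    "pair_energy",
    "make_initial_config",
    "run_nvt",
    "run_npt",
    "run_gibbs",
    "run_gcmc",
    "avb_move",
    "block_average",
]


@dataclass
class _DesignArrays:
    npatch: np.ndarray
    pvec: np.ndarray
    ptype: np.ndarray
    eps: np.ndarray
    sigma: float
    rc: float
    sigma2: float
    rc2: float
    costh: float


def _design_arrays(design: MixtureDesign) -> _DesignArrays:
    S = design.n_species
    pmax = int(design.valences.max())
    npatch = design.valences.astype(np.int64)
    pvec = np.zeros((S, pmax, 3))
    ptype = np.zeros((S, pmax), dtype=np.int64)
    order = {t: i for i, t in enumerate(design.patch_type_order)}
    for si, sp in enumerate(design.species):
        pvec[si, : sp.valence] = sp.patch_vectors
        for a, t in enumerate(sp.patch_type_ids):
            ptype[si, a] = order[t]
    kf = design.kf
    return _DesignArrays(
        npatch=npatch,
        pvec=pvec,
        ptype=ptype,
        eps=np.ascontiguousarray(design.energy_matrix),
        sigma=kf.sigma,
        rc=kf.well_outer,
        sigma2=kf.sigma**2,
        rc2=kf.well_outer**2,
        costh=kf.cos_theta_max,
    )


def _dargs(d: _DesignArrays) -> tuple:
    return (d.npatch, d.pvec, d.ptype, d.eps, d.sigma2, d.rc2, d.costh)


@dataclass
class SimulationState:
    """Particles in one periodic cubic box."""

    box: float
    positions: np.ndarray  # (N, 3)
    orientations: np.ndarray  # (N, 4) unit quaternions (w, x, y, z)
    species: np.ndarray  # (N,) indices into design.species
    energy: float = np.nan  # cached total potential energy

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def rho(self) -> float:
        return self.n / self.box**3

    def composition(self, n_species: int = 2) -> np.ndarray:
        return np.bincount(self.species, minlength=n_species) / max(self.n, 1)

    def compute_energy(self, design: MixtureDesign) -> float:
        d = _design_arrays(design)
        return float(
            K.total_energy(
                self.positions, self.orientations, self.species.astype(np.int64),
                self.n, self.box, *_dargs(d),
            )
        )

    def validate(self, design: MixtureDesign) -> None:
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("orientation quaternions must be unit-normalized")
        e = self.compute_energy(design)
        if e >= 0.5 * K.BIG:
            raise ValueError("state contains hard-core overlaps")
        if np.isfinite(self.energy):
            if abs(e - self.energy) > 1e-9 * max(1.0, abs(e)):
                raise ValueError(
                    f"cached energy {self.energy} inconsistent with recomputation {e}"
                )
        else:
            self.energy = e

    def copy(self) -> "SimulationState":
        return SimulationState(
            box=self.box,
            positions=self.positions.copy(),
            orientations=self.orientations.copy(),
            species=self.species.copy(),
            energy=self.energy,
        )


@dataclass
class GibbsState:
    """Two coupled boxes exchanging volume and particles."""

    box_a: SimulationState
    box_b: SimulationState

    @property
    def n_total(self) -> int:
        return self.box_a.n + self.box_b.n

    @property
    def v_total(self) -> float:
        return self.box_a.box**3 + self.box_b.box**3

    def species_totals(self, n_species: int = 2) -> np.ndarray:
        return np.bincount(self.box_a.species, minlength=n_species) + np.bincount(
            self.box_b.species, minlength=n_species
        )


@dataclass
class MoveSchedule:
    """Per-move attempt probabilities and step sizes.

    Probabilities are renormalized over the moves each ensemble actually
    uses (e.g. ``volume`` is ignored in NVT).  ``exchange`` is the
    transfer probability in the Gibbs ensemble and the insertion/deletion
    probability in GCMC.
    """

    translate: float = 0.4
    rotate: float = 0.4
    avb: float = 0.1
    volume: float = 0.02
    exchange: float = 0.05
    swap: float = 0.03
    max_disp: float = 0.2
    max_rot: float = 0.4
    max_lnv: float = 0.04
    max_dzeta: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("translate", "rotate", "avb", "volume", "exchange", "swap"):
            if getattr(self, name) < 0:
                raise ValueError(f"move probability '{name}' must be >= 0")
        if self.translate + self.rotate + self.avb <= 0:
            raise ValueError("at least one intra-box move must have weight > 0")

    def _norm(self, *names: str) -> dict:
        tot = sum(getattr(self, n) for n in names)
        return {n: getattr(self, n) / tot for n in names}


@dataclass
class Frame:
    sweep: int
    box: float
    positions: np.ndarray
    species: np.ndarray


@dataclass
class SimResult:
    observables: pd.DataFrame
    frames: list[Frame]
    state: SimulationState
    max_energy_drift: float
    acceptance: dict


@dataclass
class GibbsResult:
    observables: pd.DataFrame
    state: GibbsState
    max_energy_drift: float
    acceptance: dict


def pair_energy(r_i, r_j, q_i, q_j, s_i, s_j, design: MixtureDesign, box: float | None = None):
    """Kern-Frenkel energy of one pair (minimum image if ``box`` given)."""
    d = _design_arrays(design)
    dr = np.asarray(r_j, dtype=float) - np.asarray(r_i, dtype=float)
    if box is not None:
        dr -= box * np.rint(dr / box)
    e = K.pair_energy_kernel(
        dr[0], dr[1], dr[2],
        np.asarray(q_i, dtype=float), np.asarray(q_j, dtype=float),
        int(s_i), int(s_j), *_dargs(d),
    )
    return np.inf if e >= 0.5 * K.BIG else float(e)


def make_initial_config(
    n_per_species: list[int] | np.ndarray,
    rho: float,
    design: MixtureDesign,
    seed: int = 0,
    max_attempts: int = 2000,
) -> SimulationState:
    """Random overlap-free configuration with random orientations.

    Particles are inserted one by one at uniform random positions,
    re-drawing on hard-core overlap.  Feasible for packing fractions up to
    ~0.45; denser states must be prepared by compression.
    """
    n_per_species = np.asarray(n_per_species, dtype=int)
    n = int(n_per_species.sum())
    phi = rho * np.pi / 6.0 * design.kf.sigma**3
    if phi >= 0.45:
        raise ValueError(f"packing fraction {phi:.3f} too high for random insertion")
    L = (n / rho) ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)
    pos = np.empty((n, 3))
    sigma2 = design.kf.sigma**2
    for i in range(n):
        for attempt in range(max_attempts):
            trial = rng.random(3) * L
            dr = pos[:i] - trial
            dr -= L * np.rint(dr / L)
            if i == 0 or np.min(np.einsum("ij,ij->i", dr, dr)) >= sigma2:
                pos[i] = trial
                break
        else:
            raise RuntimeError(f"random insertion failed for particle {i} at phi={phi:.3f}")
    # uniform random orientations (Shoemake)
    u = rng.random((n, 3))
    a, b = np.sqrt(1.0 - u[:, 0]), np.sqrt(u[:, 0])
    quat = np.column_stack(
        [
            a * np.sin(2 * np.pi * u[:, 1]),
            a * np.cos(2 * np.pi * u[:, 1]),
            b * np.sin(2 * np.pi * u[:, 2]),
            b * np.cos(2 * np.pi * u[:, 2]),
        ]
    )
    species = np.repeat(np.arange(len(n_per_species)), n_per_species).astype(np.int64)
    rng.shuffle(species)
    state = SimulationState(box=L, positions=pos, orientations=quat, species=species)
    state.energy = state.compute_energy(design)
    return state


def _chunk_seeds(seed: int, n_chunks: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n_chunks) % np.uint32(2**31 - 1)).astype(np.int64) + 1


def block_average(series: np.ndarray, n_blocks: int = 10) -> tuple[float, float]:
    """Mean and standard error by block averaging (>= 10 blocks default)."""
    series = np.asarray(series, dtype=float)
    n = len(series) - (len(series) % n_blocks)
    if n < n_blocks:
        return float(np.mean(series)), float(np.std(series, ddof=1) / np.sqrt(len(series)))
    blocks = series[:n].reshape(n_blocks, -1).mean(axis=1)
    return float(np.mean(blocks)), float(np.std(blocks, ddof=1) / np.sqrt(n_blocks))


def run_nvt(
    state: SimulationState,
    design: MixtureDesign,
    T: float,
    schedule: MoveSchedule | None = None,
    sweeps: int = 10_000,
    stride: int = 100,
    frame_stride: int | None = None,
) -> SimResult:
    """Canonical-ensemble run; one sweep = N attempted moves.

    Returns observables (sweep, E, e_per_particle), stored frames, the
    final state and the maximum incremental-vs-recomputed energy drift.
    """
    schedule = schedule or MoveSchedule()
    d = _design_arrays(design)
    st = state.copy()
    if not np.isfinite(st.energy):
        st.energy = st.compute_energy(design)
    p = schedule._norm("translate", "rotate", "avb")
    n_chunks = max(1, sweeps // stride)
    seeds = _chunk_seeds(schedule.seed, n_chunks)
    rows = []
    frames: list[Frame] = []
    frame_stride = frame_stride or stride
    max_drift = 0.0
    acc_tot = 0
    e = st.energy
    for c in range(n_chunks):
        n_moves = stride * st.n
        e, acc = K.run_nvt_chunk(
            st.positions, st.orientations, st.species, st.n, st.box, T, e,
            n_moves, p["rotate"], p["avb"], schedule.max_disp, schedule.max_rot,
            d.sigma, d.rc, *_dargs(d), seeds[c],
        )
        acc_tot += acc
        sweep = (c + 1) * stride
        e_full = st.compute_energy(design)
        max_drift = max(max_drift, abs(e - e_full))
        e = e_full
        rows.append({"sweep": sweep, "E": e, "e_per_particle": e / st.n})
        if sweep % frame_stride == 0:
            frames.append(
                Frame(sweep=sweep, box=st.box, positions=st.positions.copy(),
                      species=st.species.copy())
            )
    st.energy = e
    return SimResult(
        observables=pd.DataFrame(rows),
        frames=frames,
        state=st,
        max_energy_drift=max_drift,
        acceptance={"moves": acc_tot / max(1, sweeps * st.n)},
    )


def run_npt(
    state: SimulationState,
    design: MixtureDesign,
    T: float,
    P: float,
    schedule: MoveSchedule | None = None,
    sweeps: int = 10_000,
    stride: int = 100,
    frame_stride: int | None = None,
) -> SimResult:
    """Isothermal-isobaric run with log-volume moves."""
    schedule = schedule or MoveSchedule()
    d = _design_arrays(design)
    st = state.copy()
    if not np.isfinite(st.energy):
        st.energy = st.compute_energy(design)
    p = schedule._norm("translate", "rotate", "avb", "volume")
    n_chunks = max(1, sweeps // stride)
    seeds = _chunk_seeds(schedule.seed, n_chunks)
    rows = []
    frames: list[Frame] = []
    frame_stride = frame_stride or stride
    max_drift = 0.0
    acc_tot = 0
    accv_tot = 0
    e = st.energy
    L = st.box
    for c in range(n_chunks):
        n_moves = stride * st.n
        e, L, acc, accv = K.run_npt_chunk(
            st.positions, st.orientations, st.species, st.n, L, T, P, e,
            n_moves, p["rotate"], p["avb"], p["volume"],
            schedule.max_disp, schedule.max_rot, schedule.max_lnv,
            d.sigma, d.rc, *_dargs(d), seeds[c],
        )
        st.box = L
        acc_tot += acc
        accv_tot += accv
        sweep = (c + 1) * stride
        e_full = st.compute_energy(design)
        max_drift = max(max_drift, abs(e - e_full))
        e = e_full
        rows.append(
            {
                "sweep": sweep, "E": e, "L": L, "V": L**3,
                "rho": st.n / L**3,
                "phi": st.n / L**3 * np.pi / 6 * design.kf.sigma**3,
            }
        )
        if sweep % frame_stride == 0:
            frames.append(
                Frame(sweep=sweep, box=L, positions=st.positions.copy(),
                      species=st.species.copy())
            )
    st.energy = e
    return SimResult(
        observables=pd.DataFrame(rows),
        frames=frames,
        state=st,
        max_energy_drift=max_drift,
        acceptance={
            "moves": acc_tot / max(1, sweeps * st.n),
            "volume": accv_tot / max(1, sweeps),
        },
    )


def run_gibbs(
    gstate: GibbsState,
    design: MixtureDesign,
    T: float,
    schedule: MoveSchedule | None = None,
    sweeps: int = 10_000,
    stride: int = 100,
) -> GibbsResult:
    """Gibbs-ensemble run over two boxes at fixed (N_total, V_total, T).

    Observables per stride and per box: particle number, volume, density,
    composition of species 0, and energy.  Total particle count and volume
    are conserved exactly by construction.
    """
    schedule = schedule or MoveSchedule()
    d = _design_arrays(design)
    a = gstate.box_a.copy()
    b = gstate.box_b.copy()
    for st in (a, b):
        if not np.isfinite(st.energy):
            st.energy = st.compute_energy(design)
    cap = a.n + b.n
    # fixed-capacity arrays so transfers never reallocate
    def _cap(st: SimulationState):
        pos = np.zeros((cap, 3))
        pos[: st.n] = st.positions
        quat = np.zeros((cap, 4))
        quat[: st.n] = st.orientations
        spc = np.zeros(cap, dtype=np.int64)
        spc[: st.n] = st.species
        return pos, quat, spc

    pos_a, quat_a, spec_a = _cap(a)
    pos_b, quat_b, spec_b = _cap(b)
    na, nb = a.n, b.n
    La, Lb = a.box, b.box
    ea, eb = a.energy, b.energy
    pin = schedule._norm("translate", "rotate", "avb")
    pout = schedule._norm("volume", "exchange", "swap")
    # overall probabilities: inter-box moves get their share, intra-box the rest
    inter = min(0.999, schedule.volume + schedule.exchange + schedule.swap)
    p_vol = inter * pout["volume"]
    p_tr = inter * pout["exchange"]
    p_sw = inter * pout["swap"]
    n_chunks = max(1, sweeps // stride)
    seeds = _chunk_seeds(schedule.seed, n_chunks)
    rows = []
    max_drift = 0.0
    acc = {"transfer": 0, "volume": 0, "swap": 0}
    n_species = design.n_species
    for c in range(n_chunks):
        n_moves = stride * cap
        na, La, ea, nb, Lb, eb, atr, av, asw = K.run_gibbs_chunk(
            pos_a, quat_a, spec_a, na, La,
            pos_b, quat_b, spec_b, nb, Lb,
            T, ea, eb, n_moves,
            pin["rotate"], pin["avb"], p_vol, p_tr, p_sw,
            schedule.max_disp, schedule.max_rot, schedule.max_dzeta,
            d.sigma, d.rc, *_dargs(d), seeds[c],
        )
        acc["transfer"] += atr
        acc["volume"] += av
        acc["swap"] += asw
        ea_full = K.total_energy(pos_a, quat_a, spec_a, na, La, *_dargs(d))
        eb_full = K.total_energy(pos_b, quat_b, spec_b, nb, Lb, *_dargs(d))
        max_drift = max(max_drift, abs(ea - ea_full), abs(eb - eb_full))
        ea, eb = ea_full, eb_full
        sweep = (c + 1) * stride
        xa = np.bincount(spec_a[:na], minlength=n_species) / max(na, 1)
        xb = np.bincount(spec_b[:nb], minlength=n_species) / max(nb, 1)
        rows.append(
            {
                "sweep": sweep,
                "N_a": na, "V_a": La**3, "rho_a": na / La**3, "x_a": xa[0], "E_a": ea,
                "N_b": nb, "V_b": Lb**3, "rho_b": nb / Lb**3, "x_b": xb[0], "E_b": eb,
            }
        )
    out_a = SimulationState(
        box=La, positions=pos_a[:na].copy(), orientations=quat_a[:na].copy(),
        species=spec_a[:na].copy(), energy=ea,
    )
    out_b = SimulationState(
        box=Lb, positions=pos_b[:nb].copy(), orientations=quat_b[:nb].copy(),
        species=spec_b[:nb].copy(), energy=eb,
    )
    return GibbsResult(
        observables=pd.DataFrame(rows),
        state=GibbsState(box_a=out_a, box_b=out_b),
        max_energy_drift=max_drift,
        acceptance=acc,
    )


def run_gcmc(
    state: SimulationState,
    design: MixtureDesign,
    T: float,
    mu: float | np.ndarray,
    schedule: MoveSchedule | None = None,
    sweeps: int = 10_000,
    stride: int = 100,
    capacity: int | None = None,
) -> SimResult:
    """Grand-canonical run at per-species chemical potentials ``mu``.

    A scalar ``mu`` applies to every species present.  Thermal de Broglie
    volumes are taken as 1, matching the theory-side convention, so the
    chemical potentials are directly comparable with
    :func:`azeopatch.wertheim.chemical_potentials`.
    """
    schedule = schedule or MoveSchedule()
    d = _design_arrays(design)
    st = state.copy()
    if not np.isfinite(st.energy):
        st.energy = st.compute_energy(design)
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    if len(mu_arr) == 1:
        mu_arr = np.full(design.n_species, mu_arr[0])
    cap = capacity or max(4 * st.n, 512)
    pos = np.zeros((cap, 3))
    pos[: st.n] = st.positions
    quat = np.zeros((cap, 4))
    quat[: st.n] = st.orientations
    spc = np.zeros(cap, dtype=np.int64)
    spc[: st.n] = st.species
    n = st.n
    e = st.energy
    p = schedule._norm("translate", "rotate", "avb")
    p_ex = min(0.8, schedule.exchange)
    scale = 1.0 - p_ex
    n_chunks = max(1, sweeps // stride)
    seeds = _chunk_seeds(schedule.seed, n_chunks)
    rows = []
    max_drift = 0.0
    ins_tot = 0
    del_tot = 0
    nominal = max(n, 1)
    for c in range(n_chunks):
        n_moves = stride * nominal
        n, e, ins, dels = K.run_gcmc_chunk(
            pos, quat, spc, n, cap, st.box, T, mu_arr, e, n_moves,
            scale * p["rotate"], scale * p["avb"], p_ex,
            schedule.max_disp, schedule.max_rot, d.sigma, d.rc,
            *_dargs(d), seeds[c],
        )
        ins_tot += ins
        del_tot += dels
        e_full = K.total_energy(pos, quat, spc, n, st.box, *_dargs(d))
        max_drift = max(max_drift, abs(e - e_full))
        e = e_full
        sweep = (c + 1) * stride
        rows.append({"sweep": sweep, "N": n, "rho": n / st.box**3, "E": e})
    out = SimulationState(
        box=st.box, positions=pos[:n].copy(), orientations=quat[:n].copy(),
        species=spc[:n].copy(), energy=e,
    )
    return SimResult(
        observables=pd.DataFrame(rows),
        frames=[],
        state=out,
        max_energy_drift=max_drift,
        acceptance={
            "insert": ins_tot / max(1, sweeps * nominal),
            "delete": del_tot / max(1, sweeps * nominal),
        },
    )


def avb_move(state: SimulationState, design: MixtureDesign, T: float, seed: int = 0) -> bool:
    """Attempt a single AVB in/out move on the state (in place)."""
    d = _design_arrays(design)
    if not np.isfinite(state.energy):
        state.energy = state.compute_energy(design)
    K.seed_rng(int(seed) % (2**31 - 1) + 1)
    ok, de = K._try_avb(
        state.positions, state.orientations, state.species, state.n, state.box,
        1.0 / T, d.sigma, d.rc, *_dargs(d),
    )
    if ok:
        state.energy += de
    return bool(ok)


def avb_acceptance_factor(
    n_in: int,
    n_out: int,
    V: float,
    v_in: float,
    to_in: bool,
    dE: float,
    T: float,
    valence: int = 4,
    cos_theta_max: float = 0.98,
    aligned_count: int = 1,
) -> float:
    """The AVBMC acceptance ratio R for a proposed in/out move.

    ``min(1, R)`` is the acceptance probability.  In-moves use an
    orientation-biased proposal (a uniformly chosen patch is aligned into
    the back-cone), contributing the density factor
    ``valence * (1 - cos_theta_max) / 2 / aligned_count``; out-moves carry
    its inverse.  For a forced in<->out pair of moves on the same geometry
    the two R factors multiply to 1, the detailed-balance identity the
    move relies on.
    """
    afac = valence * (1.0 - cos_theta_max) / 2.0
    if to_in:
        pref = n_out * v_in / ((n_in + 1.0) * V) * afac / aligned_count
    else:
        pref = n_in * V / ((n_out + 1.0) * v_in) * aligned_count / afac
    return pref * float(np.exp(-dE / T))
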