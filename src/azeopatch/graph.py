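"""Mixture designs as species/patch interaction graphs.

A design is a graph whose nodes are species and their patches, and whose
patch-patch edges carry bonding energies.  Patches are *typed*: every patch
type is globally unique across species, and the symmetric matrix
``energy_matrix`` over all patch types holds the bonding energy
:math:`\\epsilon_{\\alpha\\gamma} \\ge 0` of each pair (zero means the pair
never bonds).  Self-loops (diagonal entries) encode self-complementary
patches.

Energies are measured in units of a reference bond energy
:math:`\\epsilon = 1`; temperatures elsewhere in the package are in units of
:math:`\\epsilon/k_B`, lengths in units of the hard-core diameter
:math:`\\sigma`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DesignError",
    "KernFrenkelParams",
    "SpeciesSpec",
    "MixtureDesign",
    "tetrahedral_patch_vectors",
    "build_n2c8",
    "build_ideal_azeotrope_binary",
    "is_bond_exclusive",
    "is_ideal_azeotropic",
    "read_design",
    "write_design",
]


class DesignError(ValueError):
    """Raised when a mixture design violates a structural invariant."""


@dataclass(frozen=True)
class KernFrenkelParams:
    """Geometry of the Kern-Frenkel patch interaction.

    Parameters
    ----------
    sigma
        Hard-core diameter (reduced length unit).
    delta
        Width of the attractive square well beyond contact; a patch pair
        interacts only for center separations in ``[sigma, sigma + delta)``.
    cos_theta_max
        Cosine of the angular half-width of a patch.  A patch participates
        in a bond only if its unit vector is aligned with the center-center
        axis to better than ``theta_max``.
    """

    sigma: float = 1.0
    delta: float = 0.2
    cos_theta_max: float = 0.98

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise DesignError(f"sigma must be positive, got {self.sigma}")
        if not 0 < self.delta < self.sigma:
            raise DesignError(f"delta must lie in (0, sigma), got {self.delta}")
        if not 0 < self.cos_theta_max < 1:
            raise DesignError(
                f"cos_theta_max must lie in (0, 1), got {self.cos_theta_max}"
            )

    @property
    def well_outer(self) -> float:
        return self.sigma + self.delta

    def bond_volume(self) -> float:
        """Volume of the single-patch bonding region.

        Shell volume between ``sigma`` and ``sigma + delta`` times the solid
        angle fraction ``(1 - cos_theta_max) / 2`` of one patch cone.
        """
        shell = 4.0 * np.pi / 3.0 * (self.well_outer**3 - self.sigma**3)
        return shell * (1.0 - self.cos_theta_max) / 2.0


@dataclass(frozen=True)
class SpeciesSpec:
    """One particle species: its global patch types and their placement."""

    species_id: int
    patch_type_ids: tuple[int, ...]
    patch_vectors: np.ndarray  # (n_patches, 3), unit rows

    def __post_init__(self) -> None:
        vec = np.asarray(self.patch_vectors, dtype=float)
        object.__setattr__(self, "patch_vectors", vec)
        object.__setattr__(self, "patch_type_ids", tuple(int(t) for t in self.patch_type_ids))
        if vec.ndim != 2 or vec.shape[1] != 3:
            raise DesignError(
                f"species {self.species_id}: patch_vectors must be (n, 3), got {vec.shape}"
            )
        if len(self.patch_type_ids) != vec.shape[0]:
            raise DesignError(
                f"species {self.species_id}: {len(self.patch_type_ids)} patch ids "
                f"but {vec.shape[0]} patch vectors"
            )
        norms = np.linalg.norm(vec, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise DesignError(
                f"species {self.species_id}: patch_vectors must be unit length "
                f"(norms {norms})"
            )

    @property
    def valence(self) -> int:
        return len(self.patch_type_ids)


@dataclass
class MixtureDesign:
    """A mixture of patchy-particle species with a typed interaction matrix.

    ``energy_matrix`` is indexed in the order in which patch types appear
    when species are concatenated (``patch_type_order``).  It is the single
    source of truth for bond connectivity: the bonding graph is exactly the
    set of pairs with a strictly positive entry.
    """

    species: list[SpeciesSpec]
    energy_matrix: np.ndarray
    kf: KernFrenkelParams = field(default_factory=KernFrenkelParams)

    def __post_init__(self) -> None:
        self.energy_matrix = np.asarray(self.energy_matrix, dtype=float)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def patch_type_order(self) -> tuple[int, ...]:
        return tuple(t for sp in self.species for t in sp.patch_type_ids)

    @property
    def n_patch_types(self) -> int:
        return len(self.patch_type_order)

    def type_index(self, patch_type_id: int) -> int:
        return self.patch_type_order.index(patch_type_id)

    @property
    def species_of_type(self) -> np.ndarray:
        """Species index (position in ``self.species``) owning each patch type."""
        owner = np.empty(self.n_patch_types, dtype=np.int64)
        k = 0
        for si, sp in enumerate(self.species):
            owner[k : k + sp.valence] = si
            k += sp.valence
        return owner

    @property
    def valences(self) -> np.ndarray:
        return np.array([sp.valence for sp in self.species], dtype=np.int64)

    def bonding_adjacency(self) -> np.ndarray:
        """Boolean adjacency of the patch-patch bonding graph."""
        return self.energy_matrix > 0.0

    def energy(self, type_a: int, type_b: int) -> float:
        return float(self.energy_matrix[self.type_index(type_a), self.type_index(type_b)])

    def with_energy(self, pairs: list[tuple[int, int]], value: float) -> "MixtureDesign":
        """Return a copy with the listed patch-type pairs set to ``value``."""
        mat = self.energy_matrix.copy()
        for a, b in pairs:
            ia, ib = self.type_index(a), self.type_index(b)
            mat[ia, ib] = mat[ib, ia] = value
        return MixtureDesign(species=list(self.species), energy_matrix=mat, kf=self.kf)

    def validate(self) -> None:
        ids = [t for sp in self.species for t in sp.patch_type_ids]
        if len(ids) != len(set(ids)):
            raise DesignError("patch_type_ids must be globally unique across species")
        n = len(ids)
        if self.energy_matrix.shape != (n, n):
            raise DesignError(
                f"energy_matrix must be ({n}, {n}) for {n} patch types, "
                f"got {self.energy_matrix.shape}"
            )
        if not np.allclose(self.energy_matrix, self.energy_matrix.T, atol=0.0):
            raise DesignError("energy_matrix must be symmetric")
        if np.any(self.energy_matrix < 0):
            raise DesignError("energy_matrix entries must be >= 0")


def tetrahedral_patch_vectors() -> np.ndarray:
    """Four unit vectors pointing to alternating cube corners (tetrahedron)."""
    v = np.array(
        [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
    )
    return v / np.sqrt(3.0)


def _binary_tetrahedral_species() -> list[SpeciesSpec]:
    vecs = tetrahedral_patch_vectors()
    return [
        SpeciesSpec(species_id=1, patch_type_ids=(1, 2, 3, 4), patch_vectors=vecs),
        SpeciesSpec(species_id=2, patch_type_ids=(5, 6, 7, 8), patch_vectors=vecs),
    ]


def _matrix_from_pairs(
    order: tuple[int, ...], pairs: dict[tuple[int, int], float]
) -> np.ndarray:
    idx = {t: i for i, t in enumerate(order)}
    mat = np.zeros((len(order), len(order)))
    for (a, b), eps in pairs.items():
        mat[idx[a], idx[b]] = eps
        mat[idx[b], idx[a]] = eps
    return mat


def build_n2c8(eps_prime: float = 1.0, eps: float = 1.0) -> MixtureDesign:
    """The N2c8 binary design: 2 species x 4 tetrahedral patches, 8 patch types.

    The bonding graph is bond-exclusive: every patch type has exactly one
    partner.  Patch types 2 and 3 (both on species 1) are self-complementary
    (diagonal edges 2-2 and 3-3) and carry energy ``eps_prime``; patches 6
    and 7 on species 2 bond each other, and the remaining cross-species
    pairs are 1-5 and 4-8.  All edges other than 2-2 and 3-3 carry ``eps``.
    With ``eps_prime == eps`` the design is thermodynamically symmetric
    under species exchange (two self-loops on species 1 play the same
    mass-action role as the intra-species 6-7 pair on species 2), so the
    tunable pairs 2-2 and 3-3 shift the azeotrope away from equimolarity.
    """
    if eps <= 0 or eps_prime <= 0:
        raise DesignError("bonding energies must be positive")
    pairs = {
        (1, 5): eps,
        (2, 2): eps_prime,
        (3, 3): eps_prime,
        (4, 8): eps,
        (6, 7): eps,
    }
    species = _binary_tetrahedral_species()
    order = tuple(t for sp in species for t in sp.patch_type_ids)
    return MixtureDesign(species=species, energy_matrix=_matrix_from_pairs(order, pairs))


def build_ideal_azeotrope_binary() -> MixtureDesign:
    """Binary design that is azeotropic at every composition.

    Every patch type has exactly two complementary patch types, one on each
    species, and all bonding energies are equal (to 1).  Under the law of
    mass action the species-sum then collapses and every patch's not-bonded
    probability becomes independent of composition.
    """
    pairs = {
        (1, 2): 1.0,
        (3, 4): 1.0,
        (5, 6): 1.0,
        (7, 8): 1.0,
        (1, 5): 1.0,
        (2, 6): 1.0,
        (3, 7): 1.0,
        (4, 8): 1.0,
    }
    species = _binary_tetrahedral_species()
    order = tuple(t for sp in species for t in sp.patch_type_ids)
    return MixtureDesign(species=species, energy_matrix=_matrix_from_pairs(order, pairs))


def _partner_counts(design: MixtureDesign) -> np.ndarray:
    """Number of distinct partner patch types of each patch type.

    A self-loop counts as one partner (the patch type itself).
    """
    return design.bonding_adjacency().sum(axis=1)


def is_bond_exclusive(design: MixtureDesign) -> bool:
    """True iff every patch type has exactly one bondable partner overall."""
    return bool(np.all(_partner_counts(design) == 1))


def is_ideal_azeotropic(design: MixtureDesign) -> bool:
    """True iff each patch has exactly one partner *per species* and all
    bonding energies are equal."""
    adj = design.bonding_adjacency()
    owner = design.species_of_type
    for alpha in range(design.n_patch_types):
        for si in range(design.n_species):
            if int(adj[alpha, owner == si].sum()) != 1:
                return False
    nonzero = design.energy_matrix[adj]
    return bool(nonzero.size == 0 or np.allclose(nonzero, nonzero[0], rtol=0, atol=0))


# -- serialization ---------------------------------------------------------


def write_design(design: MixtureDesign, path: str | Path) -> None:
    """Write a design to JSON (sparse symmetric energy entries, ``"a-g"`` keys)."""
    emat = {}
    order = design.patch_type_order
    for i in range(design.n_patch_types):
        for j in range(i, design.n_patch_types):
            if design.energy_matrix[i, j] > 0:
                emat[f"{order[i]}-{order[j]}"] = design.energy_matrix[i, j]
    doc = {
        "kern_frenkel": {
            "sigma": design.kf.sigma,
            "delta": design.kf.delta,
            "cos_theta_max": design.kf.cos_theta_max,
        },
        "species": [
            {
                "id": sp.species_id,
                "patch_types": list(sp.patch_type_ids),
                "patch_vectors": sp.patch_vectors.tolist(),
            }
            for sp in design.species
        ],
        "energy_matrix": emat,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_design(path: str | Path) -> MixtureDesign:
    """Read a design from JSON, applying symmetric completion and validation."""
    doc = json.loads(Path(path).read_text())
    for key in ("kern_frenkel", "species", "energy_matrix"):
        if key not in doc:
            raise DesignError(f"design file missing required key '{key}'")
    kf = KernFrenkelParams(**doc["kern_frenkel"])
    species = []
    for sp in doc["species"]:
        species.append(
            SpeciesSpec(
                species_id=int(sp["id"]),
                patch_type_ids=tuple(sp["patch_types"]),
                patch_vectors=np.asarray(sp["patch_vectors"], dtype=float),
            )
        )
    order = tuple(t for sp in species for t in sp.patch_type_ids)
    idx = {t: i for i, t in enumerate(order)}
    n = len(order)
    mat = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for key, eps in doc["energy_matrix"].items():
        a_s, b_s = key.split("-")
        a, b = int(a_s), int(b_s)
        if a not in idx or b not in idx:
            raise DesignError(f"energy_matrix key '{key}' names unknown patch type")
        pair = (min(a, b), max(a, b))
        if pair in seen and seen[pair] != eps:
            raise DesignError(
                f"energy_matrix entries for pair {pair} are inconsistent "
                f"({seen[pair]} vs {eps}): matrix must be symmetric"
            )
        seen[pair] = float(eps)
        mat[idx[a], idx[b]] = eps
        mat[idx[b], idx[a]] = eps
    return MixtureDesign(species=species, energy_matrix=mat, kf=kf)
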