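"""Reduced model systems for charge-transfer electron dynamics.

A :class:`ModelSystem` is a site-basis stand-in for a molecule: each site
carries an energy, a position, a nuclear charge and an on-site Hubbard-like
interaction strength; sites are grouped into chemically meaningful fragments
(donor / bridge / acceptor, metal hub / ligand arms). The site basis plays
the role of the atomic-orbital basis; a general symmetric positive-definite
overlap is supported, identity by default.

The effective one-electron Hamiltonian is

    F(P) = H0 + diag(U_mu * (P S)_mu_mu)

i.e. a mean-field on-site interaction that makes the equation of motion
genuinely nonlinear while reducing to exactly solvable linear dynamics when
all U_mu = 0. ``H0`` collects site energies, inter-site couplings and, when
present, the electrostatic potential of embedding point charges.

Units: energies in hartree, positions in angstrom (converted to bohr
internally), charges in units of e, dipole operators in e*bohr.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_PER_ANGSTROM
from .state import DensityMatrix, FockMatrix, lowdin_inverse, spd_sqrt

__all__ = [
    "FragmentScheme",
    "EmbeddingCharges",
    "ModelSystem",
    "build_chain_model",
    "build_star_model",
    "add_point_charge_embedding",
    "mean_field_fock",
]

#: minimum allowed distance between an embedding charge and a site (angstrom)
MIN_EMBEDDING_DISTANCE = 1e-6


@dataclass
class FragmentScheme:
    """Partition of sites into named fragments.

    ``site_to_fragment[mu]`` is the index into ``names`` of the fragment that
    owns site ``mu``; every site is mapped exactly once.
    """

    names: list
    site_to_fragment: np.ndarray

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.site_to_fragment = np.asarray(self.site_to_fragment, dtype=int)
        if len(set(self.names)) != len(self.names):
            raise ValueError("fragment names must be unique")
        if self.site_to_fragment.ndim != 1:
            raise ValueError("site_to_fragment must be a 1-D index array")
        bad = (self.site_to_fragment < 0) | (self.site_to_fragment >= len(self.names))
        if bad.any():
            raise ValueError("site_to_fragment contains indices outside the name list")
        present = set(self.site_to_fragment.tolist())
        missing = [n for i, n in enumerate(self.names) if i not in present]
        if missing:
            raise ValueError(f"fragments with zero sites: {missing}")

    @property
    def n_fragments(self) -> int:
        return len(self.names)

    def sites_of(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.site_to_fragment == self.names.index(name))

    def membership_matrix(self) -> np.ndarray:
        """(n_fragments, n_sites) 0/1 aggregation matrix."""
        m = np.zeros((len(self.names), self.site_to_fragment.size))
        m[self.site_to_fragment, np.arange(self.site_to_fragment.size)] = 1.0
        return m


@dataclass
class EmbeddingCharges:
    """Fixed external point charges (electrostatic embedding).

    positions in angstrom, charges in units of e.
    """

    positions: np.ndarray
    charges: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        if self.positions.size == 0:
            self.positions = self.positions.reshape(0, 3)
        if self.positions.shape != (self.charges.size, 3):
            raise ValueError(
                f"positions shape {self.positions.shape} inconsistent with "
                f"{self.charges.size} charges"
            )
        if not (np.isfinite(self.positions).all() and np.isfinite(self.charges).all()):
            raise ValueError("embedding positions and charges must be finite")

    def __len__(self) -> int:
        return self.charges.size


@dataclass
class ModelSystem:
    """Site-basis model Hamiltonian with fragments and dipole operators."""

    site_positions: np.ndarray       # (n, 3) angstrom
    site_energies: np.ndarray        # (n,) hartree
    coupling: np.ndarray             # (n, n) hartree, Hermitian, zero diagonal
    interaction_strengths: np.ndarray  # (n,) hartree, U_mu >= 0
    dipole_operators: np.ndarray     # (3, n, n) e*bohr, each Hermitian
    fragments: FragmentScheme
    n_electrons: int
    overlap: np.ndarray | None = None            # (n, n) SPD, default identity
    site_nuclear_charges: np.ndarray | None = None  # (n,) e, default neutral
    embedding: EmbeddingCharges | None = None

    def __post_init__(self) -> None:
        self.site_positions = np.atleast_2d(np.asarray(self.site_positions, dtype=float))
        n = self.site_positions.shape[0]
        if self.site_positions.shape != (n, 3):
            raise ValueError("site_positions must have shape (n, 3)")
        self.site_energies = np.asarray(self.site_energies, dtype=float)
        self.coupling = np.asarray(self.coupling, dtype=float)
        self.interaction_strengths = np.asarray(self.interaction_strengths, dtype=float)
        self.dipole_operators = np.asarray(self.dipole_operators, dtype=float)
        if self.overlap is None:
            self.overlap = np.eye(n)
        else:
            self.overlap = np.asarray(self.overlap, dtype=float)
        if self.site_nuclear_charges is None:
            # neutral by default: total nuclear charge balances the electrons
            self.site_nuclear_charges = np.full(n, self.n_electrons / n)
        else:
            self.site_nuclear_charges = np.asarray(self.site_nuclear_charges, dtype=float)

        for name, arr, shape in [
            ("site_energies", self.site_energies, (n,)),
            ("coupling", self.coupling, (n, n)),
            ("interaction_strengths", self.interaction_strengths, (n,)),
            ("dipole_operators", self.dipole_operators, (3, n, n)),
            ("overlap", self.overlap, (n, n)),
            ("site_nuclear_charges", self.site_nuclear_charges, (n, )),
        ]:
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")

        if np.max(np.abs(self.coupling - self.coupling.T)) > 1e-12:
            raise ValueError("coupling matrix must be Hermitian (symmetric) within 1e-12")
        if np.max(np.abs(np.diag(self.coupling))) > 0:
            raise ValueError("coupling matrix must have zero diagonal")
        for i, d in enumerate(self.dipole_operators):
            if np.max(np.abs(d - d.T)) > 1e-12:
                raise ValueError(f"dipole operator {'xyz'[i]} must be Hermitian within 1e-12")
        if (self.interaction_strengths < 0).any():
            raise ValueError("interaction strengths U_mu must be non-negative")
        if np.linalg.eigvalsh(self.overlap).min() <= 0:
            raise ValueError("overlap matrix must be positive definite")
        if self.n_electrons % 2 != 0:
            raise ValueError(f"n_electrons must be even (closed shell), got {self.n_electrons}")
        if not (0 < self.n_electrons <= 2 * n):
            raise ValueError(f"n_electrons must lie in (0, {2 * n}]")
        if self.fragments.site_to_fragment.size != n:
            raise ValueError("fragment scheme does not cover every site exactly once")
        if self.embedding is not None:
            self._check_embedding(self.embedding)

        self._overlap_factors = spd_sqrt(self.overlap)

    # -- derived quantities -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.site_positions.shape[0]

    @property
    def overlap_factors(self):
        return self._overlap_factors

    def _check_embedding(self, embedding: EmbeddingCharges) -> None:
        if len(embedding) == 0:
            return
        d = np.linalg.norm(
            self.site_positions[:, None, :] - embedding.positions[None, :, :], axis=-1
        )
        if d.min() <= MIN_EMBEDDING_DISTANCE:
            mu, c = np.unravel_index(np.argmin(d), d.shape)
            raise ValueError(
                f"embedding charge {c} lies {d[mu, c]:.2e} A from site {mu}; "
                f"minimum allowed separation is {MIN_EMBEDDING_DISTANCE:g} A"
            )

    def embedding_site_potential(self) -> np.ndarray:
        """Diagonal one-electron potential of the embedding charges (hartree).

        v_mu = -sum_c q_c / |r_mu - R_c| in atomic units: the electron
        (charge -e) is attracted by positive external charges.
        """
        n = self.n_sites
        if self.embedding is None or len(self.embedding) == 0:
            return np.zeros(n)
        r = self.site_positions * BOHR_PER_ANGSTROM
        rc = self.embedding.positions * BOHR_PER_ANGSTROM
        dist = np.linalg.norm(r[:, None, :] - rc[None, :, :], axis=-1)
        return -(self.embedding.charges[None, :] / dist).sum(axis=1)

    def embedding_nuclear_energy(self) -> float:
        """Constant interaction of site nuclear charges with the embedding (hartree)."""
        if self.embedding is None or len(self.embedding) == 0:
            return 0.0
        r = self.site_positions * BOHR_PER_ANGSTROM
        rc = self.embedding.positions * BOHR_PER_ANGSTROM
        dist = np.linalg.norm(r[:, None, :] - rc[None, :, :], axis=-1)
        return float(
            (self.site_nuclear_charges[:, None] * self.embedding.charges[None, :] / dist).sum()
        )

    def core_hamiltonian(self) -> np.ndarray:
        """H0 = site energies + couplings + embedding potential (AO basis, hartree)."""
        return np.diag(self.site_energies + self.embedding_site_potential()) + self.coupling

    def nuclear_dipole(self) -> np.ndarray:
        """sum_A Z_A r_A in e*bohr (origin = coordinate origin)."""
        return (self.site_nuclear_charges[:, None] * self.site_positions * BOHR_PER_ANGSTROM).sum(
            axis=0
        )

    def total_charge(self) -> float:
        return float(self.site_nuclear_charges.sum() - self.n_electrons)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "site_positions": self.site_positions.tolist(),
            "site_energies": self.site_energies.tolist(),
            "coupling": self.coupling.tolist(),
            "interaction_strengths": self.interaction_strengths.tolist(),
            "dipole_operators": self.dipole_operators.tolist(),
            "overlap": self.overlap.tolist(),
            "site_nuclear_charges": self.site_nuclear_charges.tolist(),
            "fragments": {
                "names": self.fragments.names,
                "site_to_fragment": self.fragments.site_to_fragment.tolist(),
            },
            "n_electrons": int(self.n_electrons),
        }
        if self.embedding is not None and len(self.embedding) > 0:
            d["embedding"] = {
                "positions": self.embedding.positions.tolist(),
                "charges": self.embedding.charges.tolist(),
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSystem":
        emb = d.get("embedding")
        return cls(
            site_positions=np.array(d["site_positions"], dtype=float),
            site_energies=np.array(d["site_energies"], dtype=float),
            coupling=np.array(d["coupling"], dtype=float),
            interaction_strengths=np.array(d["interaction_strengths"], dtype=float),
            dipole_operators=np.array(d["dipole_operators"], dtype=float),
            fragments=FragmentScheme(
                d["fragments"]["names"], np.array(d["fragments"]["site_to_fragment"], dtype=int)
            ),
            n_electrons=int(d["n_electrons"]),
            overlap=np.array(d["overlap"], dtype=float),
            site_nuclear_charges=np.array(d["site_nuclear_charges"], dtype=float),
            embedding=EmbeddingCharges(emb["positions"], emb["charges"]) if emb else None,
        )

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path_or_text) -> "ModelSystem":
        text = str(path_or_text)
        if not text.lstrip().startswith("{"):
            with open(path_or_text) as fh:
                text = fh.read()
        return cls.from_dict(json.loads(text))

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    def to_xyz(self, path=None, elements=None) -> str:
        """XYZ geometry; the element column carries the fragment label by default."""
        if elements is None:
            elements = [self.fragments.names[i] for i in self.fragments.site_to_fragment]
        lines = [str(self.n_sites), "chargeflow model geometry (angstrom)"]
        for el, (x, y, z) in zip(elements, self.site_positions):
            lines.append(f"{el} {x:18.10f} {y:18.10f} {z:18.10f}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# builders


def _diagonal_dipoles(positions_angstrom: np.ndarray) -> np.ndarray:
    """Point-charge-like dipole operators: d^i = diag(r_mu,i) in e*bohr."""
    r_bohr = positions_angstrom * BOHR_PER_ANGSTROM
    n = r_bohr.shape[0]
    d = np.zeros((3, n, n))
    for i in range(3):
        d[i] = np.diag(r_bohr[:, i])
    return d


def build_chain_model(
    n_sites: int,
    site_energies,
    couplings,
    spacing: float,
    interaction_strengths,
    fragment_boundaries,
    n_electrons: int,
    fragment_names=None,
    site_nuclear_charges=None,
) -> ModelSystem:
    """Linear chain of sites along x, partitioned into contiguous fragments.

    Parameters
    ----------
    couplings : scalar or length n_sites-1 sequence
        Nearest-neighbour couplings (hartree).
    spacing : float
        Inter-site distance (angstrom), > 0.
    fragment_boundaries : sequence of int
        Split points; ``(3, 4)`` on 7 sites yields fragments 0-2 | 3 | 4-6.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    site_energies = np.asarray(site_energies, dtype=float)
    if site_energies.shape != (n_sites,):
        raise ValueError(f"expected {n_sites} site energies, got {site_energies.shape}")
    t = np.asarray(couplings, dtype=float)
    if t.ndim == 0:
        t = np.full(n_sites - 1, float(t))
    if t.shape != (n_sites - 1,):
        raise ValueError(f"expected {n_sites - 1} nearest-neighbour couplings, got {t.shape}")
    U = np.asarray(interaction_strengths, dtype=float)
    if U.ndim == 0:
        U = np.full(n_sites, float(U))

    positions = np.zeros((n_sites, 3))
    positions[:, 0] = np.arange(n_sites) * spacing

    H_offdiag = np.zeros((n_sites, n_sites))
    idx = np.arange(n_sites - 1)
    H_offdiag[idx, idx + 1] = t
    H_offdiag[idx + 1, idx] = t

    bounds = [0, *sorted(int(b) for b in fragment_boundaries), n_sites]
    if len(set(bounds)) != len(bounds) or any(b < 0 or b > n_sites for b in bounds):
        raise ValueError(f"invalid fragment boundaries {fragment_boundaries}")
    n_frag = len(bounds) - 1
    if fragment_names is None:
        fragment_names = (
            ["donor", "bridge", "acceptor"] if n_frag == 3 else [f"F{i + 1}" for i in range(n_frag)]
        )
    site_to_fragment = np.zeros(n_sites, dtype=int)
    for k in range(n_frag):
        site_to_fragment[bounds[k]: bounds[k + 1]] = k

    return ModelSystem(
        site_positions=positions,
        site_energies=site_energies,
        coupling=H_offdiag,
        interaction_strengths=U,
        dipole_operators=_diagonal_dipoles(positions),
        fragments=FragmentScheme(list(fragment_names), site_to_fragment),
        n_electrons=n_electrons,
        site_nuclear_charges=site_nuclear_charges,
    )


def build_star_model(
    hub_energy: float,
    arm_energies,
    hub_arm_couplings,
    arm_length: int,
    geometry_radius: float,
    interaction_strengths,
    n_electrons: int,
    intra_arm_coupling=None,
    arm_names=None,
) -> ModelSystem:
    """Hub-and-arms model: one central site with >= 4 radial arms.

    Arms are placed at distinct polar angles in the xy-plane so that dipole
    projections onto arm directions are distinguishable; each arm is one
    fragment, the hub another. ``arm_energies[k]`` applies to every site of
    arm ``k``; ``hub_arm_couplings[k]`` couples the hub to the first site of
    arm ``k`` and, unless overridden, consecutive sites within the arm.
    """
    arm_energies = np.atleast_1d(np.asarray(arm_energies, dtype=float))
    n_arms = arm_energies.size
    if n_arms < 4:
        raise ValueError(f"star model requires >= 4 arms, got {n_arms}")
    if arm_length < 1:
        raise ValueError("arm_length must be >= 1")
    if geometry_radius <= 0:
        raise ValueError("geometry_radius must be positive")
    tk = np.asarray(hub_arm_couplings, dtype=float)
    if tk.ndim == 0:
        tk = np.full(n_arms, float(tk))
    if tk.shape != (n_arms,):
        raise ValueError(f"expected {n_arms} hub-arm couplings, got {tk.shape}")

    n_sites = 1 + n_arms * arm_length
    positions = np.zeros((n_sites, 3))
    energies = np.empty(n_sites)
    energies[0] = hub_energy
    site_to_fragment = np.zeros(n_sites, dtype=int)
    coupling = np.zeros((n_sites, n_sites))

    angles = 2.0 * np.pi * np.arange(n_arms) / n_arms
    for k in range(n_arms):
        direction = np.array([np.cos(angles[k]), np.sin(angles[k]), 0.0])
        t_arm = tk[k] if intra_arm_coupling is None else float(intra_arm_coupling)
        prev = 0
        for j in range(arm_length):
            s = 1 + k * arm_length + j
            positions[s] = (j + 1) * geometry_radius * direction
            energies[s] = arm_energies[k]
            site_to_fragment[s] = k + 1
            t = tk[k] if j == 0 else t_arm
            coupling[prev, s] = coupling[s, prev] = t
            prev = s

    # degenerate geometry guard
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    d[np.diag_indices(n_sites)] = np.inf
    if d.min() < 1e-9:
        raise ValueError("degenerate geometry: two sites coincide")

    U = np.asarray(interaction_strengths, dtype=float)
    if U.ndim == 0:
        U = np.full(n_sites, float(U))
    if arm_names is None:
        arm_names = [f"arm{k + 1}" for k in range(n_arms)]
    names = ["hub", *arm_names]

    return ModelSystem(
        site_positions=positions,
        site_energies=energies,
        coupling=coupling,
        interaction_strengths=U,
        dipole_operators=_diagonal_dipoles(positions),
        fragments=FragmentScheme(names, site_to_fragment),
        n_electrons=n_electrons,
    )


def add_point_charge_embedding(model: ModelSystem, embedding: EmbeddingCharges) -> ModelSystem:
    """Return a copy of ``model`` with electrostatic embedding charges attached.

    The one-electron Hamiltonian of the returned model gains the diagonal
    potential ``v_mu = -sum_c q_c / |r_mu - R_c|`` (atomic units) and the
    total energy gains the constant nuclear-charge interaction term. An
    empty charge list returns a model with an identical Hamiltonian.
    """
    d = model.to_dict()
    base = ModelSystem.from_dict(d)
    base.embedding = embedding if len(embedding) else None
    if base.embedding is not None:
        base._check_embedding(base.embedding)
    return base


def mean_field_fock(model: ModelSystem, P: DensityMatrix) -> FockMatrix:
    """Mean-field Fock operator F(P) = H0 + diag(U_mu (P S)_mu_mu).

    The on-site Hubbard-like term couples each site energy to its own
    Mulliken population, making the dynamics density-dependent; with all
    U_mu = 0 the operator is H0 regardless of P (linear dynamics). The
    returned matrix is expressed in the same basis as ``P``.
    """
    if P.n != model.n_sites:
        raise ValueError(f"density dimension {P.n} does not match model ({model.n_sites} sites)")
    f = model.overlap_factors
    if P.basis == "atomic":
        populations = np.einsum("ij,ji->i", P.values, model.overlap).real
    else:
        # (P_AO S)_mumu = (S^{-1/2} P' S^{1/2})_mumu
        populations = np.einsum("ij,jk,ki->i", f.inv_sqrt, P.values, f.sqrt).real
    F_AO = model.core_hamiltonian() + np.diag(model.interaction_strengths * populations)
    if P.basis == "atomic":
        return FockMatrix(F_AO, "atomic")
    return FockMatrix(f.inv_sqrt @ F_AO @ f.inv_sqrt, "orthonormal")


def total_energy(model: ModelSystem, P: DensityMatrix) -> float:
    """Mean-field total energy (hartree).

    E = Tr(P H0) + 1/2 sum_mu U_mu (P S)_mu_mu^2 + E_embed(nuclear), where
    the factor 1/2 avoids double counting of the mean-field interaction.
    Invariant under the Lowdin round trip.
    """
    if P.basis == "orthonormal":
        P_AO = lowdin_inverse(P, model.overlap).values
    else:
        P_AO = P.values
    populations = np.einsum("ij,ji->i", P_AO, model.overlap).real
    e_one = np.einsum("ij,ji->", P_AO, model.core_hamiltonian()).real
    e_mf = 0.5 * float(np.sum(model.interaction_strengths * populations**2))
    return float(e_one + e_mf + model.embedding_nuclear_energy())
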