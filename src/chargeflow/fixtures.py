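"""Synthetic study systems.

Two fixtures define the package's reference scenarios:

* ``chain_dba`` — a donor-bridge-acceptor chain (three fragments). The
  donor block lies lowest, the acceptor slightly above it, the single
  bridge site well above both, so the HOMO is donor-localized and the LUMO
  acceptor-localized; a HOMO -> LUMO Koopman excitation launches charge
  transfer across the bridge. Donor-bridge and bridge-acceptor couplings
  differ, so the two charge-exchange channels beat at distinct frequencies.

* ``star_hub4`` — a low-lying hub with four radial arms (five fragments),
  the minimal stand-in for a metal center with ligand arms. Two arms are
  near-degenerate acceptors split by 0.01 hartree — a deliberate slight
  symmetry breaking — so a hub -> arm excitation lands mainly on one arm
  and then migrates to its partner (the interligand-transfer scenario).

Optional embedding modes: ``point_charges`` surrounds the system with
fixed external charges (electrostatic embedding); ``explicit_shell`` adds
weakly coupled high-lying quantum sites beyond the termini, a coarse
explicit environment shell. Fixture generation is deterministic given
(spec, seed); the seed only jitters embedding-charge placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .model import (
    EmbeddingCharges,
    FragmentScheme,
    ModelSystem,
    add_point_charge_embedding,
    build_chain_model,
    build_star_model,
)

__all__ = ["FixtureSpec", "generate_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("chain_dba", "star_hub4")
EMBEDDING_MODES = ("none", "point_charges", "explicit_shell")


@dataclass
class FixtureSpec:
    name: str
    embedding: str = "none"
    block_sizes: tuple = (3, 1, 3)   # chain_dba: donor/bridge/acceptor site counts
    arm_length: int = 2              # star_hub4

    def __post_init__(self) -> None:
        if self.name not in FIXTURE_NAMES:
            raise ValueError(f"unknown fixture {self.name!r}; expected one of {FIXTURE_NAMES}")
        if self.embedding not in EMBEDDING_MODES:
            raise ValueError(
                f"unknown embedding mode {self.embedding!r}; expected one of {EMBEDDING_MODES}"
            )


def _chain_model(spec: FixtureSpec) -> ModelSystem:
    nd, nb, na = spec.block_sizes
    n = nd + nb + na
    # donor block lowest, acceptor slightly above, bridge level in the virtual
    # manifold just above the frontier: the photo-target orbital is
    # bridge-centered, so both carriers exchange charge with the bridge
    energies = np.concatenate([np.zeros(nd), np.full(nb, 0.10), np.full(na, 0.03)])
    # asymmetric bond pattern: the donor-bridge and bridge-acceptor channels
    # beat at distinct frequencies, desynchronizing the two carriers
    t = np.full(n - 1, -0.08)
    t[nd - 1] = -0.05          # donor - bridge
    t[nd + nb - 1] = -0.04     # bridge - acceptor
    # softer charging energy on the small bridge moiety
    U = np.concatenate([np.full(nd, 0.10), np.full(nb, 0.02), np.full(na, 0.10)])
    return build_chain_model(
        n_sites=n,
        site_energies=energies,
        couplings=t,
        spacing=2.5,
        interaction_strengths=U,
        fragment_boundaries=(nd, nd + nb),
        n_electrons=6,
    )


def _star_model(spec: FixtureSpec) -> ModelSystem:
    return build_star_model(
        hub_energy=-0.30,
        # two near-degenerate acceptor arms (split 0.01) + two high-lying arms
        arm_energies=[0.05, 0.06, 0.20, 0.20],
        hub_arm_couplings=[-0.06, -0.06, -0.05, -0.05],
        arm_length=spec.arm_length,
        geometry_radius=2.0,
        interaction_strengths=0.10,
        n_electrons=2,
    )


def _point_charges(model: ModelSystem, rng: np.random.Generator) -> EmbeddingCharges:
    """A ring of alternating +-0.4 e charges 4 A outside the model, xy-plane."""
    center = model.site_positions.mean(axis=0)
    extent = np.linalg.norm(model.site_positions - center, axis=1).max()
    radius = extent + 4.0
    n_c = 6
    angles = 2 * np.pi * np.arange(n_c) / n_c + np.pi / n_c
    pos = center + radius * np.column_stack(
        [np.cos(angles), np.sin(angles), np.zeros(n_c)]
    )
    pos += rng.normal(scale=0.01, size=pos.shape)
    charges = 0.4 * (-1.0) ** np.arange(n_c)
    return EmbeddingCharges(pos, charges)


def _with_shell(model: ModelSystem, shell_energy=0.50, shell_coupling=-0.02) -> ModelSystem:
    """Append a weakly coupled quantum site beyond each terminal site."""
    degree = (np.abs(model.coupling) > 0).sum(axis=0)
    termini = np.flatnonzero(degree <= 1)
    center = model.site_positions.mean(axis=0)
    n_old = model.n_sites
    n_new = n_old + termini.size

    positions = np.vstack([model.site_positions] + [
        model.site_positions[t]
        + 2.0 * _safe_unit(model.site_positions[t] - center)
        for t in termini
    ])
    energies = np.concatenate([model.site_energies, np.full(termini.size, shell_energy)])
    coupling = np.zeros((n_new, n_new))
    coupling[:n_old, :n_old] = model.coupling
    for j, t in enumerate(termini):
        s = n_old + j
        coupling[t, s] = coupling[s, t] = shell_coupling
    U = np.concatenate([model.interaction_strengths, np.full(termini.size, 0.0)])
    Z = np.concatenate([model.site_nuclear_charges, np.zeros(termini.size)])
    from .model import _diagonal_dipoles

    names = [*model.fragments.names, "shell"]
    s2f = np.concatenate(
        [model.fragments.site_to_fragment, np.full(termini.size, len(names) - 1, dtype=int)]
    )
    return ModelSystem(
        site_positions=positions,
        site_energies=energies,
        coupling=coupling,
        interaction_strengths=U,
        dipole_operators=_diagonal_dipoles(positions),
        fragments=FragmentScheme(names, s2f),
        n_electrons=model.n_electrons,
        site_nuclear_charges=Z,
    )


def _safe_unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])


def generate_fixture(spec: FixtureSpec | str, seed: int = 0) -> tuple[ModelSystem, RunConfig]:
    """Build a study fixture and its default run configuration.

    Defaults mirror the reference study conditions: 25 fs of dynamics at a
    1 as time step, HOMO -> LUMO swap excitation.
    """
    if isinstance(spec, str):
        spec = FixtureSpec(spec)
    rng = np.random.default_rng(seed)
    model = _chain_model(spec) if spec.name == "chain_dba" else _star_model(spec)
    if spec.embedding == "point_charges":
        model = add_point_charge_embedding(model, _point_charges(model, rng))
    elif spec.embedding == "explicit_shell":
        model = _with_shell(model)
    # chain_dba targets the bridge-centered virtual orbital (LUMO+1), the
    # star the lowest arm-localized one
    target = "LUMO+1" if spec.name == "chain_dba" else "LUMO"
    config = RunConfig(
        model=model.to_dict(),
        fixture=spec.name,
        embedding=spec.embedding,
        excitation={"from": "HOMO", "to": target, "mode": "swap"},
        dt=1.0,
        dt_unit="as",
        duration=25.0,
        duration_unit="fs",
        seed=seed,
    )
    return model, config
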