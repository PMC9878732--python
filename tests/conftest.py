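"""Shared fixtures: small models and precomputed runs.

The "full" chain run reproduces the reference study conditions (25 fs of
dynamics at a 1 as step) and is session-scoped since several conservation
and end-to-end checks share it.
"""

from __future__ import annotations

import numpy as np
import pytest

import chargeflow as cf


@pytest.fixture()
def symmetric_dimer() -> cf.ModelSystem:
    """Two equivalent sites, coupling -0.1 hartree, 2 electrons."""
    return cf.build_chain_model(
        n_sites=2,
        site_energies=[0.0, 0.0],
        couplings=-0.1,
        spacing=2.0,
        interaction_strengths=0.0,
        fragment_boundaries=(1,),
        n_electrons=2,
    )


@pytest.fixture()
def detuned_dimer() -> cf.ModelSystem:
    """Two-level system with detuning 0.05 and coupling -0.04 hartree (linear)."""
    return cf.build_chain_model(
        n_sites=2,
        site_energies=[0.0, 0.05],
        couplings=-0.04,
        spacing=2.0,
        interaction_strengths=0.0,
        fragment_boundaries=(1,),
        n_electrons=2,
    )


@pytest.fixture()
def chain3() -> cf.ModelSystem:
    """Three-site ladder (0, 0.2, 0.4 hartree; nearest-neighbour -0.05), linear."""
    return cf.build_chain_model(
        n_sites=3,
        site_energies=[0.0, 0.2, 0.4],
        couplings=-0.05,
        spacing=1.5,
        interaction_strengths=0.0,
        fragment_boundaries=(1, 2),
        n_electrons=2,
    )


@pytest.fixture()
def chain3_hubbard() -> cf.ModelSystem:
    """Three-site chain with on-site interaction (nonlinear dynamics)."""
    return cf.build_chain_model(
        n_sites=3,
        site_energies=[0.0, 0.08, 0.02],
        couplings=-0.05,
        spacing=1.5,
        interaction_strengths=0.08,
        fragment_boundaries=(1, 2),
        n_electrons=2,
    )


@pytest.fixture(scope="session")
def chain_model() -> cf.ModelSystem:
    model, _ = cf.generate_fixture("chain_dba")
    return model


@pytest.fixture(scope="session")
def star_model() -> cf.ModelSystem:
    model, _ = cf.generate_fixture("star_hub4")
    return model


def _run_chain(model: cf.ModelSystem, dt_as: float, n_steps: int):
    P0, orbitals = cf.ground_state(model)
    # bridge-centered virtual orbital is the photo-target (LUMO+1)
    P_exc = cf.koopman_excitation(
        P0, orbitals, orbitals.homo_index, orbitals.index_of("LUMO+1"), "swap"
    )
    traj = cf.propagate(
        model, P_exc, dt_as, n_steps, dt_unit="as",
        excitation_record=(orbitals.homo_index, orbitals.index_of("LUMO+1"), "swap"),
    )
    return traj, orbitals


@pytest.fixture(scope="session")
def chain_run_full(chain_model):
    """Reference-condition run: 25 fs at 1 as on the donor-bridge-acceptor chain."""
    traj, orbitals = _run_chain(chain_model, 1.0, 25000)
    return chain_model, traj, orbitals


@pytest.fixture(scope="session")
def chain_run_short(chain_model):
    """Cheap 2.5 fs run for smoke-level observable checks."""
    traj, orbitals = _run_chain(chain_model, 2.0, 1250)
    return chain_model, traj, orbitals


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
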