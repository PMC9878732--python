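"""Trajectory container I/O.

A trajectory is exchanged as a single HDF5 file with datasets

    /times       (T,)        fs
    /densities   (T, n, n)   complex, orthonormal basis
    /energies    (T,)        hartree
    /overlap     (n, n)      AO overlap
    /C0          (n, n)      reference MO coefficients (AO basis, columns)
    /positions   (n, 3)      angstrom
    /fragments   (n,)        fragment index per site

and a root-level ``meta`` attribute holding a JSON block (dt, units,
excitation record, orbital energies, fragment names, code version and —
when the trajectory was produced in-package — the full model document, so
that analysis can be re-run from the file alone). Externally produced
trajectories need only supply the datasets; a minimal model is then
reconstructed from them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

from . import __version__
from .model import FragmentScheme, ModelSystem
from .propagation import ElectronicTrajectory, ReferenceOrbitals

__all__ = ["TrajectoryBundle", "write_trajectory", "read_trajectory"]

SCHEMA_VERSION = 1
REQUIRED_DATASETS = (
    "/times",
    "/densities",
    "/energies",
    "/overlap",
    "/C0",
    "/positions",
    "/fragments",
)


@dataclass
class TrajectoryBundle:
    """A trajectory together with the context needed to analyze it."""

    trajectory: ElectronicTrajectory
    model: ModelSystem
    orbitals: ReferenceOrbitals


def write_trajectory(
    path,
    trajectory: ElectronicTrajectory,
    model: ModelSystem,
    orbitals: ReferenceOrbitals,
) -> None:
    meta = {
        "schema_version": SCHEMA_VERSION,
        "code_version": __version__,
        "dt_fs": trajectory.dt_fs,
        "units": {"time": "fs", "energy": "hartree", "length": "angstrom"},
        "excitation_record": list(trajectory.excitation_record)
        if trajectory.excitation_record
        else None,
        "model_digest": trajectory.model_digest,
        "orbital_energies": orbitals.energies.tolist(),
        "homo_index": int(orbitals.homo_index),
        "n_electrons": int(model.n_electrons),
        "fragment_names": list(model.fragments.names),
        "model": model.to_dict(),
    }
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=trajectory.times_fs)
        fh.create_dataset("densities", data=trajectory.densities)
        fh.create_dataset("energies", data=trajectory.energies)
        fh.create_dataset("overlap", data=model.overlap)
        fh.create_dataset("C0", data=orbitals.coefficients)
        fh.create_dataset("positions", data=model.site_positions)
        fh.create_dataset("fragments", data=model.fragments.site_to_fragment)
        fh.attrs["meta"] = json.dumps(meta)


def _minimal_model(meta: dict, overlap, positions, fragments) -> ModelSystem:
    """Reconstruct a bookkeeping model from bare datasets (external producer)."""
    n = positions.shape[0]
    names = meta.get("fragment_names") or [f"F{i + 1}" for i in range(int(fragments.max()) + 1)]
    n_el = int(meta.get("n_electrons", 2))
    d = np.zeros((3, n, n))
    from .constants import BOHR_PER_ANGSTROM

    for i in range(3):
        d[i] = np.diag(positions[:, i] * BOHR_PER_ANGSTROM)
    return ModelSystem(
        site_positions=positions,
        site_energies=np.zeros(n),
        coupling=np.zeros((n, n)),
        interaction_strengths=np.zeros(n),
        dipole_operators=d,
        fragments=FragmentScheme(names, fragments),
        n_electrons=n_el,
        overlap=overlap,
    )


def read_trajectory(path) -> TrajectoryBundle:
    """Read a trajectory container; raises naming the first missing dataset."""
    with h5py.File(path, "r") as fh:
        for name in REQUIRED_DATASETS:
            if name.lstrip("/") not in fh:
                raise ValueError(f"trajectory file {path} is missing dataset {name}")
        times = fh["times"][...]
        densities = fh["densities"][...]
        energies = fh["energies"][...]
        overlap = fh["overlap"][...]
        C0 = fh["C0"][...]
        positions = fh["positions"][...]
        fragments = fh["fragments"][...].astype(int)
        meta = json.loads(fh.attrs.get("meta", "{}"))

    if times.size >= 2:
        steps = np.diff(times)
        if steps.min() <= 0 or np.ptp(steps) > 1e-12:
            raise ValueError("trajectory time grid is not uniform and increasing")
        dt_fs = float(steps[0])
    else:
        dt_fs = float(meta.get("dt_fs", 1.0))

    exc = meta.get("excitation_record")
    trajectory = ElectronicTrajectory(
        dt_fs=dt_fs,
        times_fs=times,
        densities=densities,
        energies=energies,
        model_digest=meta.get("model_digest", ""),
        excitation_record=tuple(exc) if exc else None,
    )

    if "model" in meta:
        model = ModelSystem.from_dict(meta["model"])
    else:
        model = _minimal_model(meta, overlap, positions, fragments)

    energies_mo = np.asarray(
        meta.get("orbital_energies", np.zeros(C0.shape[1])), dtype=float
    )
    homo = int(meta.get("homo_index", model.n_electrons // 2 - 1))
    orbitals = ReferenceOrbitals(
        coefficients=C0,
        energies=energies_mo,
        homo_index=homo,
        ortho_coefficients=model.overlap_factors.sqrt @ C0,
    )
    return TrajectoryBundle(trajectory=trajectory, model=model, orbitals=orbitals)
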