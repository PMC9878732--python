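"""Time-dependent observables extracted from an electronic trajectory.

All extractors are pure functions of the trajectory (and model): MO
occupations by projection onto the t = 0 orbitals, the electric dipole and
its projections onto an internal frame, Mulliken fragment charges, and the
kinetics of the charge-depletion (hole) and charge-accumulation (electron)
barycenters.

Sign conventions, stated once:

* electrons contribute negatively to the dipole, mu_el = -Tr(P d); the
  nuclear term sum_A Z_A r_A is included by default so a neutral symmetric
  system has mu = 0;
* a positive fragment charge deviation dq_F > 0 means electron depletion
  (hole-like), matching the chemical charge convention;
* the hole barycenter averages sites with dq > 0, the electron barycenter
  sites with dq < 0, each weighted by |dq|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import BOHR_PER_ANGSTROM, DEBYE_PER_E_BOHR
from .model import ModelSystem
from .propagation import ElectronicTrajectory, ReferenceOrbitals

__all__ = [
    "OccupationSeries",
    "DipoleSeries",
    "TimeSeriesSet",
    "BarycenterSeries",
    "CarrierMetrics",
    "mo_occupations",
    "dipole_series",
    "project_dipole",
    "fragment_charges",
    "charge_barycenters",
    "rms_metrics",
]


@dataclass
class TimeSeriesSet:
    """Named scalar time series on a shared uniform grid."""

    names: list
    values: np.ndarray        # (T, n_series)
    dt_fs: float
    kind: str = "generic"     # fragment_charge | dipole_projection | occupation | generic
    times_fs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.names = list(self.names)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.names):
            raise ValueError(
                f"{len(self.names)} names but values have {self.values.shape[1]} columns"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("time series contain non-finite values")
        if self.times_fs is None:
            self.times_fs = np.arange(self.values.shape[0]) * self.dt_fs
        else:
            self.times_fs = np.asarray(self.times_fs, dtype=float)
        if self.times_fs.size != self.values.shape[0]:
            raise ValueError("times and values lengths differ")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def series(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "time_fs", self.times_fs)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "generic") -> "TimeSeriesSet":
        df = pd.read_csv(path)
        if "time_fs" not in df.columns:
            raise ValueError(f"{path}: expected a 'time_fs' column")
        t = df.pop("time_fs").to_numpy()
        dt = float(t[1] - t[0]) if t.size > 1 else 1.0
        return cls(list(df.columns), df.to_numpy(), dt_fs=dt, kind=kind, times_fs=t)


@dataclass
class OccupationSeries:
    """Ground-state MO occupations n_i(t) over a frontier window."""

    orbital_labels: list
    orbital_indices: np.ndarray
    values: np.ndarray        # (T, n_orbitals), electrons in [0, 2]
    dt_fs: float
    times_fs: np.ndarray

    def series(self, label: str) -> np.ndarray:
        return self.values[:, self.orbital_labels.index(label)]

    def to_time_series(self) -> TimeSeriesSet:
        return TimeSeriesSet(
            self.orbital_labels, self.values, self.dt_fs, kind="occupation", times_fs=self.times_fs
        )

    def to_csv(self, path) -> None:
        self.to_time_series().to_csv(path)


@dataclass
class DipoleSeries:
    """Electric dipole mu(t) in e*bohr, with optional internal-frame projections."""

    values: np.ndarray        # (T, 3)
    dt_fs: float
    times_fs: np.ndarray
    frame: dict = field(default_factory=dict)   # name -> unit 3-vector

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("dipole values must have shape (T, 3)")

    def to_debye(self) -> np.ndarray:
        return self.values * DEBYE_PER_E_BOHR

    def to_time_series(self) -> TimeSeriesSet:
        return TimeSeriesSet(
            ["mu_x", "mu_y", "mu_z"], self.values, self.dt_fs,
            kind="dipole_projection", times_fs=self.times_fs,
        )

    def to_csv(self, path) -> None:
        self.to_time_series().to_csv(path)


@dataclass
class BarycenterSeries:
    """Hole and electron charge barycenters (angstrom) with validity masks."""

    r_hole: np.ndarray          # (T, 3), NaN on invalid frames
    r_electron: np.ndarray      # (T, 3)
    total_positive: np.ndarray  # (T,) summed hole-like weight (e)
    total_negative: np.ndarray  # (T,) summed electron-like weight (e)
    valid_hole: np.ndarray      # (T,) bool
    valid_electron: np.ndarray  # (T,) bool
    dt_fs: float
    times_fs: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.times_fs.size

    def to_xyz(self, path=None) -> str:
        """Barycenter tracks as pseudo-atoms Xh / Xe, one frame per block."""
        lines = []
        for k in range(self.n_frames):
            atoms = []
            if self.valid_hole[k]:
                atoms.append(("Xh", self.r_hole[k]))
            if self.valid_electron[k]:
                atoms.append(("Xe", self.r_electron[k]))
            lines.append(str(len(atoms)))
            lines.append(f"t = {self.times_fs[k]:.6f} fs")
            for el, r in atoms:
                lines.append(f"{el} {r[0]:18.10f} {r[1]:18.10f} {r[2]:18.10f}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class CarrierMetrics:
    """RMS hole-electron separation (angstrom) and RMS carrier speeds (angstrom/fs)."""

    d_he: float
    v_hole: float
    v_electron: float

    def __post_init__(self) -> None:
        if min(self.d_he, self.v_hole, self.v_electron) < 0:
            raise ValueError("carrier metrics must be non-negative")

    def to_dict(self) -> dict:
        return {
            "d_he_angstrom": self.d_he,
            "v_hole_angstrom_per_fs": self.v_hole,
            "v_electron_angstrom_per_fs": self.v_electron,
        }


# ---------------------------------------------------------------------------
# extractors


def mo_occupations(
    trajectory: ElectronicTrajectory,
    reference_orbitals: ReferenceOrbitals,
    window: tuple[int, int] | None = (20, 20),
) -> OccupationSeries:
    """Occupations of the t = 0 molecular orbitals along the trajectory.

    n_i(t) = [C~^dagger P'(t) C~]_ii with C~ the orthonormal-basis reference
    orbitals. ``window = (m, p)`` tracks HOMO-m ... LUMO+p, clipped to the
    available orbitals (default 20/20, the usual frontier window);
    ``window=None`` tracks every orbital.
    """
    C = reference_orbitals.ortho_coefficients
    n = C.shape[1]
    if trajectory.n_sites != C.shape[0]:
        raise ValueError("reference orbitals do not match the trajectory dimension")
    homo = reference_orbitals.homo_index
    if window is None:
        lo, hi = 0, n - 1
    else:
        m, p = window
        if m < 0 or p < 0:
            raise ValueError("window offsets must be non-negative")
        lo, hi = max(0, homo - m), min(n - 1, homo + 1 + p)
    idx = np.arange(lo, hi + 1)
    M = C[:, idx].astype(complex)
    tmp = trajectory.densities @ M               # (T, n, m)
    vals = np.einsum("tam,am->tm", tmp, M.conj()).real
    if vals.min() < -1e-8 or vals.max() > 2.0 + 1e-8:
        raise ValueError(
            f"occupations outside [0, 2]: range [{vals.min():.3e}, {vals.max():.3e}]"
        )
    labels = [reference_orbitals.label(i) for i in idx]
    return OccupationSeries(
        orbital_labels=labels,
        orbital_indices=idx,
        values=vals,
        dt_fs=trajectory.dt_fs,
        times_fs=trajectory.times_fs.copy(),
    )


def dipole_series(
    trajectory: ElectronicTrajectory,
    model: ModelSystem,
    include_nuclear: bool = True,
) -> DipoleSeries:
    """Electric dipole mu(t) = -Tr(P(t) d) [+ sum_A Z_A r_A] in e*bohr.

    The AO-basis trace is evaluated in the orthonormal basis as
    Tr(P' S^{-1/2} d S^{-1/2}). The origin is the coordinate origin; no
    implicit recentering.
    """
    f = model.overlap_factors
    vals = np.empty((trajectory.n_frames, 3))
    for i in range(3):
        d = model.dipole_operators[i]
        d_ortho = d if f.is_identity else f.inv_sqrt @ d @ f.inv_sqrt
        vals[:, i] = -np.einsum("tab,ba->t", trajectory.densities, d_ortho).real
    if include_nuclear:
        vals += model.nuclear_dipole()[None, :]
    return DipoleSeries(
        values=vals, dt_fs=trajectory.dt_fs, times_fs=trajectory.times_fs.copy()
    )


def project_dipole(dipole: DipoleSeries, named_directions: dict) -> TimeSeriesSet:
    """Project mu(t) onto named internal-frame directions (normalized internally)."""
    names, cols = [], []
    frame = {}
    for name, vec in named_directions.items():
        v = np.asarray(vec, dtype=float)
        norm = float(np.linalg.norm(v))
        if norm < 1e-12:
            raise ValueError(f"direction {name!r} has zero length")
        u = v / norm
        frame[name] = u
        names.append(name)
        cols.append(dipole.values @ u)
    dipole.frame.update(frame)
    return TimeSeriesSet(
        names, np.column_stack(cols), dipole.dt_fs,
        kind="dipole_projection", times_fs=dipole.times_fs.copy(),
    )


def _site_populations(trajectory: ElectronicTrajectory, model: ModelSystem) -> np.ndarray:
    """Mulliken site populations diag(P(t) S) for every frame, shape (T, n)."""
    f = model.overlap_factors
    if f.is_identity:
        return np.einsum("tii->ti", trajectory.densities).real.copy()
    # (P_AO S)_mumu = (S^{-1/2} P' S^{1/2})_mumu
    return np.einsum("mb,tbc,cm->tm", f.inv_sqrt, trajectory.densities, f.sqrt).real


def fragment_charges(
    trajectory: ElectronicTrajectory,
    model: ModelSystem,
    relative: bool = True,
    per_site: bool = False,
) -> TimeSeriesSet:
    """Mulliken fragment charges along the trajectory.

    Per-site charge q_mu(t) = Z_mu - (P(t) S)_mu_mu, summed over the sites
    of each fragment. By default the deviation from the initial frame,
    dq_F(t) = q_F(t) - q_F(0), is returned (``relative=False`` for absolute
    charges; ``per_site=True`` for the unsummed per-site series).
    """
    pops = _site_populations(trajectory, model)
    q_site = model.site_nuclear_charges[None, :] - pops
    if per_site:
        names = [f"site{m}" for m in range(model.n_sites)]
        vals = q_site
    else:
        agg = model.fragments.membership_matrix()
        names = list(model.fragments.names)
        vals = q_site @ agg.T
    if relative:
        vals = vals - vals[0]
    return TimeSeriesSet(
        names, vals, trajectory.dt_fs, kind="fragment_charge", times_fs=trajectory.times_fs.copy()
    )


def charge_barycenters(
    charges: TimeSeriesSet | np.ndarray,
    positions: np.ndarray,
    threshold: float = 1e-3,
    dt_fs: float | None = None,
) -> BarycenterSeries:
    """Hole and electron barycenters of a per-site charge-deviation pattern.

    r_hole(t) is the dq-weighted mean position over sites with dq > 0
    (electron depletion), r_electron(t) the |dq|-weighted mean over sites
    with dq < 0. Frames whose total weight on a side falls below
    ``threshold`` (default 1e-3 e) are marked invalid rather than
    interpolated.
    """
    if isinstance(charges, TimeSeriesSet):
        dq = charges.values
        dt_fs = charges.dt_fs
        times = charges.times_fs
    else:
        dq = np.atleast_2d(np.asarray(charges, dtype=float))
        if dt_fs is None:
            dt_fs = 1.0
        times = np.arange(dq.shape[0]) * dt_fs
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (dq.shape[1], 3):
        raise ValueError(
            f"positions shape {positions.shape} does not match {dq.shape[1]} charge series"
        )

    w_hole = np.clip(dq, 0.0, None)
    w_elec = np.clip(-dq, 0.0, None)
    tot_hole = w_hole.sum(axis=1)
    tot_elec = w_elec.sum(axis=1)
    valid_hole = tot_hole > threshold
    valid_elec = tot_elec > threshold
    if not (valid_hole.any() or valid_elec.any()):
        raise ValueError(
            f"no frame carries total charge deviation above the {threshold:g} e threshold"
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        r_hole = (w_hole @ positions) / tot_hole[:, None]
        r_elec = (w_elec @ positions) / tot_elec[:, None]
    r_hole[~valid_hole] = np.nan
    r_elec[~valid_elec] = np.nan

    return BarycenterSeries(
        r_hole=r_hole,
        r_electron=r_elec,
        total_positive=tot_hole,
        total_negative=tot_elec,
        valid_hole=valid_hole,
        valid_electron=valid_elec,
        dt_fs=float(dt_fs),
        times_fs=times.copy(),
    )


def _rms_speed(track: np.ndarray, valid: np.ndarray, dt_fs: float) -> float:
    """RMS |dr/dt| over contiguous valid runs, central differences inside."""
    speeds_sq = []
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return 0.0
    # split into contiguous runs
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        if run.size < 2:
            continue
        v = np.gradient(track[run], dt_fs, axis=0)
        speeds_sq.append(np.sum(v**2, axis=1))
    if not speeds_sq:
        return 0.0
    return float(np.sqrt(np.mean(np.concatenate(speeds_sq))))


def rms_metrics(barycenters: BarycenterSeries, dt_fs: float | None = None) -> CarrierMetrics:
    """Time-RMS hole-electron distance and RMS carrier speeds.

    d_he = sqrt(<|r_hole - r_electron|^2>) over frames where both
    barycenters are valid; speeds are RMS magnitudes of central-difference
    velocities along each track (one-sided at run edges), with invalid
    frames excluded. Requires at least 3 jointly valid frames.
    """
    if dt_fs is None:
        dt_fs = barycenters.dt_fs
    both = barycenters.valid_hole & barycenters.valid_electron
    if both.sum() < 3:
        raise ValueError(f"need >= 3 jointly valid frames, have {int(both.sum())}")
    sep = barycenters.r_hole[both] - barycenters.r_electron[both]
    d_he = float(np.sqrt(np.mean(np.sum(sep**2, axis=1))))
    v_h = _rms_speed(barycenters.r_hole, barycenters.valid_hole, dt_fs)
    v_e = _rms_speed(barycenters.r_electron, barycenters.valid_electron, dt_fs)
    return CarrierMetrics(d_he=d_he, v_hole=v_h, v_electron=v_e)
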