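"""One-electron state containers and basis transforms.

The propagated state is the spin-restricted one-electron density matrix P.
Two representations are used:

* ``atomic`` -- the (possibly non-orthogonal) site/AO basis with overlap S,
  where Mulliken populations live on ``diag(P S)``;
* ``orthonormal`` -- the Lowdin-orthogonalized basis,
  ``P' = S^{1/2} P S^{1/2}``, in which the equation of motion takes the
  commutator form and unitary propagation preserves the spectrum of P'.

Closed-shell convention: orbital occupations lie in [0, 2] and
``Tr(P') = Tr(P S) = n_electrons``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HERMITICITY_TOL = 1e-10

__all__ = [
    "DensityMatrix",
    "FockMatrix",
    "spd_sqrt",
    "lowdin_transform",
    "lowdin_inverse",
]


def _check_hermitian(m: np.ndarray, tol: float, what: str) -> None:
    dev = float(np.max(np.abs(m - m.conj().T))) if m.size else 0.0
    if dev > tol:
        raise ValueError(f"{what} is not Hermitian: max |M - M^dagger| = {dev:.3e} > {tol:g}")


@dataclass
class DensityMatrix:
    """One-electron density matrix with an explicit basis flag."""

    values: np.ndarray
    basis: str = "orthonormal"  # "orthonormal" | "atomic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"density matrix must be square, got shape {self.values.shape}")
        if self.basis not in ("orthonormal", "atomic"):
            raise ValueError(f"unknown basis flag {self.basis!r}")
        _check_hermitian(self.values, HERMITICITY_TOL, "density matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def trace(self) -> float:
        """Electron count Tr(P'); only meaningful in the orthonormal basis."""
        return float(np.trace(self.values).real)

    def occupation_eigenvalues(self) -> np.ndarray:
        """Natural-orbital occupations (ascending); orthonormal basis only."""
        if self.basis != "orthonormal":
            raise ValueError("occupation eigenvalues require the orthonormal representation")
        return np.linalg.eigvalsh(self.values)

    def copy(self) -> "DensityMatrix":
        return DensityMatrix(self.values.copy(), self.basis)


@dataclass
class FockMatrix:
    """Effective one-electron Hamiltonian (hartree)."""

    values: np.ndarray
    basis: str = "orthonormal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"Fock matrix must be square, got shape {self.values.shape}")
        _check_hermitian(self.values, 1e-12, "Fock matrix")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class _OverlapFactors:
    """Cached S^{1/2} and S^{-1/2} of a symmetric positive-definite overlap."""

    sqrt: np.ndarray
    inv_sqrt: np.ndarray
    is_identity: bool = field(default=False)


def spd_sqrt(S: np.ndarray) -> _OverlapFactors:
    """Symmetric square root and inverse square root of an SPD matrix."""
    S = np.asarray(S, dtype=float)
    if np.allclose(S, np.eye(S.shape[0]), atol=1e-14):
        eye = np.eye(S.shape[0])
        return _OverlapFactors(eye, eye, is_identity=True)
    w, V = np.linalg.eigh(S)
    if w.min() <= 0.0:
        raise ValueError(f"overlap matrix is not positive definite (min eigenvalue {w.min():.3e})")
    half = (V * np.sqrt(w)) @ V.T
    inv_half = (V / np.sqrt(w)) @ V.T
    return _OverlapFactors(half, inv_half)


def lowdin_transform(P_AO: np.ndarray | DensityMatrix, S: np.ndarray) -> DensityMatrix:
    """Map an AO-basis density to the orthonormal basis, P' = S^{1/2} P S^{1/2}.

    Preserves the electron count: Tr(P') = Tr(P S).
    """
    values = P_AO.values if isinstance(P_AO, DensityMatrix) else np.asarray(P_AO, dtype=complex)
    f = spd_sqrt(S)
    if f.is_identity:
        return DensityMatrix(values.copy(), "orthonormal")
    return DensityMatrix(f.sqrt @ values @ f.sqrt, "orthonormal")


def lowdin_inverse(P_ortho: np.ndarray | DensityMatrix, S: np.ndarray) -> DensityMatrix:
    """Map an orthonormal-basis density back to the AO basis."""
    values = P_ortho.values if isinstance(P_ortho, DensityMatrix) else np.asarray(P_ortho, dtype=complex)
    f = spd_sqrt(S)
    if f.is_identity:
        return DensityMatrix(values.copy(), "atomic")
    return DensityMatrix(f.inv_sqrt @ values @ f.inv_sqrt, "atomic")
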