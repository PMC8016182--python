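"""Gamma-point phonons: dynamical matrix, mode solution, stationary-point classification.

Imaginary frequencies are reported as negative wavenumbers (the common
phonon-code sign convention): an eigenvalue lambda of the mass-weighted
dynamical matrix maps to ``nu = sign(lambda) * 108.591 * sqrt(|lambda|)`` in
cm^-1 for lambda in kcal/mol/A^2/amu.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ForceConstantsParseError, ParameterError
from .model_potential import FREQ_CM1

__all__ = [
    "PhononModeSet",
    "StationaryClassification",
    "build_dynamical_matrix",
    "solve_modes",
    "hessian_modes",
    "classify_stationary",
    "read_force_constants",
    "write_force_constants",
]

KCAL_PER_EV = 23.060548


@dataclass
class PhononModeSet:
    """Gamma-point mode table: frequencies (ascending) and mass-weighted eigenvectors.

    ``eigenvectors[:, k]`` is the orthonormal mass-weighted displacement
    pattern of mode k; Cartesian displacements are ``e[3i+a] / sqrt(m_i)``.
    ``acoustic_indices`` flags the three uniform-translation modes, which are
    excluded from all Raman intensity sums downstream.
    """

    frequencies_cm1: np.ndarray  # (3N,)
    eigenvectors: np.ndarray  # (3N, 3N), columns are modes
    acoustic_indices: np.ndarray  # (3,)
    masses: np.ndarray  # (N,)

    @property
    def n_modes(self) -> int:
        return len(self.frequencies_cm1)

    @property
    def optical_indices(self) -> np.ndarray:
        mask = np.ones(self.n_modes, dtype=bool)
        mask[self.acoustic_indices] = False
        return np.where(mask)[0]

    def cartesian_displacement(self, k: int) -> np.ndarray:
        """(N, 3) Cartesian displacement of mode k per unit normal coordinate (A*sqrt(amu))."""
        e = self.eigenvectors[:, k].reshape(-1, 3)
        return e / np.sqrt(self.masses)[:, None]


@dataclass
class StationaryClassification:
    kind: str  # "minimum" | "saddle"
    n_imaginary: int


def build_dynamical_matrix(hessian: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Mass-weight the Hessian: D[ia, jb] = H[ia, jb] / sqrt(m_i m_j)."""
    hessian = np.asarray(hessian, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n3 = hessian.shape[0]
    if hessian.shape != (n3, n3) or n3 != 3 * len(masses):
        raise ParameterError(
            f"dimension mismatch: hessian {hessian.shape}, {len(masses)} masses"
        )
    if np.max(np.abs(hessian - hessian.T)) > 1e-6 * max(np.max(np.abs(hessian)), 1e-300):
        raise ParameterError("hessian must be symmetric")
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)
    return hessian * np.outer(inv_sqrt_m, inv_sqrt_m)


def _translation_basis(masses: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted uniform-translation vectors, (3N, 3)."""
    n = len(masses)
    basis = np.zeros((3 * n, 3))
    sm = np.sqrt(masses)
    for alpha in range(3):
        basis[alpha::3, alpha] = sm
    return basis / np.linalg.norm(basis, axis=0)


def solve_modes(
    dynmat: np.ndarray, masses: np.ndarray, zero_tol_cm1: float = 0.1
) -> PhononModeSet:
    """Diagonalize the dynamical matrix and flag the acoustic subspace.

    The three modes of smallest |nu| whose eigenvectors overlap the
    uniform-translation subspace by more than 0.99 are flagged acoustic; if
    they do not all lie below ``zero_tol_cm1`` a warning is emitted (the set
    is still returned).
    """
    dynmat = np.asarray(dynmat, dtype=float)
    if np.max(np.abs(dynmat - dynmat.T)) > 1e-8 * max(np.max(np.abs(dynmat)), 1e-300):
        raise ParameterError("dynamical matrix must be symmetric")
    evals, evecs = np.linalg.eigh(dynmat)
    freqs = np.sign(evals) * FREQ_CM1 * np.sqrt(np.abs(evals))
    order = np.argsort(freqs)
    freqs, evecs = freqs[order], evecs[:, order]

    t_basis = _translation_basis(np.asarray(masses, dtype=float))
    overlaps = np.linalg.norm(t_basis.T @ evecs, axis=0)
    by_abs = np.argsort(np.abs(freqs), kind="stable")
    acoustic = [int(k) for k in by_abs if overlaps[k] > 0.99][:3]
    if len(acoustic) < 3:
        warnings.warn(
            "acoustic subspace not found by translation overlap; "
            "flagging the three smallest-|nu| modes",
            stacklevel=2,
        )
        acoustic = [int(k) for k in by_abs[:3]]
    elif any(abs(freqs[k]) > zero_tol_cm1 for k in acoustic):
        warnings.warn(
            f"acoustic modes exceed zero_tol_cm1 = {zero_tol_cm1} cm^-1 "
            "(Hessian without acoustic sum rule?)",
            stacklevel=2,
        )
    return PhononModeSet(
        frequencies_cm1=freqs,
        eigenvectors=evecs,
        acoustic_indices=np.array(sorted(acoustic)),
        masses=np.asarray(masses, dtype=float),
    )


def hessian_modes(
    hessian: np.ndarray, masses: np.ndarray, zero_tol_cm1: float = 0.1
) -> PhononModeSet:
    """Convenience: mass-weight a Hessian and solve for the Gamma-point modes."""
    return solve_modes(build_dynamical_matrix(hessian, masses), masses, zero_tol_cm1)


def classify_stationary(
    modes: PhononModeSet, imag_tol_cm1: float = 5.0
) -> StationaryClassification:
    """Count non-acoustic imaginary modes below ``-imag_tol_cm1``.

    A stationary point is a minimum iff no optical frequency is more negative
    than the tolerance (which absorbs numerical noise near zero).
    """
    freqs = modes.frequencies_cm1[modes.optical_indices]
    n_imag = int(np.sum(freqs < -imag_tol_cm1))
    return StationaryClassification("minimum" if n_imag == 0 else "saddle", n_imag)


# ---------------------------------------------------------------------------
# phonopy FORCE_CONSTANTS plain-text format (single Gamma cell)
# ---------------------------------------------------------------------------

def write_force_constants(path: str, hessian: np.ndarray, unit: str = "eV/A^2") -> None:
    """Write a 3N x 3N Hessian as a phonopy-style FORCE_CONSTANTS file.

    ``unit`` selects the on-disk unit: "eV/A^2" (the phonopy convention,
    internal kcal/mol/A^2 values are divided by 23.060548) or "kcal/mol/A^2"
    (no conversion).
    """
    scale = _unit_scale(unit)
    h = np.asarray(hessian, dtype=float) / scale
    n = h.shape[0] // 3
    blocks = h.reshape(n, 3, n, 3)
    with open(path, "w") as fh:
        fh.write(f"{n} {n}\n")
        for i in range(n):
            for j in range(n):
                fh.write(f"{i + 1} {j + 1}\n")
                for row in blocks[i, :, j, :]:
                    fh.write(f" {row[0]:21.15f} {row[1]:21.15f} {row[2]:21.15f}\n")


def _unit_scale(unit: str) -> float:
    if unit == "eV/A^2":
        return KCAL_PER_EV
    if unit == "kcal/mol/A^2":
        return 1.0
    raise ParameterError(f"unknown force-constant unit {unit!r}")


def read_force_constants(path: str, unit: str = "eV/A^2") -> np.ndarray:
    """Read a phonopy FORCE_CONSTANTS file into a dense 3N x 3N internal-unit Hessian.

    Accepts both the "N" and "N N" header forms.  Raises
    :class:`ForceConstantsParseError` with a line number on malformed input.
    """
    scale = _unit_scale(unit)
    with open(path) as fh:
        lines = fh.read().splitlines()

    def fail(line_no: int, msg: str):
        raise ForceConstantsParseError(f"{path}:{line_no + 1}: {msg}")

    if not lines:
        fail(0, "empty file")
    header = lines[0].split()
    if len(header) not in (1, 2):
        fail(0, f"bad header {lines[0]!r}")
    try:
        n = int(header[0])
        n2 = int(header[1]) if len(header) == 2 else n
    except ValueError:
        fail(0, f"non-integer header {lines[0]!r}")
    if n != n2:
        fail(0, f"non-square atom counts {n} x {n2} (single Gamma cell expected)")
    blocks = np.zeros((n, 3, n, 3))
    ln = 1
    for _ in range(n * n):
        if ln >= len(lines):
            fail(len(lines) - 1, "truncated file: missing block header")
        idx = lines[ln].split()
        try:
            i, j = int(idx[0]) - 1, int(idx[1]) - 1
        except (ValueError, IndexError):
            fail(ln, f"bad block header {lines[ln]!r}")
        if not (0 <= i < n and 0 <= j < n):
            fail(ln, f"atom indices out of range in {lines[ln]!r}")
        ln += 1
        for row in range(3):
            if ln >= len(lines):
                fail(len(lines) - 1, "truncated file: missing matrix row")
            vals = lines[ln].split()
            if len(vals) != 3:
                fail(ln, f"expected 3 numbers, got {lines[ln]!r}")
            try:
                blocks[i, row, j, :] = [float(v) for v in vals]
            except ValueError:
                fail(ln, f"non-numeric matrix row {lines[ln]!r}")
            ln += 1
    return blocks.reshape(3 * n, 3 * n) * scale
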