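"""Eigenvector following: descent from a saddle along an imaginary-frequency mode.

The saddle structure is perturbed along the chosen imaginary mode in both
signs (scaled to a fixed maximum atomic displacement), each perturbed copy is
re-minimized at fixed cell, and the children are re-classified and
re-analyzed for symmetry.  By construction of a symmetric double well the two
children have equal energies; they are equivalent as crystal structures up to
a lattice-compatible isometry (an origin shift combined, when the saddle has
an operation reversing the followed mode, with that operation's rotation
part).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .crystal_core import (
    CrystalStructure,
    SpaceGroupResult,
    _lattice_point_group,
    detect_symmetry,
)
from .errors import DescentError, ModeNotImaginaryError, ParameterError
from .lattice_dynamics import (
    PhononModeSet,
    StationaryClassification,
    classify_stationary,
    hessian_modes,
)
from .model_potential import ForceFieldSpec, energy_and_forces, hessian, minimize

__all__ = ["EscapeResult", "follow_imaginary_mode", "structures_equivalent", "delta_energy_per_molecule"]


@dataclass
class EscapeResult:
    """Outcome of a two-sided descent from a saddle point."""

    structure_plus: CrystalStructure
    structure_minus: CrystalStructure
    energy_saddle: float
    energy_plus: float
    energy_minus: float
    equivalent: bool
    rmsd: float
    delta_e_per_molecule: float
    parent_group: SpaceGroupResult
    child_group: SpaceGroupResult  # at the tight tolerance
    child_group_loose: SpaceGroupResult  # at the loose (conventional) tolerance
    child_classification: StationaryClassification
    mode_index: int

    @property
    def energies(self) -> tuple[float, float]:
        return self.energy_plus, self.energy_minus


def delta_energy_per_molecule(e_saddle: float, e_min: float, n_molecules: int) -> float:
    """(E_saddle - E_min) / n_molecules; raises if the descent went uphill."""
    if n_molecules <= 0:
        raise ParameterError("n_molecules must be positive")
    delta = (e_saddle - e_min) / n_molecules
    if delta < -1e-10:
        raise DescentError(f"descent produced a higher-energy point (dE = {-delta:.3e})")
    return max(delta, 0.0)


def structures_equivalent(
    a: CrystalStructure,
    b: CrystalStructure,
    allow_origin_shift: bool = True,
    tol: float = 0.1,
    allow_lattice_point_ops: bool = False,
) -> tuple[bool, float]:
    """Best RMSD between two same-cell structures, modulo origin shifts.

    Atom matching is species-respecting (optimal assignment under
    minimum-image distances).  With ``allow_lattice_point_ops`` the rotational
    part may additionally be any lattice point-group operation — the matching
    used when comparing descent children, which are related by a symmetry
    operation the distortion destroyed, not by a pure translation.
    Returns ``(best_rmsd < tol, best_rmsd)``.
    """
    if a.n_atoms != b.n_atoms or sorted(a.species) != sorted(b.species):
        raise ParameterError("structures must share the cell content (species multiset)")
    if not np.allclose(a.lattice, b.lattice, atol=1e-8):
        raise ParameterError("structures must share the same cell")

    rotations = [np.eye(3, dtype=int)]
    if allow_lattice_point_ops:
        rotations = _lattice_point_group(a.lattice)

    species_a = np.array(a.species)
    species_b = np.array(b.species)
    ref = species_a[0]
    a0 = int(np.where(species_a == ref)[0][0])
    best = np.inf
    for w_mat in rotations:
        fa = a.frac_coords @ w_mat.T
        if allow_origin_shift:
            shifts = [b.frac_coords[j] - fa[a0] for j in np.where(species_b == ref)[0]]
        else:
            shifts = [np.zeros(3)]
        for shift in shifts:
            moved = fa + shift
            d = moved[:, None, :] - b.frac_coords[None, :, :]
            d -= np.round(d)
            cart = d @ a.lattice
            dist2 = np.sum(cart * cart, axis=2)
            dist2[species_a[:, None] != species_b[None, :]] = 1e12
            rows, cols = linear_sum_assignment(dist2)
            # refine: re-center the shift on the matched displacement mean
            if allow_origin_shift:
                resid = b.frac_coords[cols] - moved[rows]
                resid -= np.round(resid)
                moved2 = moved + resid.mean(axis=0)
                d2 = moved2[rows] - b.frac_coords[cols]
                d2 -= np.round(d2)
                rmsd = float(np.sqrt(np.mean(np.sum((d2 @ a.lattice) ** 2, axis=1))))
            else:
                rmsd = float(np.sqrt(dist2[rows, cols].mean()))
            best = min(best, rmsd)
    return best < tol, best


def follow_imaginary_mode(
    structure: CrystalStructure,
    ff: ForceFieldSpec,
    modes: PhononModeSet,
    mode_index: int | None = None,
    max_initial_displacement: float = 0.1,
    force_tol: float = 1e-6,
    tol_tight: float = 0.02,
    tol_loose: float = 0.25,
    equivalence_tol: float = 0.01,
) -> EscapeResult:
    """Perturb along an imaginary mode in both signs, re-minimize and analyze.

    The default mode is the most negative non-acoustic one; following a real
    mode raises :class:`ModeNotImaginaryError`.  The initial step is scaled so
    the largest single-atom displacement equals ``max_initial_displacement``
    (in angstrom).  Child symmetry is reported at two tolerances — the
    conventional 0.25 A, at which a slightly distorted child is indistinguishable
    from its higher-symmetry parent, and a tight 0.02 A that resolves it —
    to surface rather than hide the tolerance pitfall.
    """
    opt = modes.optical_indices
    if mode_index is None:
        mode_index = int(opt[np.argmin(modes.frequencies_cm1[opt])])
    if modes.frequencies_cm1[mode_index] >= 0 or mode_index in modes.acoustic_indices:
        raise ModeNotImaginaryError(
            f"mode {mode_index} (nu = {modes.frequencies_cm1[mode_index]:.2f} cm^-1) "
            "is not an imaginary optical mode"
        )
    e_saddle, _ = energy_and_forces(structure, ff)
    disp = modes.cartesian_displacement(mode_index)
    disp = disp * (max_initial_displacement / np.max(np.linalg.norm(disp, axis=1)))
    cart0 = structure.cart_coords

    children = []
    for sign in (+1.0, -1.0):
        child, converged, e_child = minimize(
            structure.with_cart(cart0 + sign * disp), ff, force_tol=force_tol
        )
        if not converged:
            raise DescentError(f"descent (sign {sign:+.0f}) did not reach force_tol")
        if e_child > e_saddle + 1e-10:
            raise DescentError(
                f"descent (sign {sign:+.0f}) failed to lower the energy "
                f"({e_child:.6f} vs {e_saddle:.6f})"
            )
        children.append((child, e_child))
    (plus, e_plus), (minus, e_minus) = children

    h_child = hessian(plus, ff, warn_force=np.inf)
    modes_child = hessian_modes(h_child, plus.masses)
    classification = classify_stationary(modes_child)

    equivalent, rmsd = structures_equivalent(
        plus, minus, allow_origin_shift=True, tol=equivalence_tol, allow_lattice_point_ops=True
    )
    return EscapeResult(
        structure_plus=plus,
        structure_minus=minus,
        energy_saddle=e_saddle,
        energy_plus=e_plus,
        energy_minus=e_minus,
        equivalent=equivalent,
        rmsd=rmsd,
        delta_e_per_molecule=delta_energy_per_molecule(
            e_saddle, e_plus, structure.n_molecules
        ),
        parent_group=detect_symmetry(structure, tol_loose),
        child_group=detect_symmetry(plus, tol_tight),
        child_group_loose=detect_symmetry(plus, tol_loose),
        child_classification=classification,
        mode_index=mode_index,
    )
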