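"""Irrep assignment of phonon modes from factor-group operations.

The factor group of a space group at the Gamma point is represented by one
space-group operation per point-group class.  A phonon eigenvector ``e`` gets
the character ``chi(class) = e^T M(op) e`` where ``M`` is the 3N x 3N
displacement operator (atom permutation tensored with the Cartesian rotation
part); matching the character vector against the shipped tables yields the
symmetry species, exactly the procedure of deducing mode symmetry from the
transformation properties of the eigenvectors.

Shipped tables cover the 1-D-irrep groups C1, Ci, Cs, C2, C2h, C2v, D2, D2h.
For groups with several classes of the same (det, trace) signature (the two
C2v mirror planes, the D2/D2h axes) the class assignment follows a
deterministic axis ordering (closest to z, then y, then x); the resulting
B1/B2-type labels are convention-dependent, and a global swap is accepted as
equivalent, as in standard factor-group practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .crystal_core import CrystalStructure, SpaceGroupResult, SymmetryOp, _match_atoms
from .errors import (
    AmbiguousAssignmentError,
    CorrelationError,
    InconsistentSymmetryError,
    ParameterError,
)
from .lattice_dynamics import PhononModeSet

__all__ = [
    "CharacterTable",
    "IrrepAssignment",
    "load_character_table",
    "factor_group",
    "displacement_operator",
    "assign_irreps",
    "symmetry_adapted_modes",
    "decompose_representation",
    "correlate",
    "activity",
]


@dataclass
class CharacterTable:
    """Point-group character table, optionally bound to concrete space-group ops."""

    name: str
    class_labels: list[str]
    irrep_names: list[str]
    characters: np.ndarray  # (n_irreps, n_classes)
    raman_active: dict[str, bool]
    ir_active: dict[str, bool]
    class_axis_rank: list[int | None]
    class_signatures: list[tuple[int, int]]  # (det, trace) per class
    class_reps: list[SymmetryOp] | None = None

    @property
    def order(self) -> int:
        return len(self.class_labels)  # all shipped groups have singleton classes

    def irrep_dimension(self, name: str) -> int:
        return int(self.characters[self.irrep_names.index(name), 0])

    def check_orthogonality(self, tol: float = 1e-10) -> bool:
        """Row orthogonality under the class-weighted inner product."""
        g = self.characters @ self.characters.T  # singleton classes
        return bool(np.max(np.abs(g - self.order * np.eye(len(self.irrep_names)))) < tol)


def _load_raw() -> dict:
    with resources.files("phonoraman.data").joinpath("character_tables.json").open() as fh:
        return json.load(fh)


def load_character_table(name: str) -> CharacterTable:
    raw = _load_raw()["groups"]
    if name not in raw:
        raise ParameterError(f"no shipped character table for group {name!r}")
    g = raw[name]
    return CharacterTable(
        name=name,
        class_labels=[c["label"] for c in g["classes"]],
        irrep_names=[i["name"] for i in g["irreps"]],
        characters=np.array([i["characters"] for i in g["irreps"]], dtype=float),
        raman_active={i["name"]: bool(i["raman"]) for i in g["irreps"]},
        ir_active={i["name"]: bool(i["ir"]) for i in g["irreps"]},
        class_axis_rank=[c.get("axis_rank") for c in g["classes"]],
        class_signatures=[(c["det"], c["trace"]) for c in g["classes"]],
    )


def available_tables() -> list[str]:
    return sorted(_load_raw()["groups"].keys())


# ---------------------------------------------------------------------------
# Factor-group construction from detected operations
# ---------------------------------------------------------------------------

def _op_axis(r_cart: np.ndarray) -> np.ndarray:
    """Characteristic axis: rotation axis for proper C2, plane normal for a mirror."""
    det = np.linalg.det(r_cart)
    m = r_cart if det > 0 else -r_cart  # mirror normal = rotation axis of -sigma
    w, v = np.linalg.eigh(0.5 * (m + m.T))
    axis = v[:, int(np.argmax(w))]
    for comp in axis:
        if abs(comp) > 1e-8:
            return axis * np.sign(comp)
    return axis


def _signature(op: SymmetryOp, lattice: np.ndarray) -> tuple[int, int]:
    r = op.cartesian_rotation(lattice)
    return int(round(np.linalg.det(r))), int(round(np.trace(r)))


_POINT_GROUP_BY_SIGS = {
    (): "C1",
    ((-1, -3),): "Ci",
    ((-1, 1),): "Cs",
    ((1, -1),): "C2",
    ((-1, -3), (-1, 1), (1, -1)): "C2h",
    ((-1, 1), (-1, 1), (1, -1)): "C2v",
    ((1, -1), (1, -1), (1, -1)): "D2",
    ((-1, -3), (-1, 1), (-1, 1), (-1, 1), (1, -1), (1, -1), (1, -1)): "D2h",
}


def factor_group(
    spacegroup: SpaceGroupResult | list[SymmetryOp], lattice: np.ndarray
) -> CharacterTable:
    """Build the factor-group character table with concrete class representatives.

    Non-identity operations are classified by the (det, trace) signature of
    their Cartesian rotation part; same-signature classes are ordered by a
    deterministic axis rank.
    """
    ops = spacegroup.operations if isinstance(spacegroup, SpaceGroupResult) else spacegroup
    non_id = [op for op in ops if _signature(op, lattice) != (1, 3)]
    sigs = tuple(sorted(_signature(op, lattice) for op in non_id))
    name = _POINT_GROUP_BY_SIGS.get(sigs)
    if name is None:
        raise ParameterError(f"factor group with signatures {sigs} is not shipped")
    table = load_character_table(name)

    reps: list[SymmetryOp | None] = [None] * len(table.class_labels)
    by_sig: dict[tuple[int, int], list[SymmetryOp]] = {}
    identity = next(op for op in ops if _signature(op, lattice) == (1, 3))
    for op in non_id:
        by_sig.setdefault(_signature(op, lattice), []).append(op)

    def axis_key(op: SymmetryOp):
        ax = _op_axis(op.cartesian_rotation(lattice))
        return (-round(abs(ax[2]), 6), -round(abs(ax[1]), 6), -round(abs(ax[0]), 6))

    for sig, candidates in by_sig.items():
        slots = [c for c in range(len(table.class_labels)) if table.class_signatures[c] == sig]
        if len(slots) != len(candidates):
            raise ParameterError("class multiplicity mismatch against the shipped table")
        ranked = sorted(
            slots, key=lambda c: (table.class_axis_rank[c] if table.class_axis_rank[c] is not None else 0)
        )
        for slot, op in zip(ranked, sorted(candidates, key=axis_key)):
            reps[slot] = op
    for c, lbl in enumerate(table.class_labels):
        if table.class_signatures[c] == (1, 3):
            reps[c] = identity
    if any(r is None for r in reps):
        raise ParameterError("could not populate all factor-group classes")
    return replace(table, class_reps=list(reps))  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# Displacement operator and characters
# ---------------------------------------------------------------------------

def displacement_operator(
    structure: CrystalStructure, op: SymmetryOp, tol: float = 0.1
) -> np.ndarray:
    """3N x 3N orthogonal matrix: atom permutation tensored with the Cartesian rotation.

    Raises :class:`InconsistentSymmetryError` naming the worst-matched atom
    when ``op`` is not a symmetry of the structure within ``tol``.
    """
    perm = _match_atoms(structure, op.W, op.w, tol)
    if perm is None:
        frac = structure.frac_coords
        images = frac @ op.W.T + op.w
        worst, worst_d = -1, -1.0
        for i in range(structure.n_atoms):
            d = images[i] - frac
            dist = np.linalg.norm(structure.min_image_cart(d), axis=1)
            dist[np.array(structure.species) != structure.species[i]] = np.inf
            dmin = float(np.min(dist))
            if dmin > worst_d:
                worst, worst_d = i, dmin
        raise InconsistentSymmetryError(
            f"op is not a symmetry within {tol} A: atom {worst} "
            f"({structure.species[worst]}) misses by {worst_d:.4f} A"
        )
    r = op.cartesian_rotation(structure.lattice)
    n = structure.n_atoms
    m = np.zeros((3 * n, 3 * n))
    for i in range(n):
        p = perm[i]
        m[3 * p : 3 * p + 3, 3 * i : 3 * i + 3] = r
    return m


@dataclass
class IrrepAssignment:
    """Per-optical-mode symmetry labels with matching residuals."""

    mode_indices: np.ndarray
    labels: list[str]
    characters: np.ndarray  # (n_modes_or_clusters rows expanded per mode, n_classes)
    residuals: np.ndarray

    def label_of(self, mode_index: int) -> str:
        pos = int(np.where(self.mode_indices == mode_index)[0][0])
        return self.labels[pos]

    def multiplicities(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lbl in self.labels:
            out[lbl] = out.get(lbl, 0) + 1
        return out


def _clusters(freqs: np.ndarray, tol: float) -> list[list[int]]:
    clusters: list[list[int]] = []
    for k in range(len(freqs)):
        if clusters and abs(freqs[k] - freqs[clusters[-1][-1]]) <= tol:
            clusters[-1].append(k)
        else:
            clusters.append([k])
    return clusters


def assign_irreps(
    modes: PhononModeSet,
    structure: CrystalStructure,
    table: CharacterTable,
    degeneracy_tol_cm1: float = 0.5,
    residual_tol: float = 0.05,
    match_tol: float = 0.1,
) -> IrrepAssignment:
    """Assign irrep labels to the non-acoustic modes.

    Each mode is first matched individually: its character vector
    ``chi_k(class) = e_k^T M(class) e_k`` is compared against every irrep row
    and assigned to the closest one.  Modes closer than ``degeneracy_tol_cm1``
    whose individual characters match nothing (numerically mixed degenerate
    eigenvectors; see :func:`symmetry_adapted_modes`) are treated as one
    cluster whose character is the subspace trace, matched against sums of
    irrep rows, with labels handed out in the table's irrep order against
    ascending frequency (a documented tie-break).  A residual above
    ``residual_tol`` raises :class:`AmbiguousAssignmentError` naming the mode.
    """
    if table.class_reps is None:
        raise ParameterError("table must carry class representatives (use factor_group)")
    mats = [displacement_operator(structure, op, tol=match_tol) for op in table.class_reps]
    opt = modes.optical_indices
    freqs = modes.frequencies_cm1[opt]
    from itertools import combinations_with_replacement

    labels: list[str] = []
    chars_rows: list[np.ndarray] = []
    residuals: list[float] = []
    for cluster in _clusters(freqs, degeneracy_tol_cm1):
        idx = opt[cluster]
        vecs = modes.eigenvectors[:, idx]
        per_mode_chi = np.array(
            [[float(vecs[:, c] @ m @ vecs[:, c]) for m in mats] for c in range(len(cluster))]
        )
        dists = np.linalg.norm(
            per_mode_chi[:, None, :] - table.characters[None, :, :], axis=2
        )  # (modes, irreps)
        best_rows = np.argmin(dists, axis=1)
        best_dists = dists[np.arange(len(cluster)), best_rows]
        if np.all(best_dists <= residual_tol):
            for c, row in enumerate(best_rows):
                labels.append(table.irrep_names[row])
                chars_rows.append(per_mode_chi[c])
                residuals.append(float(best_dists[c]))
            continue
        if len(cluster) == 1:
            raise AmbiguousAssignmentError(
                f"mode {int(idx[0])} (nu = {freqs[cluster[0]]:.2f} cm^-1): character "
                f"{np.round(per_mode_chi[0], 3).tolist()} matches no irrep "
                f"(residual {best_dists[0]:.3f} > {residual_tol})"
            )
        # mixed degenerate cluster: match the subspace trace against multisets
        chi = per_mode_chi.sum(axis=0)
        best = None
        for combo in combinations_with_replacement(range(len(table.irrep_names)), len(cluster)):
            expected = table.characters[list(combo)].sum(axis=0)
            dist = float(np.linalg.norm(chi - expected))
            if best is None or dist < best[0]:
                best = (dist, combo)
        dist, combo = best
        if dist > residual_tol * len(cluster):
            raise AmbiguousAssignmentError(
                f"modes {idx.tolist()} (nu ~ {freqs[cluster[0]]:.2f} cm^-1): character "
                f"{np.round(chi, 3).tolist()} matches no irrep combination "
                f"(residual {dist:.3f} > {residual_tol * len(cluster)})"
            )
        for k, irrep_i in zip(cluster, combo):
            labels.append(table.irrep_names[irrep_i])
            chars_rows.append(chi / len(cluster))
            residuals.append(dist)
    return IrrepAssignment(
        mode_indices=opt,
        labels=labels,
        characters=np.array(chars_rows),
        residuals=np.array(residuals),
    )


def symmetry_adapted_modes(
    modes: PhononModeSet,
    structure: CrystalStructure,
    table: CharacterTable,
    dynmat: np.ndarray,
    degeneracy_tol_cm1: float = 0.5,
    match_tol: float = 0.1,
) -> PhononModeSet:
    """Rotate eigenvectors within (quasi-)degenerate clusters onto irrep subspaces.

    Numerically degenerate eigenvalues — including *accidental* degeneracies,
    e.g. the near-fourfold intramolecular multiplets of weakly coupled
    molecules — leave the eigenvectors an arbitrary mix across irreps, which
    blurs selection rules.  Applying the projection operators
    ``P_i = (1/|G|) sum_R chi_i(R) M(R)`` to each cluster subspace and
    re-orthonormalizing recovers symmetry-pure modes; frequencies are
    recomputed as Rayleigh quotients with the dynamical matrix.
    """
    if table.class_reps is None:
        raise ParameterError("table must carry class representatives (use factor_group)")
    mats = [displacement_operator(structure, op, tol=match_tol) for op in table.class_reps]
    order = len(mats)
    from .lattice_dynamics import FREQ_CM1

    freqs = modes.frequencies_cm1.copy()
    vecs = modes.eigenvectors.copy()
    for cluster in _clusters(freqs, degeneracy_tol_cm1):
        if len(cluster) == 1:
            continue
        v = vecs[:, cluster]
        new_cols: list[np.ndarray] = []
        for row in table.characters:
            proj = sum(chi * m for chi, m in zip(row, mats)) / order
            w = proj @ v
            q, s, _ = np.linalg.svd(w, full_matrices=False)
            new_cols.extend(q[:, k] for k in range(len(s)) if s[k] > 1e-6)
        if len(new_cols) != len(cluster):  # projection failed; keep original basis
            continue
        basis = np.column_stack(new_cols)
        # re-orthonormalize (numerically) and recompute Rayleigh frequencies
        q, _ = np.linalg.qr(basis)
        lam = np.einsum("ik,ij,jk->k", q, dynmat, q)
        rq = np.sign(lam) * FREQ_CM1 * np.sqrt(np.abs(lam))
        sort = np.argsort(rq)
        vecs[:, cluster] = q[:, sort]
        freqs[cluster] = rq[sort]
    return PhononModeSet(
        frequencies_cm1=freqs,
        eigenvectors=vecs,
        acoustic_indices=modes.acoustic_indices,
        masses=modes.masses,
    )


def decompose_representation(
    structure: CrystalStructure, table: CharacterTable, match_tol: float = 0.1
) -> dict[str, int]:
    """Reduce the full 3N Cartesian displacement representation.

    Standard reduction formula ``n_i = (1/|G|) sum_R chi_i(R) Tr[M(R)]``;
    serves as the brute-force oracle for :func:`assign_irreps` totals
    (acoustic modes included: subtract the translation irreps to compare with
    optical-only counts).
    """
    if table.class_reps is None:
        raise ParameterError("table must carry class representatives (use factor_group)")
    traces = np.array(
        [float(np.trace(displacement_operator(structure, op, tol=match_tol))) for op in table.class_reps]
    )
    order = len(table.class_reps)
    out: dict[str, int] = {}
    for name, row in zip(table.irrep_names, table.characters):
        n = float(np.dot(row, traces)) / order
        if abs(n - round(n)) > 1e-6:
            raise InconsistentSymmetryError(
                f"non-integer multiplicity {n} for irrep {name}: ops are not a group "
                "for this structure"
            )
        out[name] = int(round(n))
    return out


def correlate(
    parent: CharacterTable, sub: CharacterTable, preserved: dict[str, str]
) -> dict[str, str]:
    """Map each parent irrep to the subgroup irrep agreeing on every preserved class.

    ``preserved`` maps parent class labels to subgroup class labels (the
    operations common to both groups).  Raises :class:`CorrelationError` when
    no unique target exists.
    """
    p_idx = [parent.class_labels.index(pc) for pc in preserved]
    s_idx = [sub.class_labels.index(sc) for sc in preserved.values()]
    mapping: dict[str, str] = {}
    for pname, prow in zip(parent.irrep_names, parent.characters):
        restricted = prow[p_idx]
        matches = [
            sname
            for sname, srow in zip(sub.irrep_names, sub.characters)
            if np.allclose(srow[s_idx], restricted)
        ]
        if len(matches) != 1:
            raise CorrelationError(
                f"parent irrep {pname}: {len(matches)} consistent subgroup irreps "
                f"(preserved classes {preserved})"
            )
        mapping[pname] = matches[0]
    return mapping


def activity(irrep: str, table: CharacterTable) -> tuple[bool, bool]:
    """(raman, ir) activity flags; mutual exclusion holds in centrosymmetric groups."""
    if irrep not in table.raman_active:
        raise ParameterError(f"irrep {irrep!r} not in table {table.name}")
    return table.raman_active[irrep], table.ir_active[irrep]
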