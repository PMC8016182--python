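"""Crystal structures, symmetry-operation algebra and tolerance-based space-group detection.

Conventions
-----------
* Fractional coordinates are row vectors wrapped into ``[0, 1)``; Cartesian
  positions are obtained as ``x = f @ lattice`` with the lattice rows being the
  cell vectors a, b, c (in angstrom).
* A symmetry operation acts on a fractional *column* vector as
  ``f' = W @ f + w`` with an integer rotation part ``W`` and a fractional
  translation ``w``.
* An atom matches its symmetry image when the minimum-image Cartesian distance
  is below the distance tolerance (default 0.25 angstrom, the conventional
  crystallographic equivalence tolerance).
* Molecules are taken from the input partition (``molecule_index``); they are
  never re-derived by bond perception.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import CifParseError, InconsistentSymmetryError, InvalidStructureError

__all__ = [
    "CrystalStructure",
    "SymmetryOp",
    "SpaceGroupResult",
    "detect_symmetry",
    "molecule_orbits",
    "read_cif",
    "write_cif",
    "cif_roundtrip",
]


def wrap_frac(frac: np.ndarray) -> np.ndarray:
    """Wrap fractional coordinates into [0, 1)."""
    return np.asarray(frac, dtype=float) - np.floor(frac)


@dataclass
class CrystalStructure:
    """A periodic crystal: cell, atoms, masses and a molecule partition.

    Attributes
    ----------
    lattice : (3, 3) array
        Rows are the cell vectors a, b, c in angstrom; determinant must be
        positive (right-handed cell).
    frac_coords : (N, 3) array
        Fractional coordinates, wrapped into [0, 1) on construction.
    species : list of str
        Element symbols, one per atom.
    masses : (N,) array
        Atomic masses in amu, strictly positive.
    molecule_index : (N,) int array
        Partition of the atoms into molecules (labels need not be contiguous).
    """

    lattice: np.ndarray
    frac_coords: np.ndarray
    species: list[str]
    masses: np.ndarray
    molecule_index: np.ndarray

    def __post_init__(self) -> None:
        self.lattice = np.asarray(self.lattice, dtype=float).reshape(3, 3)
        if np.linalg.det(self.lattice) <= 1e-8:
            raise InvalidStructureError(
                "lattice determinant must be positive (degenerate or left-handed cell)"
            )
        self.frac_coords = wrap_frac(np.asarray(self.frac_coords, dtype=float).reshape(-1, 3))
        self.species = [str(s) for s in self.species]
        self.masses = np.asarray(self.masses, dtype=float).reshape(-1)
        self.molecule_index = np.asarray(self.molecule_index, dtype=int).reshape(-1)
        n = len(self.frac_coords)
        if not (len(self.species) == len(self.masses) == len(self.molecule_index) == n):
            raise InvalidStructureError("species/masses/molecule_index length mismatch")
        if np.any(self.masses <= 0):
            raise InvalidStructureError("all masses must be strictly positive")
        if any(not s for s in self.species):
            raise InvalidStructureError("empty species symbol")

    @property
    def n_atoms(self) -> int:
        return len(self.frac_coords)

    @property
    def molecules(self) -> list[int]:
        """Sorted distinct molecule labels."""
        return sorted(set(self.molecule_index.tolist()))

    @property
    def n_molecules(self) -> int:
        return len(set(self.molecule_index.tolist()))

    @property
    def cart_coords(self) -> np.ndarray:
        return self.frac_coords @ self.lattice

    def with_frac(self, frac: np.ndarray) -> "CrystalStructure":
        return replace(self, frac_coords=wrap_frac(np.asarray(frac, dtype=float)))

    def with_cart(self, cart: np.ndarray) -> "CrystalStructure":
        frac = np.asarray(cart, dtype=float) @ np.linalg.inv(self.lattice)
        return self.with_frac(frac)

    def min_image_cart(self, dfrac: np.ndarray) -> np.ndarray:
        """Cartesian displacement(s) for fractional difference(s) under minimum image."""
        d = np.asarray(dfrac, dtype=float)
        d = d - np.round(d)
        return d @ self.lattice


@dataclass(frozen=True)
class SymmetryOp:
    """Space-group operation in the fractional basis: f' = rotation @ f + translation."""

    rotation: tuple  # 3x3 nested tuple of ints
    translation: tuple  # 3 floats in [0, 1)

    @staticmethod
    def from_arrays(rotation: np.ndarray, translation: np.ndarray) -> "SymmetryOp":
        rot = np.rint(np.asarray(rotation)).astype(int)
        if abs(round(float(np.linalg.det(rot)))) != 1:
            raise InconsistentSymmetryError("rotation part must have determinant +-1")
        tr = wrap_frac(np.asarray(translation, dtype=float))
        return SymmetryOp(tuple(map(tuple, rot.tolist())), tuple(float(t) for t in tr))

    @property
    def W(self) -> np.ndarray:
        return np.array(self.rotation, dtype=int)

    @property
    def w(self) -> np.ndarray:
        return np.array(self.translation, dtype=float)

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.W, np.eye(3, dtype=int)) and np.allclose(
            np.minimum(self.w, 1.0 - self.w), 0.0, atol=1e-8
        )

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to row-vector fractional coordinates (not wrapped)."""
        return np.asarray(frac, dtype=float) @ self.W.T + self.w

    def compose(self, other: "SymmetryOp") -> "SymmetryOp":
        """self after other: (self o other)(f) = self(other(f))."""
        return SymmetryOp.from_arrays(self.W @ other.W, self.W @ other.w + self.w)

    def cartesian_rotation(self, lattice: np.ndarray) -> np.ndarray:
        """Cartesian rotation matrix acting on column vectors."""
        a_t = np.asarray(lattice, dtype=float).T
        return a_t @ self.W @ np.linalg.inv(a_t)

    def same_as(self, other: "SymmetryOp", tol: float = 1e-6) -> bool:
        if not np.array_equal(self.W, other.W):
            return False
        d = self.w - other.w
        d -= np.round(d)
        return bool(np.all(np.abs(d) < tol))


IDENTITY_OP = SymmetryOp.from_arrays(np.eye(3), np.zeros(3))


@dataclass
class SpaceGroupResult:
    """Detected space-group information.

    ``z_count`` is the number of molecules per cell (Z); ``z_prime`` the number
    of symmetry-inequivalent molecules (Z').
    """

    hm_symbol: str
    operations: list[SymmetryOp]
    centrosymmetric: bool
    z_count: int
    z_prime: int
    orbits: list[list[int]] = field(default_factory=list)

    @property
    def order(self) -> int:
        return len(self.operations)


# ---------------------------------------------------------------------------
# Lattice point group and op search
# ---------------------------------------------------------------------------

_POINT_GROUP_CACHE: dict[bytes, list[np.ndarray]] = {}


def _lattice_point_group(lattice: np.ndarray, tol: float = 1e-5) -> list[np.ndarray]:
    """Integer matrices W (entries in {-1,0,1}) whose Cartesian image is orthogonal.

    Entries beyond +-1 cannot occur for the conventional (reduced-ish) cells
    this package handles.  Results are cached per lattice.
    """
    key = np.round(np.asarray(lattice, dtype=float), 9).tobytes()
    if key in _POINT_GROUP_CACHE:
        return _POINT_GROUP_CACHE[key]
    a_t = np.asarray(lattice, dtype=float).T
    a_t_inv = np.linalg.inv(a_t)
    out = []
    for entries in itertools.product((-1, 0, 1), repeat=9):
        w_mat = np.array(entries, dtype=int).reshape(3, 3)
        det = int(round(np.linalg.det(w_mat)))
        if det not in (-1, 1):
            continue
        r = a_t @ w_mat @ a_t_inv
        if np.max(np.abs(r @ r.T - np.eye(3))) < tol:
            out.append(w_mat)
    _POINT_GROUP_CACHE[key] = out
    return out


def _match_atoms(
    structure: CrystalStructure,
    w_mat: np.ndarray,
    trans: np.ndarray,
    tol: float,
) -> np.ndarray | None:
    """Permutation mapping each atom to its image under (W, w), or None.

    Requires a species-preserving bijection with every minimum-image distance
    below ``tol``.
    """
    frac = structure.frac_coords
    images = frac @ w_mat.T + trans
    n = structure.n_atoms
    perm = np.full(n, -1, dtype=int)
    used = np.zeros(n, dtype=bool)
    species = np.array(structure.species)
    for i in range(n):
        d = images[i] - frac  # (n, 3)
        cart = structure.min_image_cart(d)
        dist = np.linalg.norm(cart, axis=1)
        dist[species != species[i]] = np.inf
        dist[used] = np.inf
        j = int(np.argmin(dist))
        if dist[j] >= tol:
            return None
        perm[i] = j
        used[j] = True
    return perm


def _refine_translation(
    structure: CrystalStructure, w_mat: np.ndarray, trans: np.ndarray, perm: np.ndarray
) -> np.ndarray:
    """Least-squares translation: mean residual of the matched images."""
    frac = structure.frac_coords
    images = frac @ w_mat.T + trans
    d = frac[perm] - images
    d -= np.round(d)
    return wrap_frac(trans + d.mean(axis=0))


def _snap_fraction(trans: np.ndarray, snap_tol: float = 0.05) -> np.ndarray:
    """Snap translation components to nearby simple fractions (n/12)."""
    snapped = np.round(trans * 12.0) / 12.0
    out = np.where(np.abs(snapped - trans) < snap_tol, snapped, trans)
    return wrap_frac(out)


def detect_symmetry(structure: CrystalStructure, tol_distance: float = 0.25) -> SpaceGroupResult:
    """Find the highest-symmetry space group matching the structure within a tolerance.

    Every candidate rotation from the lattice point group is combined with
    candidate translations derived from atom pairs of a reference species; an
    operation is accepted when it maps every atom onto an atom of the same
    species within ``tol_distance`` (minimum-image Cartesian distance).

    Hermann-Mauguin names are emitted for the small set of groups this package
    distinguishes (P1, P-1, P2, P2_1, Pm, Pc, P2_1/c, Pna2_1); any other group
    is reported as ``order-N group``.
    """
    if tol_distance <= 0:
        raise InvalidStructureError("tol_distance must be positive")
    if abs(np.linalg.det(structure.lattice)) < 1e-8:
        raise InvalidStructureError("degenerate lattice")

    species = np.array(structure.species)
    # candidate translations anchor on the first atom of every species: a
    # species sitting on the distorted part of the structure would otherwise
    # produce only translations that misplace the rest of the cell
    anchors = []
    for sp in sorted(set(structure.species)):
        idx = np.where(species == sp)[0]
        anchors.append((int(idx[0]), idx))

    ops: list[SymmetryOp] = []
    for w_mat in _lattice_point_group(structure.lattice):
        best: tuple[float, np.ndarray] | None = None
        for a0, ref_idx in anchors:
            for b in ref_idx:
                trans = wrap_frac(structure.frac_coords[b] - w_mat @ structure.frac_coords[a0])
                perm = _match_atoms(structure, w_mat, trans, tol_distance)
                if perm is None:
                    continue
                trans = _refine_translation(structure, w_mat, trans, perm)
                trans = _snap_fraction(trans)
                perm2 = _match_atoms(structure, w_mat, trans, tol_distance)
                if perm2 is None:  # snapping overshot; keep the refined translation
                    trans = _refine_translation(structure, w_mat, wrap_frac(trans), perm)
                    perm2 = perm
                images = structure.frac_coords @ w_mat.T + trans
                d = structure.frac_coords[perm2] - images
                d -= np.round(d)
                rms = float(np.sqrt(np.mean(np.sum((d @ structure.lattice) ** 2, axis=1))))
                if best is None or rms < best[0]:
                    best = (rms, trans)
        if best is not None:
            ops.append(SymmetryOp.from_arrays(w_mat, best[1]))

    centro = any(np.array_equal(op.W, -np.eye(3, dtype=int)) for op in ops)
    orbits = molecule_orbits(structure, ops, tol=tol_distance)
    return SpaceGroupResult(
        hm_symbol=_name_group(ops, structure.lattice),
        operations=ops,
        centrosymmetric=centro,
        z_count=structure.n_molecules,
        z_prime=len(orbits),
        orbits=orbits,
    )


# ---------------------------------------------------------------------------
# Group naming
# ---------------------------------------------------------------------------

def op_signature(op: SymmetryOp, lattice: np.ndarray) -> tuple[str, bool]:
    """Classify one operation: kind and whether its intrinsic translation is nonzero.

    Kinds: 'identity', 'inversion', 'rotation' (proper, non-identity),
    'mirror' (improper order-2 plane), 'rotoinversion' (other improper).
    """
    r = op.cartesian_rotation(lattice)
    det = float(np.linalg.det(r))
    tr = float(np.trace(r))
    # intrinsic translation: average of W^j w over the rotational order
    w_mat, trans = op.W, op.w
    order = 1
    acc = np.eye(3, dtype=int)
    for _ in range(6):
        acc = w_mat @ acc
        if np.array_equal(acc, np.eye(3, dtype=int)):
            break
        order += 1
    t_int = np.zeros(3)
    wk = np.eye(3, dtype=int)
    for _ in range(order):
        t_int += wk @ trans
        wk = w_mat @ wk
    t_int /= order
    t_int -= np.round(t_int)
    has_intrinsic = bool(np.linalg.norm(t_int @ lattice) > 1e-4)

    if det > 0:
        kind = "identity" if tr > 2.99 else "rotation"
    else:
        if tr < -2.99:
            kind = "inversion"
        elif abs(tr - 1.0) < 1e-2:
            kind = "mirror"
        else:
            kind = "rotoinversion"
    return kind, has_intrinsic


def _name_group(ops: list[SymmetryOp], lattice: np.ndarray) -> str:
    sigs = [op_signature(op, lattice) for op in ops]
    kinds = sorted(k for k, _ in sigs)
    n = len(ops)
    if n == 1:
        return "P1"
    if n == 2:
        kind, intrinsic = next((k, i) for k, i in sigs if k != "identity")
        if kind == "inversion":
            return "P-1"
        if kind == "mirror":
            return "Pc" if intrinsic else "Pm"
        if kind == "rotation":
            return "P2_1" if intrinsic else "P2"
    if n == 4:
        if kinds == ["identity", "inversion", "mirror", "rotation"]:
            rot_intr = next(i for (k, i) in sigs if k == "rotation")
            mir_intr = next(i for (k, i) in sigs if k == "mirror")
            if rot_intr and mir_intr:
                return "P2_1/c"
            return "order-4 group (C2h class)"
        if kinds == ["identity", "mirror", "mirror", "rotation"]:
            mir_intr = [i for (k, i) in sigs if k == "mirror"]
            rot_intr = next(i for (k, i) in sigs if k == "rotation")
            if rot_intr and all(mir_intr):
                return "Pna2_1"
            return "order-4 group (C2v class)"
    return f"order-{n} group"


# ---------------------------------------------------------------------------
# Molecule orbits (Z')
# ---------------------------------------------------------------------------

def molecule_orbits(
    structure: CrystalStructure, operations: list[SymmetryOp], tol: float = 0.25
) -> list[list[int]]:
    """Partition molecule labels into symmetry-equivalence orbits.

    Two molecules share an orbit iff some operation maps one onto the other
    atom-by-atom (same species) within ``tol``. Raises
    :class:`InconsistentSymmetryError` when an operation maps a molecule onto
    no molecule.
    """
    labels = structure.molecules
    label_pos = {m: i for i, m in enumerate(labels)}
    parent = list(range(len(labels)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    for op in operations:
        perm = _match_atoms(structure, op.W, op.w, tol)
        if perm is None:
            raise InconsistentSymmetryError(
                f"operation {op.rotation}, {op.translation} does not map the structure "
                f"onto itself within {tol} A"
            )
        for m in labels:
            atoms = np.where(structure.molecule_index == m)[0]
            targets = set(structure.molecule_index[perm[atoms]].tolist())
            if len(targets) != 1:
                raise InconsistentSymmetryError(
                    f"operation maps molecule {m} onto several molecules {sorted(targets)}"
                )
            union(label_pos[m], label_pos[targets.pop()])

    groups: dict[int, list[int]] = {}
    for m in labels:
        groups.setdefault(find(label_pos[m]), []).append(m)
    return sorted(groups.values())


# ---------------------------------------------------------------------------
# CIF I/O (minimal dialect; molecule partition in the atom label)
# ---------------------------------------------------------------------------

def _lattice_from_cell(a: float, b: float, c: float, alpha: float, beta: float, gamma: float) -> np.ndarray:
    al, be, ga = np.radians([alpha, beta, gamma])
    va = np.array([a, 0.0, 0.0])
    vb = np.array([b * np.cos(ga), b * np.sin(ga), 0.0])
    cx = c * np.cos(be)
    cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
    cz = np.sqrt(max(c * c - cx * cx - cy * cy, 0.0))
    return np.vstack([va, vb, [cx, cy, cz]])


def write_cif(structure: CrystalStructure, path: str) -> None:
    """Write the structure as a minimal P 1 CIF.

    The molecule partition is encoded in ``_atom_site_label`` as
    ``<element><atom#>_m<molecule#>``. Cell parameters are emitted with enough
    digits for a 1e-6 angstrom round trip.
    """
    lat = structure.lattice
    a, b, c = np.linalg.norm(lat, axis=1)
    alpha = np.degrees(np.arccos(np.dot(lat[1], lat[2]) / (b * c)))
    beta = np.degrees(np.arccos(np.dot(lat[0], lat[2]) / (a * c)))
    gamma = np.degrees(np.arccos(np.dot(lat[0], lat[1]) / (a * b)))
    lines = [
        "data_phonoraman",
        f"_cell_length_a    {a:.10f}",
        f"_cell_length_b    {b:.10f}",
        f"_cell_length_c    {c:.10f}",
        f"_cell_angle_alpha {alpha:.10f}",
        f"_cell_angle_beta  {beta:.10f}",
        f"_cell_angle_gamma {gamma:.10f}",
        "_symmetry_space_group_name_H-M 'P 1'",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for i, (sp, f, m) in enumerate(
        zip(structure.species, structure.frac_coords, structure.molecule_index)
    ):
        lines.append(f"{sp}{i}_m{m} {sp} {f[0]:.10f} {f[1]:.10f} {f[2]:.10f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_cif(path: str) -> CrystalStructure:
    """Read a structure written by :func:`write_cif` (minimal CIF dialect).

    Masses are looked up from the element table. Raises
    :class:`CifParseError` naming the missing/offending item.
    """
    try:
        doc = gemmi.cif.read_file(str(path))
    except (ValueError, RuntimeError) as exc:
        raise CifParseError(f"CIF parse failure in {path}: {exc}") from exc
    block = doc.sole_block()

    def cell_value(tag: str) -> float:
        raw = block.find_value(tag)
        if raw is None:
            raise CifParseError(f"missing required cell item {tag}")
        try:
            return float(raw.split("(")[0])
        except ValueError as exc:
            raise CifParseError(f"non-numeric value for {tag}: {raw!r}") from exc

    lat = _lattice_from_cell(
        cell_value("_cell_length_a"),
        cell_value("_cell_length_b"),
        cell_value("_cell_length_c"),
        cell_value("_cell_angle_alpha"),
        cell_value("_cell_angle_beta"),
        cell_value("_cell_angle_gamma"),
    )
    table = block.find(
        "_atom_site_", ["label", "type_symbol", "fract_x", "fract_y", "fract_z"]
    )
    if len(table) == 0:
        raise CifParseError("no _atom_site_ loop found")
    species, frac, masses, mols = [], [], [], []
    for row_no, row in enumerate(table):
        label, sym = row[0], row[1]
        if "_m" not in label:
            raise CifParseError(
                f"atom label {label!r} (row {row_no}) lacks the _m<molecule> suffix"
            )
        try:
            mols.append(int(label.rsplit("_m", 1)[1]))
            frac.append([float(row[2]), float(row[3]), float(row[4])])
        except ValueError as exc:
            raise CifParseError(f"malformed atom row {row_no}: {list(row)}") from exc
        species.append(sym)
        weight = gemmi.Element(sym).weight
        if not weight or weight <= 0:
            raise CifParseError(f"unknown element symbol {sym!r} (row {row_no})")
        masses.append(weight)
    return CrystalStructure(lat, np.array(frac), species, np.array(masses), np.array(mols))


def cif_roundtrip(structure: CrystalStructure, path: str) -> CrystalStructure:
    """Write then re-read a structure; the result equals the input to 1e-6 A."""
    write_cif(structure, path)
    return read_cif(path)
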