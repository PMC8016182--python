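"""Toy molecular-crystal force field with analytic forces and a bond-polarizability model.

The potential is a desk-scale surrogate for a dispersion-corrected DFT energy
surface.  It contains harmonic bonds and angles, a quartic torsional double
well per rotor,

    V(phi) = h * (phi^2 - phi0^2)^2 / phi0^4,

(minima at +-phi0, barrier h at phi = 0), optional harmonic couplings between
torsion coordinates of different molecules (the crystal-field term that lifts
the degeneracy of the four torsional symmetry combinations), and
Lennard-Jones intermolecular interactions with a smooth C2 cutoff, summed
over periodic images by explicit neighbour-cell enumeration.

Internal units: kcal/mol, angstrom, amu, radians.  The frequency conversion
constant is ``nu[cm^-1] = 108.591 * sqrt(lambda[kcal/mol/A^2/amu])``
(108.591 to six significant figures).

Energy conventions: bonds ``E = k/2 (r - r0)^2``; angles
``E = k/2 (theta - theta0)^2``; torsion couplings
``E = J/2 (s_a phi_a - s_b phi_b)^2``.  Dihedral angles follow the standard
four-atom convention with the IUPAC sign (cis = 0, sign from
``atan2((n1 x n2).b2_hat, n1.n2)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .crystal_core import CrystalStructure
from .errors import ForceFieldError, ParameterError

__all__ = [
    "BondTerm",
    "AngleTerm",
    "TorsionWell",
    "TorsionCoupling",
    "LJPair",
    "ForceFieldSpec",
    "BondPolarizabilitySpec",
    "PolarizableBond",
    "energy",
    "forces",
    "energy_and_forces",
    "hessian",
    "minimize",
    "polarizability",
    "ff_to_toml",
    "ff_from_toml",
]

FREQ_CM1 = 108.591  # cm^-1 per sqrt(kcal/mol/A^2/amu)


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k: float  # kcal/mol/A^2
    r0: float  # A


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int  # apex
    k_atom: int
    k: float  # kcal/mol/rad^2
    theta0: float  # rad


@dataclass(frozen=True)
class TorsionWell:
    i: int
    j: int
    k_atom: int
    l: int
    barrier: float  # kcal/mol
    phi0: float  # rad, in (0, pi/2)


@dataclass(frozen=True)
class TorsionCoupling:
    """Harmonic coupling E = J/2 (s_a phi_a - s_b phi_b)^2 between two torsions."""

    a: int  # index into ForceFieldSpec.torsion_wells
    b: int
    strength: float  # kcal/mol/rad^2
    sign_a: int = 1
    sign_b: int = 1


@dataclass(frozen=True)
class LJPair:
    eps: float  # kcal/mol
    sigma: float  # A


@dataclass
class ForceFieldSpec:
    """Force-field terms; bonded terms must stay within one molecule.

    ``lj`` maps an (alphabetically sorted) species pair to parameters; species
    pairs absent from the table do not interact.  ``lj_cutoff`` is the outer
    cutoff of a quintic-smoothstep switching window of width ``lj_switch_width``.
    """

    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    torsion_wells: list[TorsionWell] = field(default_factory=list)
    torsion_couplings: list[TorsionCoupling] = field(default_factory=list)
    lj: dict[tuple[str, str], LJPair] = field(default_factory=dict)
    lj_cutoff: float = 8.0
    lj_switch_width: float = 1.0

    def validate(self, structure: CrystalStructure) -> None:
        n = structure.n_atoms
        mol = structure.molecule_index

        def check_idx(idx: tuple[int, ...], term: str) -> None:
            for a in idx:
                if not (0 <= a < n):
                    raise ForceFieldError(f"{term} references atom {a} outside 0..{n - 1}")
            if len({mol[a] for a in idx}) != 1:
                raise ForceFieldError(f"{term} {idx} spans more than one molecule")

        for b in self.bonds:
            check_idx((b.i, b.j), "bond")
            if b.k <= 0 or b.r0 <= 0:
                raise ForceFieldError("bond k and r0 must be positive")
        for a in self.angles:
            check_idx((a.i, a.j, a.k_atom), "angle")
            if a.k <= 0:
                raise ForceFieldError("angle k must be positive")
        for t in self.torsion_wells:
            check_idx((t.i, t.j, t.k_atom, t.l), "torsion")
            if t.barrier <= 0 or not (0 < t.phi0 < np.pi / 2):
                raise ForceFieldError("torsion barrier > 0 and phi0 in (0, pi/2) required")
        for c in self.torsion_couplings:
            if not (0 <= c.a < len(self.torsion_wells) and 0 <= c.b < len(self.torsion_wells)):
                raise ForceFieldError("torsion coupling references a missing torsion")
            if c.strength <= 0 or c.sign_a not in (-1, 1) or c.sign_b not in (-1, 1):
                raise ForceFieldError("coupling strength > 0 and signs +-1 required")
        for pair, p in self.lj.items():
            if p.eps <= 0 or p.sigma <= 0:
                raise ForceFieldError(f"LJ parameters for {pair} must be positive")
        if self.lj_cutoff <= 0 or not (0 < self.lj_switch_width < self.lj_cutoff):
            raise ForceFieldError("need 0 < lj_switch_width < lj_cutoff")


# ---------------------------------------------------------------------------
# Geometry helpers (values + analytic Cartesian gradients)
# ---------------------------------------------------------------------------

def _dihedral_and_grad(x0, x1, x2, x3):
    """Dihedral angle (IUPAC sign, cis = 0) and its gradient w.r.t. the 4 atoms."""
    b1 = x1 - x0
    b2 = x2 - x1
    b3 = x3 - x2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    phi = np.arctan2(np.dot(np.cross(n1, n2), b2) / nb2, np.dot(n1, n2))
    sq1 = np.dot(n1, n1)
    sq2 = np.dot(n2, n2)
    g0 = -(nb2 / sq1) * n1
    g3 = (nb2 / sq2) * n2
    f12 = np.dot(b1, b2) / (nb2 * nb2)
    f32 = np.dot(b3, b2) / (nb2 * nb2)
    g1 = -(1.0 + f12) * g0 + f32 * g3
    g2 = f12 * g0 - (1.0 + f32) * g3
    return phi, (g0, g1, g2, g3)


def _switch(r: np.ndarray, r_on: float, r_off: float):
    """Quintic smoothstep from 1 at r<=r_on to 0 at r>=r_off; value and derivative."""
    t = np.clip((r - r_on) / (r_off - r_on), 0.0, 1.0)
    s = 1.0 - t**3 * (10.0 - 15.0 * t + 6.0 * t * t)
    ds = -(30.0 * t * t - 60.0 * t**3 + 30.0 * t**4) / (r_off - r_on)
    return s, ds


def _min_image_vec(structure: CrystalStructure, i: int, j: int) -> np.ndarray:
    d = structure.frac_coords[j] - structure.frac_coords[i]
    d -= np.round(d)
    return d @ structure.lattice


def _torsion_phis_grads(structure: CrystalStructure, ff: ForceFieldSpec, cart: np.ndarray):
    """Dihedral values and sparse gradients for every torsion term.

    Intramolecular geometry is reconstructed through minimum-image chaining so
    molecules straddling the cell boundary are handled.
    """
    out = []
    for t in ff.torsion_wells:
        xi = cart[t.i]
        xj = xi + _min_image_vec(structure, t.i, t.j)
        xk = xj + _min_image_vec(structure, t.j, t.k_atom)
        xl = xk + _min_image_vec(structure, t.k_atom, t.l)
        phi, grads = _dihedral_and_grad(xi, xj, xk, xl)
        out.append((phi, (t.i, t.j, t.k_atom, t.l), grads))
    return out


def _lj_image_offsets(structure: CrystalStructure, cutoff: float) -> np.ndarray:
    """Half-space of neighbour-cell offsets covering the cutoff (origin excluded)."""
    lat = structure.lattice
    vol = abs(np.linalg.det(lat))
    nmax = []
    for i in range(3):
        cross = np.cross(lat[(i + 1) % 3], lat[(i + 2) % 3])
        d_perp = vol / np.linalg.norm(cross)
        nmax.append(int(np.ceil(cutoff / d_perp)))
    offsets = []
    for n in np.ndindex(2 * nmax[0] + 1, 2 * nmax[1] + 1, 2 * nmax[2] + 1):
        off = np.array(n) - nmax
        if tuple(off) > (0, 0, 0):
            offsets.append(off)
    return np.array(offsets, dtype=float) if offsets else np.zeros((0, 3))


def energy_and_forces(
    structure: CrystalStructure, ff: ForceFieldSpec
) -> tuple[float, np.ndarray]:
    """Total energy (kcal/mol per cell) and Cartesian forces (kcal/mol/A)."""
    ff.validate(structure)
    cart = structure.cart_coords
    n = structure.n_atoms
    e = 0.0
    grad = np.zeros((n, 3))

    for b in ff.bonds:
        d = _min_image_vec(structure, b.i, b.j)
        r = np.linalg.norm(d)
        e += 0.5 * b.k * (r - b.r0) ** 2
        g = b.k * (r - b.r0) * d / r
        grad[b.j] += g
        grad[b.i] -= g

    for a in ff.angles:
        u = _min_image_vec(structure, a.j, a.i)
        v = _min_image_vec(structure, a.j, a.k_atom)
        nu_, nv = np.linalg.norm(u), np.linalg.norm(v)
        cos_t = np.clip(np.dot(u, v) / (nu_ * nv), -1.0, 1.0)
        theta = np.arccos(cos_t)
        e += 0.5 * a.k * (theta - a.theta0) ** 2
        sin_t = max(np.sqrt(1.0 - cos_t * cos_t), 1e-10)
        dcos_du = v / (nu_ * nv) - cos_t * u / (nu_ * nu_)
        dcos_dv = u / (nu_ * nv) - cos_t * v / (nv * nv)
        pref = -a.k * (theta - a.theta0) / sin_t
        grad[a.i] += pref * dcos_du
        grad[a.k_atom] += pref * dcos_dv
        grad[a.j] -= pref * (dcos_du + dcos_dv)

    if ff.torsion_wells:
        phis = _torsion_phis_grads(structure, ff, cart)
        phi_vals = np.array([p for p, _, _ in phis])
        # per-rotor quartic double wells
        dV = np.zeros(len(phis))
        for m, t in enumerate(ff.torsion_wells):
            p = phi_vals[m]
            e += t.barrier * (p * p - t.phi0**2) ** 2 / t.phi0**4
            dV[m] += 4.0 * t.barrier * p * (p * p - t.phi0**2) / t.phi0**4
        for c in ff.torsion_couplings:
            diff = c.sign_a * phi_vals[c.a] - c.sign_b * phi_vals[c.b]
            e += 0.5 * c.strength * diff * diff
            dV[c.a] += c.strength * diff * c.sign_a
            dV[c.b] -= c.strength * diff * c.sign_b
        for m, (_, idx, grads) in enumerate(phis):
            for atom, g in zip(idx, grads):
                grad[atom] += dV[m] * g

    if ff.lj:
        species = structure.species
        eps = np.zeros((n, n))
        sig = np.zeros((n, n))
        has = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                key = tuple(sorted((species[i], species[j])))
                p = ff.lj.get(key)
                if p is not None:
                    eps[i, j], sig[i, j], has[i, j] = p.eps, p.sigma, True
        mol = structure.molecule_index
        r_off = ff.lj_cutoff
        r_on = r_off - ff.lj_switch_width

        def accumulate(dvec, ii, jj):
            nonlocal e
            r = np.linalg.norm(dvec, axis=1)
            keep = (r < r_off) & (r > 1e-8)
            if not np.any(keep):
                return
            dvec, r, ii, jj = dvec[keep], r[keep], ii[keep], jj[keep]
            ee, ss = eps[ii, jj], sig[ii, jj]
            sr6 = (ss / r) ** 6
            v = 4.0 * ee * (sr6 * sr6 - sr6)
            dv = 4.0 * ee * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
            s, ds = _switch(r, r_on, r_off)
            e += float(np.sum(s * v))
            coef = (s * dv + ds * v) / r  # dE/dr / r
            gvec = coef[:, None] * dvec
            np.add.at(grad, jj, gvec)
            np.add.at(grad, ii, -gvec)

        # home cell: unordered pairs, different molecules, pair in table
        iu, ju = np.triu_indices(n, k=1)
        mask = has[iu, ju] & (mol[iu] != mol[ju])
        iu, ju = iu[mask], ju[mask]
        d = structure.frac_coords[ju] - structure.frac_coords[iu]
        d -= np.round(d)
        accumulate(d @ structure.lattice, iu, ju)

        # periodic images: ordered pairs over half the offsets (each pair once)
        offsets = _lj_image_offsets(structure, r_off)
        if len(offsets):
            ia, ja = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
            ia, ja = ia.ravel(), ja.ravel()
            pmask = has[ia, ja]
            ia, ja = ia[pmask], ja[pmask]
            base = structure.frac_coords[ja] - structure.frac_coords[ia]
            base -= np.round(base)  # offsets are relative to the minimum image
            for off in offsets:
                accumulate((base + off) @ structure.lattice, ia, ja)

    return float(e), -grad


def energy(structure: CrystalStructure, ff: ForceFieldSpec) -> float:
    return energy_and_forces(structure, ff)[0]


def forces(structure: CrystalStructure, ff: ForceFieldSpec) -> np.ndarray:
    return energy_and_forces(structure, ff)[1]


def hessian(
    structure: CrystalStructure,
    ff: ForceFieldSpec,
    fd_step: float = 0.005,
    acoustic_sum_rule: bool = True,
    warn_force: float = 1e-3,
) -> np.ndarray:
    """3N x 3N Hessian (kcal/mol/A^2) by central finite differences of analytic forces.

    The result is symmetrized; with ``acoustic_sum_rule`` the self blocks are
    adjusted so every 3x3 row block sums to zero (uniform translations map to
    exactly zero).
    """
    if fd_step <= 0:
        raise ParameterError("fd_step must be positive")
    f0 = forces(structure, ff)
    if np.max(np.abs(f0)) > warn_force:
        warnings.warn(
            f"hessian evaluated away from a stationary point (max |F| = {np.max(np.abs(f0)):.2e})",
            stacklevel=2,
        )
    n3 = 3 * structure.n_atoms
    cart0 = structure.cart_coords
    h = np.zeros((n3, n3))
    for c in range(n3):
        i, alpha = divmod(c, 3)
        disp = np.zeros_like(cart0)
        disp[i, alpha] = fd_step
        fp = forces(structure.with_cart(cart0 + disp), ff)
        fm = forces(structure.with_cart(cart0 - disp), ff)
        h[:, c] = -((fp - fm) / (2.0 * fd_step)).ravel()
    h = 0.5 * (h + h.T)
    if acoustic_sum_rule:
        # project out the uniform-translation subspace symmetrically: exact
        # zeros for translations while preserving the symmetry of H
        n = structure.n_atoms
        t = np.zeros((n3, 3))
        for alpha in range(3):
            t[alpha::3, alpha] = 1.0
        t /= np.sqrt(n)
        p = np.eye(n3) - t @ t.T
        h = p @ h @ p
        h = 0.5 * (h + h.T)
    return h


def minimize(
    structure: CrystalStructure,
    ff: ForceFieldSpec,
    force_tol: float = 1e-6,
    max_steps: int = 5000,
) -> tuple[CrystalStructure, bool, float]:
    """Cell-constrained quasi-Newton relaxation of the atomic coordinates.

    Lattice vectors are held fixed.  Convergence means the maximum residual
    force component drops below ``force_tol`` (kcal/mol/A).  Returns the
    relaxed structure, a convergence flag, and the final energy.
    """
    if force_tol <= 0:
        raise ParameterError("force_tol must be positive")
    x0 = structure.cart_coords.ravel()

    def fun(x):
        s = structure.with_cart(x.reshape(-1, 3))
        e, f = energy_and_forces(s, ff)
        return e, -f.ravel()

    res = _scipy_minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_steps, "ftol": 1e-16, "gtol": force_tol * 0.3, "maxls": 100},
    )
    relaxed = structure.with_cart(res.x.reshape(-1, 3))
    e, f = energy_and_forces(relaxed, ff)
    # Newton polish for tight tolerances L-BFGS cannot reach: pseudo-inverse
    # steps with the uniform-translation null space projected out.  The
    # Hessian is finite-differenced once and reused; the fixed-Hessian Newton
    # map contracts the residual by the Hessian's relative error per pass.
    if np.max(np.abs(f)) >= force_tol:
        h = hessian(relaxed, ff, warn_force=np.inf)
        evals, evecs = np.linalg.eigh(h)
        keep = np.abs(evals) > 1e-6 * np.max(np.abs(evals))
        basis, inv_ev = evecs[:, keep], 1.0 / evals[keep]
        for _ in range(30):
            fmax = np.max(np.abs(f))
            if fmax < 0.2 * force_tol:
                break
            step = basis @ ((basis.T @ f.ravel()) * inv_ev)
            cart = relaxed.cart_coords
            scale = 1.0
            accepted = False
            for _ in range(10):
                trial = structure.with_cart(cart + scale * step.reshape(-1, 3))
                e_t, f_t = energy_and_forces(trial, ff)
                if np.max(np.abs(f_t)) < fmax:
                    relaxed, e, f = trial, e_t, f_t
                    accepted = True
                    break
                scale *= 0.5
            if not accepted:
                break
    converged = bool(np.max(np.abs(f)) < force_tol)
    return relaxed, converged, e


# ---------------------------------------------------------------------------
# Bond-polarizability model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolarizableBond:
    """One axially symmetric bond contribution to the crystal polarizability.

    ``a_par(r) = a_par0 + a_par_prime * (r - r0)`` along the bond axis and the
    analogous transverse component.
    """

    i: int
    j: int
    a_par0: float  # A^3
    a_perp0: float  # A^3
    a_par_prime: float = 0.0  # A^2
    a_perp_prime: float = 0.0  # A^2
    r0: float = 1.0  # A


@dataclass
class BondPolarizabilitySpec:
    bonds: list[PolarizableBond] = field(default_factory=list)

    def validate(self) -> None:
        if not self.bonds:
            raise ForceFieldError("bond-polarizability spec has an empty bond list")
        for b in self.bonds:
            if b.a_par0 < 0 or b.a_perp0 < 0:
                raise ForceFieldError("baseline polarizabilities must be non-negative")


def polarizability(structure: CrystalStructure, bp: BondPolarizabilitySpec) -> np.ndarray:
    """Crystal polarizability tensor (A^3): sum of axially symmetric bond terms.

    alpha = sum_bonds a_perp(r) I + (a_par(r) - a_perp(r)) b_hat b_hat^T,
    symmetric by construction and invariant under lattice translations of any
    atom (bond vectors use the minimum image).
    """
    bp.validate()
    alpha = np.zeros((3, 3))
    for b in bp.bonds:
        d = _min_image_vec(structure, b.i, b.j)
        r = np.linalg.norm(d)
        bhat = d / r
        a_par = b.a_par0 + b.a_par_prime * (r - b.r0)
        a_perp = b.a_perp0 + b.a_perp_prime * (r - b.r0)
        alpha += a_perp * np.eye(3) + (a_par - a_perp) * np.outer(bhat, bhat)
    return alpha


# ---------------------------------------------------------------------------
# TOML serialization
# ---------------------------------------------------------------------------

def ff_to_toml(ff: ForceFieldSpec) -> str:
    """Serialize a force field as a TOML document (readable by :func:`ff_from_toml`)."""

    def f(x) -> str:  # repr of a plain float round-trips exactly
        return repr(float(x))

    lines = [f"lj_cutoff = {f(ff.lj_cutoff)}", f"lj_switch_width = {f(ff.lj_switch_width)}", ""]
    for b in ff.bonds:
        lines += ["[[bonds]]", f"i = {int(b.i)}", f"j = {int(b.j)}",
                  f"k = {f(b.k)}", f"r0 = {f(b.r0)}", ""]
    for a in ff.angles:
        lines += ["[[angles]]", f"i = {int(a.i)}", f"j = {int(a.j)}",
                  f"k_atom = {int(a.k_atom)}", f"k = {f(a.k)}", f"theta0 = {f(a.theta0)}", ""]
    for t in ff.torsion_wells:
        lines += ["[[torsion_wells]]", f"i = {int(t.i)}", f"j = {int(t.j)}",
                  f"k_atom = {int(t.k_atom)}", f"l = {int(t.l)}",
                  f"barrier = {f(t.barrier)}", f"phi0 = {f(t.phi0)}", ""]
    for c in ff.torsion_couplings:
        lines += ["[[torsion_couplings]]", f"a = {int(c.a)}", f"b = {int(c.b)}",
                  f"strength = {f(c.strength)}",
                  f"sign_a = {int(c.sign_a)}", f"sign_b = {int(c.sign_b)}", ""]
    for (s1, s2), pr in sorted(ff.lj.items()):
        lines += ["[[lj]]", f'species = ["{s1}", "{s2}"]',
                  f"eps = {f(pr.eps)}", f"sigma = {f(pr.sigma)}", ""]
    return "\n".join(lines)


def ff_from_toml(text: str) -> ForceFieldSpec:
    import tomllib

    data = tomllib.loads(text)
    return ForceFieldSpec(
        bonds=[BondTerm(**b) for b in data.get("bonds", [])],
        angles=[AngleTerm(**a) for a in data.get("angles", [])],
        torsion_wells=[TorsionWell(**t) for t in data.get("torsion_wells", [])],
        torsion_couplings=[TorsionCoupling(**c) for c in data.get("torsion_couplings", [])],
        lj={
            tuple(sorted(e["species"])): LJPair(e["eps"], e["sigma"])
            for e in data.get("lj", [])
        },
        lj_cutoff=data.get("lj_cutoff", 8.0),
        lj_switch_width=data.get("lj_switch_width", 1.0),
    )
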