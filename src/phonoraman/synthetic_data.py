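"""Seeded generators for every fixture the pipeline needs.

Two toy "T-rotor" molecular crystals emulate the topology of a stable
orthorhombic polymorph and of a metastable monoclinic polymorph whose
high-symmetry configuration is a saddle point:

* ``make_form1_scenario``: four identical molecules in a polar orthorhombic
  cell (Pna2_1-type operations, C2v factor group, Z = 4, Z' = 1), every rotor
  sitting in a torsional well — a genuine minimum.
* ``make_saddle_scenario``: four identical molecules in a monoclinic cell
  (P2_1/c operations, C2h factor group).  Each molecule carries one rotor
  atom on a quartic torsional double well; at rotor angle 0 the crystal is
  centrosymmetric and sits on a first-order saddle whose single unstable mode
  is the Bu combination of the four torsions.  Distorting along it preserves
  only the glide plane and reaches one of two Pc minima (Z' = 2).

The T-rotor molecule (3-atom trunk + 1 rotor atom, 16 atoms / 48 Cartesian
coordinates per cell) is the smallest object with a torsional internal
coordinate that can mimic a hindered aromatic-group rotation while keeping
every pipeline stage interactive.  A group-invariant harmonic coupling
between the four torsion coordinates (the crystal-field term) stabilizes the
Ag, Au and Bg torsion combinations and leaves exactly the Bu combination
unstable; its two coupling constants are unequal so no two torsional modes
are accidentally degenerate.

The rotor geometry is calibrated so the saddle-to-minimum distortion moves
the rotor atom by about 0.1 A at the default 8 degree well position: below
the conventional 0.25 A symmetry-detection tolerance (at which the child is
mistaken for its centrosymmetric parent) and far above a tight 0.02 A one.

All generators are deterministic per seed (identical seeds give identical
bytes); the declared ground truths in ``ScenarioBundle.expected`` are
re-verified by running the real pipeline in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .crystal_core import CrystalStructure, SymmetryOp
from .errors import ParameterError
from .model_potential import (
    AngleTerm,
    BondPolarizabilitySpec,
    BondTerm,
    ForceFieldSpec,
    LJPair,
    PolarizableBond,
    TorsionCoupling,
    TorsionWell,
    energy_and_forces,
)
from .phase_map import MapGrid, WindowConfig
from .raman import Spectrum

__all__ = [
    "ScenarioBundle",
    "MapScenario",
    "make_saddle_scenario",
    "make_form1_scenario",
    "make_map_scenario",
    "random_symmetric_tensor",
    "perturb_structure",
]


@dataclass
class ScenarioBundle:
    """A structure + force field + polarizability model with declared ground truth."""

    name: str
    structure: CrystalStructure
    ff: ForceFieldSpec
    bp: BondPolarizabilitySpec
    ops: list[SymmetryOp]
    expected: dict = field(default_factory=dict)
    seed: int = 0

    def polarizability_fn(self):
        from .model_potential import polarizability

        return lambda s: polarizability(s, self.bp)


# ---------------------------------------------------------------------------
# T-rotor molecule
# ---------------------------------------------------------------------------

# trunk: A(C) - B(C) - C(N); rotor: D(F), placed by bond/angle/dihedral.
_R_AB = 1.40
_R_BC = 1.45
_R_CD = 0.95
_ANGLE_ABC = np.radians(112.0)
_ANGLE_BCD = np.radians(131.0)
_SPECIES = ["C", "C", "N", "F"]


def _molecule_cart(phi: float) -> np.ndarray:
    """Local Cartesian coordinates of one T-rotor with dihedral A-B-C-D = phi."""
    a = np.array([_R_AB * np.cos(_ANGLE_ABC), _R_AB * np.sin(_ANGLE_ABC), 0.0])
    b = np.zeros(3)
    c = np.array([_R_BC, 0.0, 0.0])
    # place D from bond length, angle at C, dihedral about B->C
    bc = (c - b) / np.linalg.norm(c - b)
    # in-plane unit vector perpendicular to bc, pointing away from A
    perp = np.array([0.0, 1.0, 0.0])
    perp -= np.dot(perp, bc) * bc
    perp /= np.linalg.norm(perp)
    # dihedral phi rotates the perpendicular component about the B-C axis;
    # phi = 0 puts D cis to A (same side), matching the IUPAC convention
    off = np.sin(_ANGLE_BCD) * (np.cos(phi) * perp + np.sin(phi) * np.cross(bc, perp))
    d = c + _R_CD * (-np.cos(_ANGLE_BCD) * bc + off)
    return np.vstack([a, b, c, d])


def _euler_rotation(ax: float, ay: float, az: float) -> np.ndarray:
    """Fixed generic rotation (radians) so the molecule avoids the symmetry axes."""
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _masses() -> np.ndarray:
    return np.array([gemmi.Element(s).weight for s in _SPECIES])


def _build_crystal(
    lattice: np.ndarray, ops: list[SymmetryOp], mol_cart: np.ndarray, center_frac: np.ndarray
) -> CrystalStructure:
    """Place one molecule at a general position and replicate it with the ops."""
    inv_lat = np.linalg.inv(lattice)
    center_cart = center_frac @ lattice
    frac_mol = (mol_cart - mol_cart.mean(axis=0) + center_cart) @ inv_lat
    frac_all, species, masses, mols = [], [], [], []
    base_masses = _masses()
    for m, op in enumerate(ops):
        frac_all.append(op.apply(frac_mol))
        species += _SPECIES
        masses += base_masses.tolist()
        mols += [m] * len(_SPECIES)
    return CrystalStructure(
        lattice, np.vstack(frac_all), species, np.array(masses), np.array(mols)
    )


def _bonded_terms(
    n_mol: int, barrier: float, phi0: float
) -> tuple[list[BondTerm], list[AngleTerm], list[TorsionWell]]:
    bonds, angles, torsions = [], [], []
    for m in range(n_mol):
        o = 4 * m
        bonds += [
            BondTerm(o + 0, o + 1, 420.0, _R_AB),
            BondTerm(o + 1, o + 2, 380.0, _R_BC),
            BondTerm(o + 2, o + 3, 350.0, _R_CD),
        ]
        angles += [
            AngleTerm(o + 0, o + 1, o + 2, 85.0, _ANGLE_ABC),
            AngleTerm(o + 1, o + 2, o + 3, 70.0, _ANGLE_BCD),
        ]
        torsions.append(TorsionWell(o + 0, o + 1, o + 2, o + 3, barrier, phi0))
    return bonds, angles, torsions


_LJ_TABLE = {
    ("C", "C"): LJPair(0.35, 3.75),
    ("C", "N"): LJPair(0.32, 3.65),
    ("N", "N"): LJPair(0.30, 3.55),
}
# The rotor species F carries no LJ terms: rotor motion then changes only the
# torsional energy, so the saddle-to-minimum energy drop per molecule equals
# the well barrier exactly.

# The metastable (saddle) polymorph packs more stiffly: its LJ wells are
# deepened by this factor, shifting its lattice-phonon bands up so the two
# forms carry well-separated spectral fingerprints (the situation window-based
# phase mapping presumes).
_LJ_SCALE_SADDLE = 2.0


def _lj_for(scale: float) -> dict:
    return {k: LJPair(v.eps * scale, v.sigma) for k, v in _LJ_TABLE.items()}

_BP_SPEC_PER_MOL = [
    # (i_off, j_off, a_par0, a_perp0, a_par', a_perp', r0)
    (0, 1, 2.2, 1.0, 1.1, 0.3, _R_AB),
    (1, 2, 1.9, 0.9, 0.9, 0.25, _R_BC),
    (2, 3, 1.4, 0.6, 0.7, 0.2, _R_CD),
]


def _bp_for(n_mol: int) -> BondPolarizabilitySpec:
    bonds = []
    for m in range(n_mol):
        o = 4 * m
        for i, j, ap, at, app, atp, r0 in _BP_SPEC_PER_MOL:
            bonds.append(PolarizableBond(o + i, o + j, ap, at, app, atp, r0))
    return BondPolarizabilitySpec(bonds)


# ---------------------------------------------------------------------------
# Symmetry-constrained relaxation of the asymmetric unit
# ---------------------------------------------------------------------------

def _relax_asymmetric_unit(
    structure: CrystalStructure,
    ff: ForceFieldSpec,
    ops: list[SymmetryOp],
    gtol: float = 1e-11,
) -> CrystalStructure:
    """Relax molecule 0 while regenerating the cell with the ops each step.

    At a configuration with the full group symmetry the gradient is itself
    group-invariant, so a vanishing symmetric-subspace gradient implies a
    vanishing full gradient: the relaxed structure is an exact stationary
    point of the unconstrained energy.
    """
    n_unit = len(_SPECIES)
    lat = structure.lattice
    inv_lat = np.linalg.inv(lat)
    frac0 = structure.frac_coords[:n_unit].copy()
    rots = [op.cartesian_rotation(lat) for op in ops]

    def rebuild(p: np.ndarray) -> CrystalStructure:
        f0 = (frac0 @ lat + p.reshape(n_unit, 3)) @ inv_lat
        frac_all = np.vstack([op.apply(f0) for op in ops])
        return structure.with_frac(frac_all)

    def fun(p: np.ndarray):
        s = rebuild(p)
        e, f = energy_and_forces(s, ff)
        g = np.zeros((n_unit, 3))
        for m, r in enumerate(rots):
            g -= f[m * n_unit : (m + 1) * n_unit] @ r  # chain rule: dx_img = R dx_0
        return e, g.ravel()

    res = _scipy_minimize(
        fun,
        np.zeros(3 * n_unit),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-18, "gtol": 1e-9, "maxls": 200},
    )
    # Newton polish on the reduced coordinates (FD Hessian of the reduced
    # gradient) to drive the stationarity residual to machine level
    p = res.x
    npar = len(p)
    for _ in range(12):
        _, g = fun(p)
        gmax = np.max(np.abs(g))
        if gmax < gtol:
            break
        h = np.zeros((npar, npar))
        step = 1e-5
        for c in range(npar):
            dp = np.zeros(npar)
            dp[c] = step
            h[:, c] = (fun(p + dp)[1] - fun(p - dp)[1]) / (2 * step)
        h = 0.5 * (h + h.T)
        dp = np.linalg.solve(h + 1e-10 * np.eye(npar), g)
        scale = 1.0
        for _ in range(12):  # backtrack on the gradient norm
            if np.max(np.abs(fun(p - scale * dp)[1])) < gmax:
                break
            scale *= 0.5
        p = p - scale * dp
    return rebuild(p)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def _p21c_ops() -> list[SymmetryOp]:
    e = SymmetryOp.from_arrays(np.eye(3), [0, 0, 0])
    screw = SymmetryOp.from_arrays(np.diag([-1, 1, -1]), [0, 0.5, 0.5])
    inv = SymmetryOp.from_arrays(-np.eye(3), [0, 0, 0])
    glide = SymmetryOp.from_arrays(np.diag([1, -1, 1]), [0, 0.5, 0.5])
    return [e, screw, inv, glide]


def _pna21_ops() -> list[SymmetryOp]:
    e = SymmetryOp.from_arrays(np.eye(3), [0, 0, 0])
    screw = SymmetryOp.from_arrays(np.diag([-1, -1, 1]), [0, 0, 0.5])
    a_glide = SymmetryOp.from_arrays(np.diag([1, -1, 1]), [0.5, 0.5, 0])
    n_glide = SymmetryOp.from_arrays(np.diag([-1, 1, 1]), [0.5, 0.5, 0.5])
    return [e, screw, a_glide, n_glide]


def make_saddle_scenario(
    distortion_deg: float = 8.0, barrier: float = 0.5, seed: int = 0
) -> ScenarioBundle:
    """Monoclinic 4-molecule crystal: P2_1/c saddle with one imaginary Bu mode.

    ``distortion_deg`` is the torsional well position phi0; ``barrier`` the
    well depth h (kcal/mol) relieved per molecule on descending to a Pc
    minimum.  The returned structure is the relaxed saddle.
    """
    if not (0 < distortion_deg < 20):
        raise ParameterError("distortion_deg must lie in (0, 20)")
    if barrier <= 0:
        raise ParameterError("barrier must be positive")
    phi0 = np.radians(distortion_deg)
    # cell, molecular orientation and site calibrated once so that the packing
    # is a genuine minimum along every coordinate except the Bu torsion combo
    beta = np.radians(98.8)
    a_len, b_len, c_len = 8.25, 8.29, 10.73
    lattice = np.array(
        [
            [a_len, 0.0, 0.0],
            [0.0, b_len, 0.0],
            [c_len * np.cos(beta), 0.0, c_len * np.sin(beta)],
        ]
    )
    ops = _p21c_ops()
    mol = _molecule_cart(0.0) @ _euler_rotation(0.622, 1.427, 2.357).T
    structure = _build_crystal(lattice, ops, mol, np.array([0.227, 0.188, 0.252]))

    bonds, angles, torsions = _bonded_terms(4, barrier, phi0)
    # Bu sign pattern over (identity, screw, inversion, glide) images:
    signs = [1, -1, 1, -1]
    j1, j2 = 150.0, 220.0
    couplings = [
        TorsionCoupling(0, 1, j1, signs[0], signs[1]),
        TorsionCoupling(2, 3, j1, signs[2], signs[3]),
        TorsionCoupling(1, 2, j2, signs[1], signs[2]),
        TorsionCoupling(3, 0, j2, signs[3], signs[0]),
    ]
    ff = ForceFieldSpec(
        bonds=bonds,
        angles=angles,
        torsion_wells=torsions,
        torsion_couplings=couplings,
        lj=_lj_for(_LJ_SCALE_SADDLE),
        lj_cutoff=8.0,
    )
    structure = _relax_asymmetric_unit(structure, ff, ops)
    return ScenarioBundle(
        name="saddle",
        structure=structure,
        ff=ff,
        bp=_bp_for(4),
        ops=ops,
        expected={
            "saddle_group": "P2_1/c",
            "child_group_tight": "Pc",
            "child_group_loose": "P2_1/c",
            "n_imaginary": 1,
            "unstable_irrep": "Bu",
            "z_count": 4,
            "z_prime_child": 2,
            "delta_e_per_molecule": barrier,
            "factor_group": "C2h",
        },
        seed=seed,
    )


def make_form1_scenario(seed: int = 0) -> ScenarioBundle:
    """Orthorhombic 4-molecule crystal (Pna2_1-type ops): a genuine minimum, Z' = 1."""
    phi0 = np.radians(14.0)
    # cell, orientation and site calibrated once for a clean all-real spectrum
    lattice = np.diag([8.15, 10.91, 9.16])
    ops = _pna21_ops()
    mol = _molecule_cart(phi0) @ _euler_rotation(0.642, 1.740, 1.519).T
    structure = _build_crystal(lattice, ops, mol, np.array([0.138, 0.198, 0.109]))
    bonds, angles, torsions = _bonded_terms(4, 0.4, phi0)
    ff = ForceFieldSpec(
        bonds=bonds,
        angles=angles,
        torsion_wells=torsions,
        lj=dict(_LJ_TABLE),
        lj_cutoff=8.0,
    )
    structure = _relax_asymmetric_unit(structure, ff, ops)
    return ScenarioBundle(
        name="form1",
        structure=structure,
        ff=ff,
        bp=_bp_for(4),
        ops=ops,
        expected={
            "group": "Pna2_1",
            "z_count": 4,
            "z_prime": 1,
            "n_imaginary": 0,
            "factor_group": "C2v",
            "irrep_labels": {"A1", "A2", "B1", "B2"},
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Map scenario
# ---------------------------------------------------------------------------

@dataclass
class MapScenario:
    grid: MapGrid
    truth: np.ndarray  # fraction_II per point, nan for substrate-only spots
    window_cfg: WindowConfig  # windows chosen on the pure spectra, references set
    spectrum_I: Spectrum
    spectrum_II: Spectrum


_STAR_PEAKS = ((84.0, 2.0), (128.0, 2.5))  # substrate peak positions / half-widths


def _substrate(grid: np.ndarray, scale: float) -> np.ndarray:
    """Glass-like background: one very broad band, a gentle slope, two narrow
    peaks, and a constant offset (so noisy counts stay positive).  The band is
    wide enough that a linear endpoint baseline over a few cm^-1 removes it
    almost completely, as for a real glass boson peak."""
    broad = 0.25 / (1.0 + ((grid - 16.0) / 80.0) ** 2)
    slope = 0.35 - 0.0012 * grid
    stars = sum(0.5 * hw**2 / ((grid - pos) ** 2 + hw**2) for pos, hw in _STAR_PEAKS)
    return scale * (broad + slope + stars + 0.3)


def _pure_spectra(config_grid=(10.0, 150.0, 0.5)):
    """Powder spectra of the two scenarios (cached: the bundles are deterministic)."""
    global _PURE_CACHE
    try:
        return _PURE_CACHE
    except NameError:
        pass
    from .lattice_dynamics import hessian_modes
    from .model_potential import hessian
    from .raman import SpectrumConfig, mode_raman_tensors, mode_spectrum
    from .saddle_escape import follow_imaginary_mode

    cfg = SpectrumConfig(grid_start=config_grid[0], grid_stop=config_grid[1], grid_step=config_grid[2])

    b1 = make_form1_scenario()
    m1 = hessian_modes(hessian(b1.structure, b1.ff, warn_force=np.inf), b1.structure.masses)
    s_i = mode_spectrum(
        mode_raman_tensors(b1.structure, m1, b1.polarizability_fn()), cfg, "powder"
    )

    b2 = make_saddle_scenario()
    m2 = hessian_modes(hessian(b2.structure, b2.ff, warn_force=np.inf), b2.structure.masses)
    esc = follow_imaginary_mode(b2.structure, b2.ff, m2)
    child = esc.structure_plus
    mc = hessian_modes(hessian(child, b2.ff, warn_force=np.inf), child.masses)
    s_ii = mode_spectrum(mode_raman_tensors(child, mc, b2.polarizability_fn()), cfg, "powder")

    # normalize both to unit peak so mixing coefficients are comparable
    s_i = Spectrum(s_i.wavenumber, s_i.intensity / s_i.intensity.max())
    s_ii = Spectrum(s_ii.wavenumber, s_ii.intensity / s_ii.intensity.max())
    _PURE_CACHE = (s_i, s_ii)
    return _PURE_CACHE


def _pick_windows(
    s_i: Spectrum, s_ii: Spectrum, width: float = 6.0, substrate: Spectrum | None = None
) -> WindowConfig:
    """Choose the most phase-diagnostic windows of fixed width on the pure spectra.

    The window pair is chosen to minimize the worst-case mixing bias of the
    two-window ratio estimator, computed analytically from the pure spectra:
    with normalized cross-talk x_I (phase II leaking into window I) and x_II,
    a noiseless mixture of true fraction f estimates

        est(f) = w_II / (w_I + w_II),
        w_I = max((1 - f) + f x_I, 0),  w_II = max(f + (1 - f) x_II, 0),

    and the picker minimizes max_f |est(f) - f| over candidate window pairs
    (fixed width, substrate star positions avoided, own-phase area at least a
    quarter of the best available so the references stay strong enough for
    the no-signal rule).  This mirrors choosing the most phase-diagnostic
    shaded windows on measured pure-phase spectra.
    """
    from .phase_map import signed_window_integral

    wn = s_i.wavenumber
    centers = np.arange(wn[0] + width, wn[-1] - width, 0.25)
    centers = np.array(
        [c for c in centers if all(abs(c - pos) > width / 2 + 4.0 for pos, _ in _STAR_PEAKS)]
    )
    area_i = np.array(
        [signed_window_integral(s_i, (c - width / 2, c + width / 2)) for c in centers]
    )
    area_ii = np.array(
        [signed_window_integral(s_ii, (c - width / 2, c + width / 2)) for c in centers]
    )
    # avoid windows where the bare substrate shows residual structure above
    # half the no-signal threshold (as one would, looking at glass-only spectra)
    if substrate is not None:
        area_sub = np.array(
            [signed_window_integral(substrate, (c - width / 2, c + width / 2)) for c in centers]
        )
        clean_i = np.abs(area_sub) < 0.005 * np.maximum(area_i, 1e-12)
        clean_ii = np.abs(area_sub) < 0.005 * np.maximum(area_ii, 1e-12)
    else:
        clean_i = clean_ii = np.ones(len(centers), dtype=bool)
    f_grid = np.linspace(0.0, 1.0, 21)

    if substrate is not None:
        sub_lead_i = area_sub / np.maximum(area_i, 1e-12)
        sub_lead_ii = area_sub / np.maximum(area_ii, 1e-12)
    else:
        sub_lead_i = sub_lead_ii = np.zeros(len(centers))

    def search(floor: float, use_clean: bool):
        ok_i = (area_i >= floor * area_i.max()) & (clean_i | (not use_clean))
        ok_ii = (area_ii >= floor * area_ii.max()) & (clean_ii | (not use_clean))
        best = None
        for a in np.where(ok_i)[0]:
            x_i = area_ii[a] / area_i[a]  # phase II leaking into window I
            for b in np.where(ok_ii)[0]:
                if abs(centers[a] - centers[b]) < width + 0.5:
                    continue
                x_ii = area_i[b] / area_ii[b]
                # noiseless-mixture bias model, substrate leakage included
                w_i = np.maximum((1 - f_grid) + f_grid * x_i + sub_lead_i[a], 0.0)
                w_ii = np.maximum(f_grid + (1 - f_grid) * x_ii + sub_lead_ii[b], 0.0)
                est = np.where(w_i + w_ii > 0, w_ii / np.maximum(w_i + w_ii, 1e-300), 0.5)
                bias = float(np.max(np.abs(est - f_grid)))
                if best is None or bias < best[0]:
                    best = (bias, centers[a], centers[b])
        return best

    best = search(0.15, True) or search(0.05, True) or search(0.05, False)
    if best is None:
        raise ParameterError("no usable phase-diagnostic window pair found")
    _, ca, cb = best
    cfg = WindowConfig(
        window_I=(float(ca - width / 2), float(ca + width / 2)),
        window_II=(float(cb - width / 2), float(cb + width / 2)),
        baseline="linear",
    )
    return cfg.with_references(s_i, s_ii)


def make_map_scenario(
    nx: int = 10,
    ny: int = 10,
    field_kind: str = "smooth",
    snr: float = 300.0,
    seed: int = 0,
    n_substrate_points: int = 0,
) -> MapScenario:
    """Noisy two-phase map over a glass-like background, with known truth field.

    Per point: ``spectrum = f * S_II + (1 - f) * S_I + substrate + noise``,
    Gaussian noise with sigma = (pure-phase peak) / snr.  The default SNR of
    300 emulates a good confocal map on a strongly scattering crystalline
    film (visible noise, but quantification-grade statistics — the regime the
    1% no-signal threshold presumes).  ``field_kind`` is "smooth" (sinusoidal
    composition field) or "blocks" (random patches); the first
    ``n_substrate_points`` grid points carry substrate only (truth nan there).
    """
    if nx < 2 or ny < 2:
        raise ParameterError("nx, ny must be >= 2")
    if snr <= 0:
        raise ParameterError("snr must be positive")
    s_i, s_ii = _pure_spectra()
    cfg = _pick_windows(
        s_i, s_ii, substrate=Spectrum(s_i.wavenumber, _substrate(s_i.wavenumber, 1.0))
    )
    rng = np.random.default_rng(seed)
    grid_wn = s_i.wavenumber

    xs = np.arange(nx) * 5.0  # 5 um grid pitch
    ys = np.arange(ny) * 5.0
    if field_kind == "smooth":
        gx, gy = np.meshgrid(np.linspace(0, 1, nx), np.linspace(0, 1, ny), indexing="ij")
        truth2d = 0.5 * (1.0 + np.sin(2.2 * np.pi * gx) * np.cos(1.3 * np.pi * gy))
    elif field_kind == "blocks":
        bx, by = max(nx // 3, 1), max(ny // 3, 1)
        levels = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=((nx + bx - 1) // bx, (ny + by - 1) // by))
        truth2d = np.empty((nx, ny))
        for i in range(nx):
            for j in range(ny):
                truth2d[i, j] = levels[i // bx, j // by]
    else:
        raise ParameterError(f"unknown field_kind {field_kind!r}")

    sigma = 1.0 / snr  # pure spectra are unit-peak normalized
    points, truth = [], []
    k = 0
    for i in range(nx):
        for j in range(ny):
            substrate_only = k < n_substrate_points
            f = float(truth2d[i, j])
            signal = 0.0 if substrate_only else f * s_ii.intensity + (1 - f) * s_i.intensity
            counts = signal + _substrate(grid_wn, 1.0) + rng.normal(0.0, sigma, len(grid_wn))
            counts = np.maximum(counts, 0.0)
            points.append((float(xs[i]), float(ys[j]), Spectrum(grid_wn, counts)))
            truth.append(np.nan if substrate_only else f)
            k += 1
    return MapScenario(MapGrid(points), np.array(truth), cfg, s_i, s_ii)


# ---------------------------------------------------------------------------
# Small fixtures
# ---------------------------------------------------------------------------

def random_symmetric_tensor(seed: int) -> np.ndarray:
    """Symmetrized 3x3 standard-normal tensor; deterministic per seed."""
    rng = np.random.default_rng(seed)
    t = rng.standard_normal((3, 3))
    return 0.5 * (t + t.T)


def perturb_structure(
    structure: CrystalStructure, amplitude: float, seed: int
) -> CrystalStructure:
    """Gaussian Cartesian displacement of every atom (sigma = amplitude)."""
    rng = np.random.default_rng(seed)
    cart = structure.cart_coords + rng.normal(0.0, amplitude, (structure.n_atoms, 3))
    return structure.with_cart(cart)
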