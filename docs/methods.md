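# Methods

This note records the models behind `phonoraman`, the parameter choices that
matter, and what the synthetic scenarios do and do not establish.

## Crystal representation and symmetry detection

A crystal is a fixed cell (rows a, b, c in Å), wrapped fractional
coordinates, species, masses (amu) and an explicit molecule partition. The
partition is always taken from the input — never re-derived by bond
perception — so Z′ statements are free of a hidden heuristic. Symmetry
operations act on fractional column vectors as `f' = Wf + w`.

`detect_symmetry` enumerates the lattice point group (integer matrices with
entries in {−1,0,1} whose Cartesian image is orthogonal — sufficient for the
conventional cells handled here), then searches translations for each
rotation by anchoring one atom of *every* species against all atoms of the
same species. Anchoring on every species matters: if the anchor species
happens to carry the whole distortion (here, the rotor atoms), all candidate
translations misplace the rest of the cell and a genuinely present
pseudo-symmetry is missed. An operation is accepted when it maps every atom
onto a same-species atom within the distance tolerance (minimum-image
Cartesian metric); the translation is then refined by least squares and
snapped to nearby twelfths. The default tolerance is 0.25 Å — the
conventional crystallographic equivalence default — and the package's
deliberate stance on the associated pitfall is to *report* symmetry at both
0.25 Å and 0.02 Å after a descent rather than silently choosing one.

Only the groups arising in the scenarios are named (P1, P-1, P2, P2₁, Pm,
Pc, P2₁/c, Pna2₁); anything else is reported by operation list and order.
Z′ is the number of molecule orbits under the accepted operations; an
operation that maps a molecule onto no molecule raises rather than guesses.

## The surrogate potential

The force field exists to give the pipeline a cheap, exact, differentiable
energy surface with the right *topology*; its numbers model no real
substance. Terms: harmonic bonds `k/2 (r−r₀)²` and angles `k/2 (θ−θ₀)²`
inside molecules; a quartic torsional double well per rotor,
`V(φ) = h (φ²−φ₀²)²/φ₀⁴` (minima ±φ₀, barrier `h` at φ = 0, IUPAC dihedral
sign convention); pairwise harmonic couplings between torsions of different
molecules, `J/2 (s_a φ_a − s_b φ_b)²`; and Lennard-Jones interactions
between molecules with a quintic smoothstep cutoff (default 8 Å, 1 Å
switching width), summed over periodic images relative to the minimum image
so the energy is continuous in the coordinates.

The torsion couplings deserve a word. Four independent double wells would
make the high-symmetry configuration a fourth-order saddle: the four
torsional symmetry combinations (Ag, Bu, Au, Bg in the C2h factor group) all
share the bare curvature −4h/φ₀². The coupling term is constructed to be
invariant under the space group, to vanish identically along the Bu
combination, and to stabilize the other three (two distinct coupling
constants, 150 and 220 kcal/mol/rad², also keep those three modes
non-degenerate). The result is the textbook topology: exactly one unstable
direction, of Bu symmetry. The rotor species carries no Lennard-Jones terms,
so rotor motion changes only torsional energy — which makes the
saddle-to-minimum energy drop per molecule *exactly* the barrier height `h`,
a closed-form anchor the tests assert to 1e-6.

Forces are fully analytic (including the dihedral gradient, verified against
central differences at 1e-6 relative); the Hessian is a central finite
difference of the analytic forces (step 0.005 Å — differencing forces rather
than energies halves the noise), symmetrized, with the acoustic sum rule
imposed by symmetrically projecting out the uniform-translation subspace
(`PHP`), which zeroes translations exactly while preserving symmetry. The
minimizer is L-BFGS-B followed by a fixed-Hessian Newton polish with the
translation null space removed; the default force tolerance is
1e-6 kcal/mol/Å, which bounds the energy error near a quadratic minimum at
~1e-12 — far below every tolerance stated elsewhere in this note.

Internal units are kcal/mol, Å, amu; `ν[cm⁻¹] = 108.591·√λ` with λ in
kcal/mol/Å²/amu (constant correct to six significant figures).

## Lattice dynamics and mode symmetry

Γ-point only; no k-mesh and no LO-TO splitting. Imaginary frequencies are
reported as negative wavenumbers. Acoustic modes are identified as the three
smallest-|ν| modes whose eigenvectors overlap the mass-weighted
uniform-translation subspace by more than 0.99; they are excluded from every
Raman sum. Stationary-point classification counts optical modes below
−5 cm⁻¹ by default — the threshold absorbs numerical noise near zero, and
its sensitivity is itself unit-tested (a threshold wider than the most
negative mode reclassifies a saddle as a minimum).

Irrep assignment computes per-mode characters `χ(R) = eᵀM(R)e` with the
displacement operator `M` (atom permutation ⊗ Cartesian rotation) and
matches against shipped character tables (C1, Ci, Cs, C2, C2h, C2v, D2,
D2h — all 1-D irreps; classes matched by det/trace signature with a
deterministic axis ordering, so B1/B2-type labels are convention-dependent
and a global swap is accepted). The reduction formula
`nᵢ = (1/|G|) Σ_R χᵢ(R) Tr M(R)` serves as an independent oracle for the
per-mode totals.

One numerically important subtlety: weakly coupled identical molecules
produce *accidentally* quasi-degenerate multiplets (splittings well under
0.1 cm⁻¹) whose raw eigenvectors mix across irreps, blurring selection
rules. `symmetry_adapted_modes` applies the irrep projection operators
within each degenerate cluster and re-orthonormalizes, recovering
symmetry-pure modes (Rayleigh-quotient frequencies); with adapted modes the
u-mode Raman tensors of the centrosymmetric saddle vanish to ~1e-11 of the
largest tensor norm — the mutual-exclusion rule emerging numerically rather
than by table lookup.

## Raman model

Crystal polarizability is a bond-polarizability sum: each bond contributes
`a_∥(r) b̂b̂ᵀ + a_⊥(r)(1−b̂b̂ᵀ)` with linear bond-length dependence. This is
a deliberately crude but symmetry-correct stand-in for a quantum-chemical
polarizability: it transforms properly under rotations and lattice
translations, which is all the selection-rule and averaging machinery needs.
Mode tensors are central differences along mass-weighted eigenvectors
(default normal-coordinate amplitude 0.01 Å·√amu; halving it changes
tensors by < 1e-4 relative).

Intensity conventions: the powder average uses the natural (unanalyzed)
combination 45a² + 7γ² — appropriate when no polarization scrambler is in
the beam — with the 45a² + 4γ² and 3γ² channels also exposed; the
marginalized single-crystal channels are closed forms verified against
brute-force rotation averaging to 1e-10. The thermal/laser prefactor is the
standard Placzek form (ν_L − ν)⁴/ν with Bose occupation (defaults 293 K,
647.1 nm), togglable off for tests against bare invariants. Spectra are
sums of Lorentzians parameterized by *peak height* proportional to
intensity (fwhm 5 cm⁻¹ by default); the area convention would differ by a
width factor and is not used. Spectral similarity is the cosine of
mean-subtracted intensities on the overlapping grid.

## Eigenvector following

The initial kick is scaled so the largest single-atom displacement equals
0.1 Å (a geometric criterion is robust across force-field scales; an energy
criterion would not be). Both signs are followed; children are re-minimized,
re-classified, and compared. For a Z = 4 P2₁/c crystal distorted along a Bu
mode, the two children are related by the *lost* inversion/screw — never by
a pure lattice translation — so the equivalence check used after descent
matches structures modulo origin shifts combined with lattice point-group
rotations (species-respecting optimal assignment under minimum-image
distances); translation-only matching remains available and is what the
generic `structures_equivalent` default does.

## Synthetic scenarios

The T-rotor molecule (three-atom trunk + one rotor atom, 16 atoms per cell)
is the smallest object with a torsional internal coordinate that can mimic a
hindered aromatic-group rotation. Cells, molecular orientations and sites
were calibrated once, during construction, so that each scenario's packing
realizes its declared topology — for the monoclinic scenario a genuine
minimum along every coordinate except the single Bu torsion combination
(lowest real optical mode ≈ 15 cm⁻¹), for the orthorhombic scenario an
all-real spectrum — and then frozen. The default well position (8°) together
with the rotor arm (~0.72 Å) puts the saddle→minimum displacement at
~0.1 Å: below the 0.25 Å detection tolerance, far above 0.02 Å, which is
the construction of the tolerance pitfall. The two scenarios use the same
molecule but different packings, and the metastable form's LJ well depths
are doubled — a stiffer, denser packing — so the two polymorphs have
well-separated lattice-phonon fingerprints, the situation window-based
phase mapping presumes in the first place.

Map grids superpose the two phases' powder spectra (unit-peak normalized)
on a glass-like substrate (a very broad band plus slope and offset — slowly
varying, so a linear endpoint baseline removes it almost completely — and
two narrow substrate peaks), with Gaussian noise of σ = peak/SNR. Gaussian
rather than Poisson noise keeps the SNR a single interpretable dial. The
default SNR of 300 emulates a good confocal map on a strongly scattering
film; it is also roughly the level at which the 1% "no signal" rule is
meaningful at all, since window-integral noise must stay below a percent of
the pure-phase reference for substrate flagging to be well defined.

The scenario's diagnostic windows are chosen from the pure spectra by
minimizing the worst-case mixing bias of the two-window ratio estimator —
computed analytically from the signed baseline-corrected cross-areas,
substrate leakage included — over width-6 cm⁻¹ window pairs away from the
substrate peaks. This mirrors what one does with measured pure-phase
spectra, and makes the choice reproducible instead of aesthetic.

## Phase quantification

`fraction_II = w_II/(w_I + w_II)` with `w_X` the baseline-corrected window
integral normalized by the pure-phase reference; both windows below 1% of
their references flags "no signal" (reported as missing, never as 0.5).
Linear endpoint baseline by default, since low-wavenumber spectra on glass
ride a sloped background. Negative baseline-corrected areas are clipped at
zero; the signed variant is exposed for analysis.

## Numerical anchors the tests enforce

* forces vs. finite differences: 1e-6 relative; Hessian symmetric to 1e-6.
* acoustic modes: exactly three, |ν| < 0.1 cm⁻¹ after the sum rule.
* diatomic stretch vs. closed form ν = 108.591·√(k(1/m₁+1/m₂)): 1e-10.
* marginalized intensities vs. rotation averaging: 1e-10 (200 tensors).
* powder formula vs. 1e5-sample Monte-Carlo orientation average: 1%.
* u-mode tensor norms in the centrosymmetric saddle: < 1e-6 of the max.
* descent: equal child energies to 1e-8 (symmetry gives ~1e-13); energy
  drop per molecule equals the barrier to 1e-6.
* synthesized band fwhm: 5.00 ± 0.05 cm⁻¹.
* composition recovery: RMSE ≤ 0.05 over 20 seeded maps at default SNR
  (measured ≈ 0.041 ± 0.002).

## Known limitations

* The potential is a toy; no frequency or energy models a real substance.
  Passing tests demonstrate the *machinery* (symmetry algebra, selection
  rules, descent topology, estimators), not chemical accuracy.
* Only 1-D-irrep factor groups ship; degenerate (E-type) groups are out of
  scope, as are disorder, partial occupancy, and cell relaxation.
* The two-window ratio estimator carries a residual bias (up to ~0.09 near
  pure phase II for the shipped scenarios) from Lorentzian tail cross-talk
  between the two band systems; it is documented rather than hidden, and
  the smooth-field RMSE stays ≈ 0.04. Multivariate unmixing would remove
  it but is deliberately out of scope.
* Substrate "no signal" flagging under the 1% rule is reliable for
  SNR ≳ 1000 and degrades gracefully below; at the default SNR 300 roughly
  half of substrate-only points are flagged and none are mislabeled as
  mixtures with signal.
* Synthetic map spectra share the generator's own synthesis conventions
  (Lorentzian shapes, Gaussian noise, flat instrument response), so phase
  mapping results say nothing about instrument-specific artifacts.
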