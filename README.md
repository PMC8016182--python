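# phonoraman

Desk-scale structure validation of molecular-crystal polymorphs through
lattice-phonon Raman spectroscopy.

Candidate crystal structures for a polymorph — from crystal-structure
prediction, indexing of diffraction data, or chemical intuition — can be
subtly wrong in a way diffraction barely sees: a structure refined into a
space group that is actually a *saddle point* of the energy, a fraction of an
angstrom away from the true, lower-symmetry minimum. Low-wavenumber
(< 150 cm⁻¹) Raman spectra of lattice phonons are exquisitely sensitive to
exactly this, because the symmetry lowering changes which vibrational modes
are Raman active. `phonoraman` implements the full validation loop on toy
molecular crystals small enough to run in seconds:

* **Γ-point lattice dynamics** — the dynamical matrix
  `D[iα,jβ] = H[iα,jβ]/√(mᵢmⱼ)` from a finite-difference Hessian of a
  periodic force field; eigenvalues λ map to wavenumbers
  `ν = sign(λ)·108.591·√|λ|` (kcal/mol/Å²/amu units), negative values
  flagging imaginary modes. A positive-definite dynamical matrix certifies a
  minimum; imaginary modes expose a saddle.
* **Factor-group analysis** — irrep labels for every mode from the
  transformation of its eigenvector, `χ(R) = eᵀM(R)e`, with the standard
  reduction formula as an independent cross-check, mutual exclusion in
  centrosymmetric groups, and parent→subgroup correlation
  (C2h → Cs: Ag+Bu → A′, Au+Bg → A″).
* **Eigenvector following** — perturbing a saddle along an imaginary mode in
  both signs, re-minimizing, and verifying that the two descents reach
  equivalent minima; symmetry of the child is reported at two distance
  tolerances to surface the classic pitfall in which a ~0.1 Å distortion is
  invisible at the conventional 0.25 Å equivalence tolerance.
* **Raman intensities** — per-mode Raman tensors by central differences of a
  bond-polarizability model along each normal coordinate; powder averages
  `45a² + 7γ²`; single-crystal polarized intensities `(e_out·α·e_in)²`; and
  the orientation-marginalized channels for a needle with known axis *a*:
  `I_aa ∝ α_aa²`, `I_aa⊥ ∝ (α_ab² + α_ac²)/2`,
  `I_a⊥a⊥ ∝ (3α_bb² + 4α_bc² + 2α_bb α_cc + 3α_cc²)/8`;
  Lorentzian synthesis (peak-height convention, 5 cm⁻¹ fwhm) with the
  Placzek/Bose prefactor at 293 K and 647.1 nm.
* **Phase mapping** — per-point polymorph fractions across a spatial grid of
  noisy spectra via baseline-corrected integrals over two phase-diagnostic
  spectral windows, with substrate-only points flagged as "no signal".
* **Synthetic data** — deterministic generators for a stable orthorhombic
  crystal (Pna2₁-type operations, Z′ = 1), a monoclinic crystal whose
  centrosymmetric P2₁/c configuration is a first-order saddle with a single
  imaginary Bu torsional mode descending to glide-only Pc minima (Z′ = 2),
  and noisy two-phase micro-Raman maps over a glass-like background.

The intended audience is anyone building or teaching pipelines of this kind:
all physics (symmetry algebra, selection rules, descent topology, window
quantification) is exercised for real, on crystals of 16 atoms per cell.

## Worked example

`examples/04_saddle_escape.py` runs the central validation loop; it prints:

```
followed mode 0: nu = -945.0 cm^-1
saddle energy          : -37.984505 kcal/mol per cell
child energies (+ / -) : -39.984505 / -39.984505
energy drop per molecule: 0.500000 kcal/mol
children equivalent (modulo lattice isometry): True (best RMSD 1.87e-09 A)
child stationary point : minimum (0 imaginary modes)
parent group (0.25 A)  : P2_1/c
child group  (0.02 A)  : Pc, Z' = 2
child group  (0.25 A)  : P2_1/c  <- the tolerance pitfall
```

Reading: the candidate structure has one imaginary mode (−945 cm⁻¹, of Bu
symmetry — antisymmetric under inversion and the screw axis), so it is a
saddle, not a minimum. Following that mode in either direction lands in
equivalent minima 0.5 kcal/mol per molecule downhill (the constructed
torsional barrier). The minima keep only the glide plane (Pc, two
inequivalent molecule pairs), yet a symmetry checker at the conventional
0.25 Å tolerance converts them right back to the centrosymmetric parent —
the lattice-dynamical test catches what the geometric test misses.

The other examples cover space-group detection (`01`), irrep assignment and
the correlation scheme (`02`), powder/polarized spectra (`03`), and phase
mapping (`05`). A thin CLI mirrors the stages:

```bash
phonoraman fixtures --scenario saddle --out fixtures/
phonoraman symmetry fixtures/saddle.cif --tol 0.25
phonoraman modes fixtures/saddle.cif --ff fixtures/saddle_ff.toml
phonoraman escape fixtures/saddle.cif --ff fixtures/saddle_ff.toml --out escape_out/
```

## Layout

```
src/phonoraman/
  crystal_core.py     structures, symmetry ops, space-group detection, CIF
  model_potential.py  toy force field, forces, Hessian, bond polarizability
  lattice_dynamics.py dynamical matrix, modes, FORCE_CONSTANTS I/O
  symmetry_modes.py   character tables, irrep assignment, correlation
  raman.py            Raman tensors, intensity formulas, synthesis
  saddle_escape.py    eigenvector following, structure equivalence
  phase_map.py        window integrals, composition maps
  synthetic_data.py   scenario and map generators
docs/methods.md       model assumptions, parameter choices, limitations
```
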