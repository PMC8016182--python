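"""Gamma-point phonons, irrep assignment, and the parent-subgroup correlation.

Solves the lattice dynamics of the centrosymmetric saddle configuration,
labels every optical mode with its factor-group symmetry species, and prints
the correlation scheme obtained when the distortion removes the inversion
center and screw axis but keeps the glide plane.
"""

import warnings

import numpy as np

from phonoraman import (
    assign_irreps,
    build_dynamical_matrix,
    classify_stationary,
    correlate,
    detect_symmetry,
    factor_group,
    hessian,
    hessian_modes,
    load_character_table,
    make_saddle_scenario,
    symmetry_adapted_modes,
)
from phonoraman.symmetry_modes import activity

warnings.filterwarnings("ignore")

bundle = make_saddle_scenario()
h = hessian(bundle.structure, bundle.ff)
modes = hessian_modes(h, bundle.structure.masses)
cls = classify_stationary(modes)
print(f"stationary point: {cls.kind} with {cls.n_imaginary} imaginary mode(s)")

table = factor_group(detect_symmetry(bundle.structure, 0.25), bundle.structure.lattice)
modes = symmetry_adapted_modes(
    modes, bundle.structure, table, build_dynamical_matrix(h, bundle.structure.masses)
)
asg = assign_irreps(modes, bundle.structure, table)
print(f"factor group {table.name}; irrep multiplicities: {asg.multiplicities()}")

k_imag = int(modes.optical_indices[np.argmin(modes.frequencies_cm1[modes.optical_indices])])
nu = modes.frequencies_cm1[k_imag]
label = asg.label_of(k_imag)
raman, ir = activity(label, table)
print(
    f"unstable mode: nu = {nu:.1f} cm^-1 (imaginary), irrep {label}, "
    f"Raman active = {raman}, IR active = {ir}"
)
# In a centrosymmetric crystal no mode is both Raman and IR active; the
# unstable torsional combination is inversion-odd (u) and therefore silent
# in the Raman spectrum of the saddle.

mapping = correlate(
    load_character_table("C2h"), load_character_table("Cs"), {"E": "E", "sigma_h": "sigma"}
)
print(f"correlation on descent (glide preserved): {mapping}")
# Ag+Bu -> A' and Au+Bg -> A'': after the distortion every mode is Raman
# active, which is what distinguishes the two structures spectroscopically.
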