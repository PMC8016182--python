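"""Eigenvector following: from a saddle point to the true minimum.

Perturbs the centrosymmetric configuration along its single imaginary mode in
both directions, relaxes each copy, and reports energies, equivalence of the
two children, and the symmetry of parent and child.
"""

import warnings

from phonoraman import follow_imaginary_mode, hessian, hessian_modes, make_saddle_scenario

warnings.filterwarnings("ignore")

bundle = make_saddle_scenario()
modes = hessian_modes(hessian(bundle.structure, bundle.ff), bundle.structure.masses)
result = follow_imaginary_mode(bundle.structure, bundle.ff, modes)

print(f"followed mode {result.mode_index}: nu = {modes.frequencies_cm1[result.mode_index]:.1f} cm^-1")
print(f"saddle energy          : {result.energy_saddle:+.6f} kcal/mol per cell")
print(f"child energies (+ / -) : {result.energy_plus:+.6f} / {result.energy_minus:+.6f}")
print(f"energy drop per molecule: {result.delta_e_per_molecule:.6f} kcal/mol")
# equals the torsional barrier height: each rotor relaxes from the barrier
# top into one of its two wells.
print(f"children equivalent (modulo lattice isometry): {result.equivalent} "
      f"(best RMSD {result.rmsd:.2e} A)")
print(f"child stationary point : {result.child_classification.kind} "
      f"({result.child_classification.n_imaginary} imaginary modes)")
print(f"parent group (0.25 A)  : {result.parent_group.hm_symbol}")
print(f"child group  (0.02 A)  : {result.child_group.hm_symbol}, Z' = {result.child_group.z_prime}")
print(f"child group  (0.25 A)  : {result.child_group_loose.hm_symbol}  <- the tolerance pitfall")
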