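"""Character tables, displacement operators, irrep assignment and correlation."""

import numpy as np
import pytest

from phonoraman.crystal_core import CrystalStructure, detect_symmetry
from phonoraman.errors import CorrelationError, InconsistentSymmetryError, ParameterError
from phonoraman.lattice_dynamics import hessian_modes
from phonoraman.symmetry_modes import (
    activity,
    assign_irreps,
    available_tables,
    correlate,
    decompose_representation,
    displacement_operator,
    factor_group,
    load_character_table,
)


class TestCharacterTables:
    @pytest.mark.parametrize("name", ["C1", "Ci", "Cs", "C2", "C2h", "C2v", "D2", "D2h"])
    def test_orthogonality(self, name):
        table = load_character_table(name)
        assert table.check_orthogonality()

    @pytest.mark.parametrize("name", ["C1", "Ci", "Cs", "C2", "C2h", "C2v", "D2", "D2h"])
    def test_first_column_is_dimension(self, name):
        table = load_character_table(name)
        assert np.all(table.characters[:, 0] == 1)  # all shipped irreps 1-D

    def test_mutual_exclusion_in_centrosymmetric_groups(self):
        for name in ("Ci", "C2h", "D2h"):
            table = load_character_table(name)
            for irrep in table.irrep_names:
                r, i = activity(irrep, table)
                assert not (r and i), f"{name}:{irrep} both Raman and IR active"

    def test_all_tables_listed(self):
        assert set(available_tables()) == {"C1", "Ci", "Cs", "C2", "C2h", "C2v", "D2", "D2h"}

    def test_unknown_group_raises(self):
        with pytest.raises(ParameterError):
            load_character_table("Oh")


class TestDisplacementOperator:
    def test_identity_op_is_identity_matrix(self, saddle_bundle, saddle_table):
        e_class = saddle_table.class_labels.index("E")
        m = displacement_operator(saddle_bundle.structure, saddle_table.class_reps[e_class])
        assert np.allclose(m, np.eye(m.shape[0]))

    def test_inversion_squares_to_identity(self, saddle_bundle, saddle_table):
        i_class = saddle_table.class_labels.index("i")
        m = displacement_operator(saddle_bundle.structure, saddle_table.class_reps[i_class])
        assert np.allclose(m @ m, np.eye(m.shape[0]), atol=1e-10)

    def test_orthogonal(self, saddle_bundle, saddle_table):
        for op in saddle_table.class_reps:
            m = displacement_operator(saddle_bundle.structure, op)
            assert np.allclose(m @ m.T, np.eye(m.shape[0]), atol=1e-10)

    def test_trace_matches_character_formula(self, escape_result):
        """Glide on the Pc child: Tr M = sum over unmoved atoms of (+-1 + 2 cos theta);
        no atom is unmoved by the glide, so the trace vanishes."""
        child = escape_result.structure_plus
        sg = detect_symmetry(child, 0.02)
        glide = next(op for op in sg.operations if not op.is_identity)
        m = displacement_operator(child, glide)
        assert float(np.trace(m)) == pytest.approx(0.0, abs=1e-10)

    def test_non_symmetry_op_raises_with_worst_atom(self, saddle_bundle):
        from phonoraman.crystal_core import SymmetryOp

        bogus = SymmetryOp.from_arrays(np.diag([1, -1, 1]), [0.2, 0.11, 0.37])
        with pytest.raises(InconsistentSymmetryError, match="atom"):
            displacement_operator(saddle_bundle.structure, bogus, tol=0.05)


class TestAssignIrreps:
    def test_imaginary_mode_is_bu(self, saddle_bundle, saddle_modes_adapted, saddle_table):
        asg = assign_irreps(saddle_modes_adapted, saddle_bundle.structure, saddle_table)
        k_imag = int(
            saddle_modes_adapted.optical_indices[
                np.argmin(saddle_modes_adapted.frequencies_cm1[saddle_modes_adapted.optical_indices])
            ]
        )
        assert asg.label_of(k_imag) == "Bu"

    def test_multiplicities_match_reduction_oracle(
        self, saddle_bundle, saddle_modes_adapted, saddle_table
    ):
        """Per-mode totals equal the brute-force reduction formula after the
        translation irreps (acoustic modes) are subtracted."""
        asg = assign_irreps(saddle_modes_adapted, saddle_bundle.structure, saddle_table)
        reduction = decompose_representation(saddle_bundle.structure, saddle_table)
        counted = asg.multiplicities()
        # C2h, twofold axis along b: translations transform as Au + 2 Bu
        translations = {"Au": 1, "Bu": 2}
        for irrep, n in reduction.items():
            assert counted.get(irrep, 0) == n - translations.get(irrep, 0)

    def test_form1_multiplicities_match_oracle(
        self, form1_bundle, form1_modes_adapted, form1_table
    ):
        asg = assign_irreps(form1_modes_adapted, form1_bundle.structure, form1_table)
        reduction = decompose_representation(form1_bundle.structure, form1_table)
        counted = asg.multiplicities()
        assert set(counted) <= {"A1", "A2", "B1", "B2"}
        # C2v: translations transform as A1 (z) + B1 + B2 (x, y)
        translations = {"A1": 1, "B1": 1, "B2": 1}
        for irrep, n in reduction.items():
            assert counted.get(irrep, 0) == n - translations.get(irrep, 0)

    def test_c1_structure_all_modes_labeled_a(self, rng):
        frac = rng.uniform(0, 1, (4, 3))
        s = CrystalStructure(
            np.diag([7.0, 8.0, 9.0]), frac, ["C"] * 4, np.full(4, 12.0), np.arange(4)
        )
        # any symmetric positive-definite matrix works as a stand-in Hessian
        a = rng.normal(0, 1, (12, 12))
        h = a @ a.T + 12 * np.eye(12)
        h = h - h.mean()  # not ASR-corrected; acoustic flags fall back with warning
        modes = hessian_modes(h @ h.T, s.masses)  # ensure symmetric PSD
        table = factor_group(detect_symmetry(s, 0.25), s.lattice)
        assert table.name == "C1"
        asg = assign_irreps(modes, s, table)
        assert set(asg.labels) == {"A"}


class TestDecomposeRepresentation:
    def test_p1_gives_3n_copies_of_a(self, rng):
        frac = rng.uniform(0, 1, (5, 3))
        s = CrystalStructure(
            np.diag([7.0, 8.0, 9.0]), frac, ["C"] * 5, np.full(5, 12.0), np.arange(5)
        )
        table = factor_group(detect_symmetry(s, 0.25), s.lattice)
        assert decompose_representation(s, table) == {"A": 15}

    def test_centrosymmetric_completeness(self, saddle_bundle, saddle_table):
        n = decompose_representation(saddle_bundle.structure, saddle_table)
        g_total = n["Ag"] + n["Bg"]
        u_total = n["Au"] + n["Bu"]
        assert g_total + u_total == 3 * saddle_bundle.structure.n_atoms


class TestCorrelate:
    def test_c2h_to_cs_scheme(self):
        """Losing inversion and the screw maps Ag+Bu -> A' and Au+Bg -> A''."""
        parent = load_character_table("C2h")
        sub = load_character_table("Cs")
        mapping = correlate(parent, sub, {"E": "E", "sigma_h": "sigma"})
        assert mapping == {"Ag": "A'", "Bu": "A'", "Au": "A''", "Bg": "A''"}

    def test_identity_correlation(self):
        t = load_character_table("C2h")
        mapping = correlate(t, t, {c: c for c in t.class_labels})
        assert mapping == {n: n for n in t.irrep_names}

    def test_c2v_to_c1_everything_to_a(self):
        mapping = correlate(load_character_table("C2v"), load_character_table("C1"), {"E": "E"})
        assert set(mapping.values()) == {"A"}

    def test_ambiguous_correlation_raises(self):
        # preserving only E cannot distinguish the two Cs irreps
        with pytest.raises(CorrelationError):
            correlate(load_character_table("C2h"), load_character_table("Cs"), {"E": "E"})

    def test_descent_children_follow_the_correlation_scheme(
        self, saddle_bundle, saddle_modes_adapted, saddle_table, escape_result
    ):
        """Matching saddle modes to child modes by eigenvector overlap, the child
        label equals the correlated saddle label for the overwhelming majority."""
        import warnings

        from phonoraman.lattice_dynamics import build_dynamical_matrix
        from phonoraman.model_potential import hessian
        from phonoraman.symmetry_modes import symmetry_adapted_modes

        child = escape_result.structure_plus
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = hessian(child, saddle_bundle.ff)
        modes_child = hessian_modes(h, child.masses)
        sg_child = detect_symmetry(child, 0.02)
        table_child = factor_group(sg_child, child.lattice)
        modes_child = symmetry_adapted_modes(
            modes_child, child, table_child, build_dynamical_matrix(h, child.masses)
        )
        asg_parent = assign_irreps(saddle_modes_adapted, saddle_bundle.structure, saddle_table)
        asg_child = assign_irreps(modes_child, child, table_child)
        mapping = correlate(saddle_table, table_child, {"E": "E", "sigma_h": "sigma"})

        matches = 0
        total = 0
        for k in saddle_modes_adapted.optical_indices:
            overlaps = np.abs(
                modes_child.eigenvectors.T @ saddle_modes_adapted.eigenvectors[:, k]
            )
            j = int(np.argmax(overlaps))
            if j in modes_child.acoustic_indices or overlaps[j] < 0.9:
                continue
            total += 1
            if asg_child.label_of(j) == mapping[asg_parent.label_of(int(k))]:
                matches += 1
        assert total > 30
        assert matches / total > 0.95


class TestActivity:
    def test_c2h_flags(self):
        t = load_character_table("C2h")
        assert activity("Ag", t) == (True, False)
        assert activity("Bu", t) == (False, True)

    def test_cs_all_raman_active(self):
        t = load_character_table("Cs")
        assert activity("A'", t)[0] and activity("A''", t)[0]

    def test_c1_both(self):
        assert activity("A", load_character_table("C1")) == (True, True)

    def test_unknown_irrep_raises(self):
        with pytest.raises(ParameterError):
            activity("Eg", load_character_table("C2h"))
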