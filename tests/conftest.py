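"""Shared fixtures: the synthetic crystals and their (expensive) phonon solutions.

Everything heavy is session-scoped; all fixtures are deterministic.
"""

import warnings

import numpy as np
import pytest

from phonoraman.crystal_core import detect_symmetry
from phonoraman.lattice_dynamics import build_dynamical_matrix, hessian_modes
from phonoraman.model_potential import hessian
from phonoraman.saddle_escape import follow_imaginary_mode
from phonoraman.symmetry_modes import factor_group, symmetry_adapted_modes
from phonoraman.synthetic_data import make_form1_scenario, make_saddle_scenario


@pytest.fixture(scope="session")
def saddle_bundle():
    return make_saddle_scenario()


@pytest.fixture(scope="session")
def saddle_hessian(saddle_bundle):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hessian(saddle_bundle.structure, saddle_bundle.ff)


@pytest.fixture(scope="session")
def saddle_modes(saddle_bundle, saddle_hessian):
    return hessian_modes(saddle_hessian, saddle_bundle.structure.masses)


@pytest.fixture(scope="session")
def saddle_table(saddle_bundle):
    sg = detect_symmetry(saddle_bundle.structure, 0.25)
    return factor_group(sg, saddle_bundle.structure.lattice)


@pytest.fixture(scope="session")
def saddle_modes_adapted(saddle_bundle, saddle_hessian, saddle_modes, saddle_table):
    dynmat = build_dynamical_matrix(saddle_hessian, saddle_bundle.structure.masses)
    return symmetry_adapted_modes(
        saddle_modes, saddle_bundle.structure, saddle_table, dynmat
    )


@pytest.fixture(scope="session")
def escape_result(saddle_bundle, saddle_modes):
    return follow_imaginary_mode(saddle_bundle.structure, saddle_bundle.ff, saddle_modes)


@pytest.fixture(scope="session")
def form1_bundle():
    return make_form1_scenario()


@pytest.fixture(scope="session")
def form1_hessian(form1_bundle):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hessian(form1_bundle.structure, form1_bundle.ff)


@pytest.fixture(scope="session")
def form1_modes(form1_bundle, form1_hessian):
    return hessian_modes(form1_hessian, form1_bundle.structure.masses)


@pytest.fixture(scope="session")
def form1_table(form1_bundle):
    sg = detect_symmetry(form1_bundle.structure, 0.25)
    return factor_group(sg, form1_bundle.structure.lattice)


@pytest.fixture(scope="session")
def form1_modes_adapted(form1_bundle, form1_hessian, form1_modes, form1_table):
    dynmat = build_dynamical_matrix(form1_hessian, form1_bundle.structure.masses)
    return symmetry_adapted_modes(form1_modes, form1_bundle.structure, form1_table, dynmat)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
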