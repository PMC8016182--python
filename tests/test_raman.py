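"""Raman tensors, intensity formulas (with averaging oracles) and spectral synthesis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phonoraman.errors import ConfigError, ParameterError
from phonoraman.raman import (
    Spectrum,
    SpectrumConfig,
    marginalized_intensities,
    mode_raman_tensors,
    mode_spectrum,
    polarized_intensity,
    powder_intensity,
    similarity,
    synthesize,
    thermal_prefactor,
)
from phonoraman.synthetic_data import random_symmetric_tensor


def rot_x(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


symmetric_tensors = st.lists(
    st.floats(-5, 5, allow_nan=False, allow_infinity=False), min_size=6, max_size=6
).map(
    lambda v: np.array(
        [[v[0], v[3], v[4]], [v[3], v[1], v[5]], [v[4], v[5], v[2]]]
    )
)


class TestIntensityProperties:
    """Invariants that must hold for arbitrary symmetric Raman tensors."""

    @given(t=symmetric_tensors)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_powder_nonnegative_and_rotation_invariant(self, t):
        val = powder_intensity(t)
        assert val >= -1e-9
        r = rot_x(0.7)
        assert powder_intensity(r @ t @ r.T) == pytest.approx(val, rel=1e-8, abs=1e-8)

    @given(t=symmetric_tensors)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_marginalized_channels_nonnegative(self, t):
        assert all(v >= -1e-12 for v in marginalized_intensities(t))


class TestModeRamanTensors:
    def test_count_and_symmetry(self, saddle_bundle, saddle_modes_adapted):
        ts = mode_raman_tensors(
            saddle_bundle.structure, saddle_modes_adapted, saddle_bundle.polarizability_fn()
        )
        n = saddle_bundle.structure.n_atoms
        assert len(ts.tensors) == 3 * n - 3
        assert np.max(np.abs(ts.tensors - ts.tensors.transpose(0, 2, 1))) < 1e-10

    def test_acoustic_translation_gives_zero_tensor(self, saddle_bundle):
        """A uniform translation leaves the crystal polarizability unchanged."""
        fn = saddle_bundle.polarizability_fn()
        s = saddle_bundle.structure
        delta = 0.01
        shifted = s.with_cart(s.cart_coords + np.array([delta, 0, 0]))
        assert np.max(np.abs(fn(shifted) - fn(s))) < 1e-10

    def test_central_difference_richardson(self, saddle_bundle, saddle_modes_adapted):
        """Halving the amplitude changes the tensors by < 1e-4 relative."""
        fn = saddle_bundle.polarizability_fn()
        t1 = mode_raman_tensors(saddle_bundle.structure, saddle_modes_adapted, fn, amplitude=0.01)
        t2 = mode_raman_tensors(saddle_bundle.structure, saddle_modes_adapted, fn, amplitude=0.005)
        scale = np.max(np.abs(t1.tensors))
        assert np.max(np.abs(t1.tensors - t2.tensors)) < 1e-4 * scale

    def test_u_modes_have_vanishing_tensors(
        self, saddle_bundle, saddle_modes_adapted, saddle_table
    ):
        """Mutual exclusion emerges numerically: in the centrosymmetric saddle,
        inversion-odd modes carry no Raman tensor."""
        from phonoraman.symmetry_modes import assign_irreps

        asg = assign_irreps(saddle_modes_adapted, saddle_bundle.structure, saddle_table)
        ts = mode_raman_tensors(
            saddle_bundle.structure, saddle_modes_adapted, saddle_bundle.polarizability_fn()
        )
        norms = np.linalg.norm(ts.tensors.reshape(len(ts.tensors), -1), axis=1)
        u_mask = np.array([asg.label_of(int(k)) in ("Au", "Bu") for k in ts.mode_indices])
        assert norms[u_mask].max() < 1e-6 * norms.max()

    def test_oversized_amplitude_raises(self, saddle_bundle, saddle_modes):
        with pytest.raises(ParameterError):
            mode_raman_tensors(
                saddle_bundle.structure,
                saddle_modes,
                saddle_bundle.polarizability_fn(),
                amplitude=10.0,
            )


class TestPowderIntensity:
    def test_identity_tensor(self):
        assert powder_intensity(np.eye(3)) == pytest.approx(45.0)

    def test_pure_shear_tensor(self):
        # traceless shear alpha_xy = alpha_yx = 1: a = 0, gamma^2 = 6/2 = 3
        t = np.zeros((3, 3))
        t[0, 1] = t[1, 0] = 1.0
        assert powder_intensity(t) == pytest.approx(21.0)

    def test_monte_carlo_orientation_average(self):
        """45 a^2 + 7 gamma^2 equals the 3-D orientation average of the two
        backscattering polarization channels, 1e5 rotations, within 1%."""
        from scipy.spatial.transform import Rotation

        rots = Rotation.random(100_000, random_state=12345).as_matrix()
        for seed in (0, 1, 2):
            t = random_symmetric_tensor(seed)
            rotated = np.einsum("nij,jk,nlk->nil", rots, t, rots)
            i_par = rotated[:, 0, 0] ** 2
            i_perp = rotated[:, 1, 0] ** 2
            mc = 45.0 * float(np.mean(i_par + i_perp))
            assert mc == pytest.approx(powder_intensity(t), rel=0.01)

    def test_channels(self):
        t = random_symmetric_tensor(7)
        nat = powder_intensity(t, "natural")
        par = powder_intensity(t, "parallel")
        perp = powder_intensity(t, "perpendicular")
        assert nat == pytest.approx(par + perp)


class TestPolarizedIntensity:
    def test_aa_geometry_probes_alpha_aa(self):
        t = random_symmetric_tensor(3)
        x = np.array([1.0, 0, 0])
        assert polarized_intensity(t, x, x) == pytest.approx(t[0, 0] ** 2)

    def test_cross_polarization_identity(self):
        """aa_perp and a_perp-a spectra coincide because alpha is symmetric."""
        t = random_symmetric_tensor(4)
        a = np.array([1.0, 0, 0])
        for theta in (0.3, 1.1, 2.5):
            perp = rot_x(theta) @ np.array([0, 1.0, 0])
            assert polarized_intensity(t, a, perp) == pytest.approx(
                polarized_intensity(t, perp, a), rel=1e-12
            )

    def test_orthogonal_principal_axes_give_zero(self):
        t = np.diag([1.0, 2.0, 3.0])
        assert polarized_intensity(t, [1, 0, 0], [0, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_vector_raises(self):
        with pytest.raises(ParameterError):
            polarized_intensity(np.eye(3), [0, 0, 0], [1, 0, 0])


class TestMarginalizedIntensities:
    def test_printed_coefficient_bc(self):
        t = np.zeros((3, 3))
        t[1, 2] = t[2, 1] = 1.0
        i_aa, i_ap, i_pp = marginalized_intensities(t)
        assert (i_aa, i_ap, i_pp) == (0.0, 0.0, pytest.approx(0.5))  # 4/8

    def test_printed_coefficient_ab_ac(self):
        t = np.zeros((3, 3))
        t[0, 1] = t[1, 0] = 1.0
        t[0, 2] = t[2, 0] = 1.0
        assert marginalized_intensities(t)[1] == pytest.approx(1.0)  # (1+1)/2

    def test_closed_forms_equal_theta_average_oracle(self):
        """All three formulas equal the numerical average over the unknown
        rotation about a, for 200 random tensors, to 1e-10."""
        # the integrand is a trig polynomial in theta, so the uniform-grid mean
        # is the exact average already at modest resolution
        thetas = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        a = np.array([1.0, 0, 0])
        perps = np.stack([rot_x(th) @ np.array([0, 1.0, 0]) for th in thetas])  # (n, 3)
        for seed in range(200):
            t = random_symmetric_tensor(seed)
            i_aa, i_ap, i_pp = marginalized_intensities(t)
            ta = t @ a
            assert abs(np.dot(a, ta) ** 2 - i_aa) < 1e-10
            assert abs(np.mean((perps @ ta) ** 2) - i_ap) < 1e-10
            assert abs(np.mean(np.einsum("ni,ij,nj->n", perps, t, perps) ** 2) - i_pp) < 1e-10

    def test_rotational_consistency(self):
        """Rotating tensor and polarization vectors together changes nothing."""
        t = random_symmetric_tensor(11)
        r = rot_x(0.77) @ np.array(
            [[np.cos(0.4), -np.sin(0.4), 0], [np.sin(0.4), np.cos(0.4), 0], [0, 0, 1]]
        )
        e_in, e_out = np.array([1.0, 0, 0]), np.array([0, 1.0, 0])
        before = polarized_intensity(t, e_in, e_out)
        after = polarized_intensity(r @ t @ r.T, r @ e_in, r @ e_out)
        assert after == pytest.approx(before, rel=1e-12)


class TestThermalPrefactor:
    def test_low_temperature_limit_is_placzek_only(self):
        cfg_cold = SpectrumConfig(temperature=1e-6)
        cfg = SpectrumConfig()
        nu = 50.0
        placzek = (cfg.laser_cm1 - nu) ** 4 / nu
        assert thermal_prefactor(nu, cfg_cold) == pytest.approx(placzek, rel=1e-9)

    def test_monotone_enhancement_at_low_wavenumber(self):
        cfg = SpectrumConfig()
        assert thermal_prefactor(20.0, cfg) > thermal_prefactor(120.0, cfg)

    def test_matches_direct_evaluation(self):
        cfg = SpectrumConfig()
        nu = 50.0
        bose = 1.0 / (1.0 - np.exp(-1.4387769 * nu / 293.0))
        ref = (1e7 / 647.1 - nu) ** 4 / nu * bose
        assert thermal_prefactor(nu, cfg) == pytest.approx(ref, rel=1e-12)

    def test_nonpositive_wavenumber_raises(self):
        with pytest.raises(ParameterError):
            thermal_prefactor(-10.0, SpectrumConfig())


class TestSynthesize:
    def test_single_band_fwhm_is_five(self):
        """Numerically measured full width at half maximum of an isolated band
        equals the configured 5 cm^-1."""
        cfg = SpectrumConfig(grid_start=80, grid_stop=120, grid_step=0.01)
        spec = synthesize(np.array([100.0]), np.array([1.0]), cfg)
        half = spec.intensity.max() / 2
        above = spec.wavenumber[spec.intensity >= half]
        fwhm = above[-1] - above[0]
        assert fwhm == pytest.approx(5.0, abs=0.05)

    def test_zero_intensities_give_zero_spectrum(self):
        spec = synthesize(np.array([50.0, 80.0]), np.zeros(2))
        assert np.all(spec.intensity == 0)

    def test_peak_heights_proportional_to_intensity(self):
        cfg = SpectrumConfig(grid_start=10, grid_stop=200, grid_step=0.01)
        spec = synthesize(np.array([50.0, 150.0]), np.array([2.0, 1.0]), cfg)
        h1 = spec.intensity[np.argmin(np.abs(spec.wavenumber - 50.0))]
        h2 = spec.intensity[np.argmin(np.abs(spec.wavenumber - 150.0))]
        assert h1 == pytest.approx(2.0, rel=0.01)
        assert h2 == pytest.approx(1.0, rel=0.01)

    def test_imaginary_frequencies_excluded(self):
        spec = synthesize(np.array([-100.0, 50.0]), np.array([5.0, 1.0]))
        peak_at_50 = spec.intensity[np.argmin(np.abs(spec.wavenumber - 50.0))]
        assert spec.intensity.max() == pytest.approx(peak_at_50)


class TestSimilarity:
    def test_self_similarity_is_one(self):
        s = synthesize(np.array([40.0, 90.0]), np.array([1.0, 0.5]))
        assert similarity(s, s) == pytest.approx(1.0)

    def test_inverted_spectrum_scores_minus_one(self):
        s = synthesize(np.array([40.0, 90.0]), np.array([1.0, 0.5]))
        inverted = Spectrum(s.wavenumber, s.intensity.max() - s.intensity)
        assert similarity(s, inverted) == pytest.approx(-1.0)

    def test_no_overlap_raises(self):
        a = Spectrum(np.linspace(10, 20, 50), np.ones(50))
        b = Spectrum(np.linspace(30, 40, 50), np.ones(50))
        with pytest.raises(ConfigError):
            similarity(a, b)

    def test_spectrum_discriminates_the_true_phase(
        self, saddle_bundle, saddle_modes_adapted, escape_result
    ):
        """The distorted-minimum spectrum scores higher against an 'observed'
        mixture than the saddle spectrum does: the extra bands activated by the
        loss of inversion are the discriminator."""
        import warnings

        from phonoraman.lattice_dynamics import hessian_modes
        from phonoraman.model_potential import hessian

        cfg = SpectrumConfig(grid_start=10, grid_stop=150, grid_step=0.5)
        ts = mode_raman_tensors(
            saddle_bundle.structure, saddle_modes_adapted, saddle_bundle.polarizability_fn()
        )
        s_saddle = mode_spectrum(ts, cfg, "powder")
        child = escape_result.structure_plus
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            modes_child = hessian_modes(hessian(child, saddle_bundle.ff), child.masses)
        tc = mode_raman_tensors(child, modes_child, saddle_bundle.polarizability_fn())
        s_child = mode_spectrum(tc, cfg, "powder")

        rng = np.random.default_rng(0)
        observed = Spectrum(
            s_child.wavenumber,
            np.maximum(
                0.9 * s_child.intensity
                + 0.1 * s_saddle.intensity
                + 0.01 * s_child.intensity.max() * rng.normal(0, 1, len(s_child.wavenumber)),
                0.0,
            ),
        )
        assert similarity(s_child, observed) > similarity(s_saddle, observed)

    def test_symmetry_lowering_activates_more_bands(
        self, saddle_bundle, saddle_modes_adapted, saddle_table, escape_result
    ):
        """Loss of inversion makes formerly silent u modes Raman active: the
        distorted minimum carries strictly more active bands, including bands at
        the frequencies of modes that were exactly silent in the saddle."""
        import warnings

        from phonoraman.lattice_dynamics import hessian_modes
        from phonoraman.model_potential import hessian
        from phonoraman.symmetry_modes import assign_irreps

        ts = mode_raman_tensors(
            saddle_bundle.structure, saddle_modes_adapted, saddle_bundle.polarizability_fn()
        )
        child = escape_result.structure_plus
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            modes_child = hessian_modes(hessian(child, saddle_bundle.ff), child.masses)
        tc = mode_raman_tensors(child, modes_child, saddle_bundle.polarizability_fn())

        def active_bands(tensor_set, lo=10.0, hi=150.0, rel=1e-3):
            acts = np.array([powder_intensity(t) for t in tensor_set.tensors])
            keep = (tensor_set.frequencies_cm1 > lo) & (tensor_set.frequencies_cm1 < hi)
            acts, freqs = acts[keep], tensor_set.frequencies_cm1[keep]
            return freqs[acts > rel * acts.max()]

        saddle_bands = active_bands(ts)
        child_bands = active_bands(tc)
        assert len(child_bands) > len(saddle_bands)

        asg = assign_irreps(saddle_modes_adapted, saddle_bundle.structure, saddle_table)
        u_freqs = [
            float(nu)
            for k, nu in zip(ts.mode_indices, ts.frequencies_cm1)
            if asg.label_of(int(k)) in ("Au", "Bu") and 10 < nu < 150
        ]
        assert u_freqs, "expected inversion-odd lattice modes in the spectral range"
        gained = sum(
            1 for nu in u_freqs if np.any(np.abs(child_bands - nu) < 1.0)
        )
        assert gained >= 1
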