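"""Raman tensors, polarized/marginalized/powder intensities and spectral synthesis.

The Raman tensor of mode k is the derivative of the crystal polarizability
along the normal coordinate, computed by central finite differences of the
bond-polarizability model (or any user-supplied polarizability function):

    alpha'_k = [alpha(x + d u_k) - alpha(x - d u_k)] / (2 d),

with ``u_k`` the mass-weighted eigenvector converted to Cartesian
displacements.  Intensity formulas:

* single-crystal polarized backscattering: ``I = (e_out . alpha . e_in)^2``;
* marginalized over the unknown rotation about the crystal a axis (a || x):
  ``I_aa = alpha_aa^2``, ``I_aa_perp = (alpha_ab^2 + alpha_ac^2)/2``,
  ``I_aperp_aperp = (3 alpha_bb^2 + 4 alpha_bc^2 + 2 alpha_bb alpha_cc
  + 3 alpha_cc^2)/8``;
* powder (full 3-D orientational average, same rules as gases):
  ``45 a^2 + 7 gamma^2`` in the natural (unanalyzed) channel, with
  ``a = tr(alpha)/3`` and ``gamma^2`` the standard anisotropy invariant.

Spectra are sums of Lorentzians parameterized by *peak height* proportional
to the mode intensity (the area convention would differ by a factor of the
width); the default thermal/laser prefactor is the standard Placzek form
``(nu_L - nu)^4 / nu`` times the Bose occupation factor at the configured
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crystal_core import CrystalStructure
from .errors import ConfigError, ParameterError
from .lattice_dynamics import PhononModeSet

__all__ = [
    "RamanTensorSet",
    "SpectrumConfig",
    "Spectrum",
    "mode_raman_tensors",
    "powder_intensity",
    "polarized_intensity",
    "marginalized_intensities",
    "thermal_prefactor",
    "synthesize",
    "mode_spectrum",
    "similarity",
]

HC_OVER_KB_CM_K = 1.4387769  # second radiation constant, cm*K


@dataclass
class SpectrumConfig:
    """Synthesis conditions: 293 K, 647.1 nm excitation, 5 cm^-1 fwhm by default."""

    temperature: float = 293.0  # K
    laser_nm: float = 647.1
    fwhm_cm1: float = 5.0
    grid_start: float = 10.0
    grid_stop: float = 200.0
    grid_step: float = 0.1

    def __post_init__(self) -> None:
        if self.fwhm_cm1 <= 0 or self.temperature <= 0:
            raise ConfigError("fwhm and temperature must be positive")
        if not (self.grid_start < self.grid_stop and self.grid_step > 0):
            raise ConfigError("spectrum grid must be ascending")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.grid_start, self.grid_stop + 0.5 * self.grid_step, self.grid_step)

    @property
    def laser_cm1(self) -> float:
        return 1.0e7 / self.laser_nm


@dataclass
class Spectrum:
    wavenumber: np.ndarray  # cm^-1, ascending
    intensity: np.ndarray  # arbitrary units, >= 0

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumber.shape != self.intensity.shape:
            raise ConfigError("wavenumber and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ConfigError("negative spectral intensity")


@dataclass
class RamanTensorSet:
    """Symmetric 3x3 polarizability derivatives per non-acoustic mode.

    Tensors are expressed in the crystal Cartesian frame (a along x, b in the
    xy plane), units A^2 amu^-1/2.
    """

    mode_indices: np.ndarray
    frequencies_cm1: np.ndarray
    tensors: np.ndarray  # (M, 3, 3)


def mode_raman_tensors(
    structure: CrystalStructure,
    modes: PhononModeSet,
    polarizability_fn,
    amplitude: float = 0.01,
) -> RamanTensorSet:
    """Finite-difference Raman tensors along every non-acoustic normal coordinate.

    ``amplitude`` is the normal-coordinate step in A*sqrt(amu).  Raises
    :class:`ParameterError` when the displaced structure moves any atom by
    more than 0.5 A (connectivity sanity bound).
    """
    if amplitude <= 0:
        raise ParameterError("amplitude must be positive")
    cart0 = structure.cart_coords
    idx = modes.optical_indices
    tensors = np.empty((len(idx), 3, 3))
    for n, k in enumerate(idx):
        disp = amplitude * modes.cartesian_displacement(int(k))
        if np.max(np.linalg.norm(disp, axis=1)) > 0.5:
            raise ParameterError(
                f"amplitude {amplitude} displaces atoms by more than 0.5 A on mode {k}"
            )
        a_plus = polarizability_fn(structure.with_cart(cart0 + disp))
        a_minus = polarizability_fn(structure.with_cart(cart0 - disp))
        t = (a_plus - a_minus) / (2.0 * amplitude)
        tensors[n] = 0.5 * (t + t.T)
    return RamanTensorSet(
        mode_indices=np.asarray(idx),
        frequencies_cm1=modes.frequencies_cm1[idx],
        tensors=tensors,
    )


def powder_intensity(tensor: np.ndarray, channel: str = "natural") -> float:
    """Orientation-averaged intensity from the tensor invariants.

    Channels: "natural" (unanalyzed, 45 a^2 + 7 gamma^2, the default used for
    unpolarized spectra recorded without a scrambler), "parallel"
    (45 a^2 + 4 gamma^2) and "perpendicular" (3 gamma^2).
    """
    t = np.asarray(tensor, dtype=float)
    a = np.trace(t) / 3.0
    g2 = 0.5 * (
        (t[0, 0] - t[1, 1]) ** 2
        + (t[1, 1] - t[2, 2]) ** 2
        + (t[2, 2] - t[0, 0]) ** 2
        + 6.0 * (t[0, 1] ** 2 + t[1, 2] ** 2 + t[2, 0] ** 2)
    )
    if channel == "natural":
        return float(45.0 * a * a + 7.0 * g2)
    if channel == "parallel":
        return float(45.0 * a * a + 4.0 * g2)
    if channel == "perpendicular":
        return float(3.0 * g2)
    raise ParameterError(f"unknown powder channel {channel!r}")


def polarized_intensity(tensor: np.ndarray, e_in: np.ndarray, e_out: np.ndarray) -> float:
    """Single-crystal polarized intensity (e_out . alpha . e_in)^2."""
    e_in = np.asarray(e_in, dtype=float)
    e_out = np.asarray(e_out, dtype=float)
    for v in (e_in, e_out):
        n = np.linalg.norm(v)
        if n < 1e-12:
            raise ParameterError("zero-length polarization vector")
    e_in = e_in / np.linalg.norm(e_in)
    e_out = e_out / np.linalg.norm(e_out)
    return float(np.dot(e_out, np.asarray(tensor) @ e_in) ** 2)


def marginalized_intensities(tensor: np.ndarray) -> tuple[float, float, float]:
    """(I_aa, I_aa_perp, I_aperp_aperp): closed forms after averaging the unknown
    rotation about the crystal a axis (a along x)."""
    t = np.asarray(tensor, dtype=float)
    i_aa = t[0, 0] ** 2
    i_aa_perp = 0.5 * (t[0, 1] ** 2 + t[0, 2] ** 2)
    i_pp = (
        3.0 * t[1, 1] ** 2
        + 4.0 * t[1, 2] ** 2
        + 2.0 * t[1, 1] * t[2, 2]
        + 3.0 * t[2, 2] ** 2
    ) / 8.0
    return float(i_aa), float(i_aa_perp), float(i_pp)


def thermal_prefactor(nu_cm1: float, config: SpectrumConfig) -> float:
    """Placzek intensity prefactor (nu_L - nu)^4 / nu with Bose occupation.

    Acoustic and imaginary modes carry no Raman band: nu <= 0 raises.
    """
    if nu_cm1 <= 0:
        raise ParameterError("thermal prefactor requires a positive wavenumber")
    bose = 1.0 / (1.0 - np.exp(-HC_OVER_KB_CM_K * nu_cm1 / config.temperature))
    return float((config.laser_cm1 - nu_cm1) ** 4 / nu_cm1 * bose)


def synthesize(
    frequencies: np.ndarray, intensities: np.ndarray, config: SpectrumConfig | None = None
) -> Spectrum:
    """Sum of Lorentzian bands with peak height proportional to intensity.

    Only strictly positive frequencies contribute; negative (imaginary) and
    zero entries are ignored.
    """
    config = config or SpectrumConfig()
    frequencies = np.asarray(frequencies, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if frequencies.shape != intensities.shape:
        raise ConfigError("frequencies and intensities must have equal length")
    keep = frequencies > 0
    grid = config.grid
    total = np.zeros_like(grid)
    half = 0.5 * config.fwhm_cm1
    for nu, inten in zip(frequencies[keep], intensities[keep]):
        total += inten * half**2 / ((grid - nu) ** 2 + half**2)
    return Spectrum(grid, total)


def mode_spectrum(
    tensors: RamanTensorSet,
    config: SpectrumConfig | None = None,
    geometry: str = "powder",
    thermal: bool = True,
) -> Spectrum:
    """Synthesize a spectrum for one scattering geometry from a mode tensor set.

    ``geometry``: "powder" (unanalyzed orientational average), "aa", "aaperp"
    or "aperpaperp" (the marginalized single-crystal channels).  With
    ``thermal`` the Placzek/Bose prefactor multiplies each band (raw
    activities otherwise).
    """
    config = config or SpectrumConfig()
    raw = []
    for t in tensors.tensors:
        if geometry == "powder":
            raw.append(powder_intensity(t))
        else:
            i_aa, i_ap, i_pp = marginalized_intensities(t)
            raw.append({"aa": i_aa, "aaperp": i_ap, "aperpaperp": i_pp}[geometry])
    raw = np.asarray(raw)
    freqs = tensors.frequencies_cm1
    if thermal:
        pref = np.array([thermal_prefactor(nu, config) if nu > 0 else 0.0 for nu in freqs])
        raw = raw * pref
    return synthesize(freqs, raw, config)


def similarity(s1: Spectrum, s2: Spectrum, window: tuple[float, float] | None = None) -> float:
    """Cosine similarity of mean-subtracted intensities over the overlapping grid."""
    lo = max(s1.wavenumber[0], s2.wavenumber[0])
    hi = min(s1.wavenumber[-1], s2.wavenumber[-1])
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    mask = (s1.wavenumber >= lo) & (s1.wavenumber <= hi)
    if not np.any(mask):
        raise ConfigError("spectra have no overlapping wavenumber range")
    grid = s1.wavenumber[mask]
    a = s1.intensity[mask]
    b = np.interp(grid, s2.wavenumber, s2.intensity)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ConfigError("flat spectrum in the comparison range")
    return float(np.dot(a, b) / denom)
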