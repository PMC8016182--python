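"""Polymorph composition mapping from spatial grids of low-wavenumber Raman spectra.

Each map point is quantified by baseline-corrected integrals over two
phase-diagnostic spectral windows (defaults: 53-59 cm^-1 for phase I,
30-36 cm^-1 for phase II), normalized by the corresponding pure-phase
reference integrals, and combined into the two-window ratio estimator

    fraction_II = w_II / (w_I + w_II),   w_X = W_X / reference_X.

Points where both normalized window signals fall below a no-signal threshold
(substrate-only spots) are flagged and reported as missing rather than 0.5.
The linear-endpoint baseline removes the sloped glass-substrate background
that low-wavenumber spectra typically ride on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError, WindowError
from .raman import Spectrum

__all__ = [
    "MapGrid",
    "WindowConfig",
    "CompositionMap",
    "PhaseFraction",
    "window_integral",
    "phase_fraction",
    "build_map",
    "read_map_csv",
    "write_map_csv",
]


@dataclass
class MapGrid:
    """Spatial grid of spectra; all points share one wavenumber grid."""

    points: list[tuple[float, float, Spectrum]]

    def __post_init__(self) -> None:
        if not self.points:
            raise ConfigError("empty map grid")
        ref = self.points[0][2].wavenumber
        for x, y, s in self.points:
            if s.wavenumber.shape != ref.shape or not np.allclose(s.wavenumber, ref):
                raise WindowError(f"point ({x}, {y}) has an inconsistent wavenumber grid")
        coords = [(x, y) for x, y, _ in self.points]
        if len(set(coords)) != len(coords):
            raise ConfigError("duplicate map points")


@dataclass
class WindowConfig:
    """Spectral windows, baseline choice and pure-phase reference integrals."""

    window_I: tuple[float, float] = (53.0, 59.0)
    window_II: tuple[float, float] = (30.0, 36.0)
    baseline: str = "linear"  # "linear" (endpoint line) or "none"
    reference_I: float | None = None
    reference_II: float | None = None
    no_signal_frac: float = 0.01

    def __post_init__(self) -> None:
        for lo, hi in (self.window_I, self.window_II):
            if lo >= hi:
                raise ConfigError(f"window ({lo}, {hi}) must have lo < hi")
        a, b = sorted([self.window_I, self.window_II])
        if a[1] > b[0]:
            raise ConfigError("the two windows must be disjoint")
        if self.baseline not in ("linear", "none"):
            raise ConfigError(f"unknown baseline {self.baseline!r}")
        for ref in (self.reference_I, self.reference_II):
            if ref is not None and ref <= 0:
                raise ConfigError("reference integrals must be positive")

    def with_references(self, pure_I: Spectrum, pure_II: Spectrum) -> "WindowConfig":
        """Set the normalization references from pure-phase spectra."""
        ref_i = window_integral(pure_I, self.window_I, self.baseline)
        ref_ii = window_integral(pure_II, self.window_II, self.baseline)
        if ref_i <= 0 or ref_ii <= 0:
            raise ConfigError("pure-phase spectra carry no signal in their windows")
        return WindowConfig(
            self.window_I, self.window_II, self.baseline, ref_i, ref_ii, self.no_signal_frac
        )


class PhaseFraction(NamedTuple):
    fraction_II: float  # nan when no_signal
    no_signal: bool


@dataclass
class CompositionMap:
    """Per-point phase-II fraction in [0, 1] (nan where no signal was found)."""

    x: np.ndarray
    y: np.ndarray
    fraction_II: np.ndarray
    no_signal: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.no_signal is None:
            self.no_signal = np.isnan(self.fraction_II)
        valid = self.fraction_II[~self.no_signal]
        if np.any((valid < 0) | (valid > 1)):
            raise ConfigError("fractions must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "fraction_II": self.fraction_II,
                "no_signal": self.no_signal,
            }
        )

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


def signed_window_integral(
    spectrum: Spectrum, window: tuple[float, float], baseline: str = "linear"
) -> float:
    """Trapezoidal area of a spectral window, optionally above the endpoint line.

    Unlike :func:`window_integral` the result keeps its sign (a spectrum convex
    across the window has negative baseline-corrected area).
    """
    lo, hi = window
    wn, inten = spectrum.wavenumber, spectrum.intensity
    if lo < wn[0] - 1e-9 or hi > wn[-1] + 1e-9:
        raise WindowError(
            f"window ({lo}, {hi}) outside the spectrum grid ({wn[0]}, {wn[-1]})"
        )
    inner = (wn > lo) & (wn < hi)
    xs = np.concatenate(([lo], wn[inner], [hi]))
    ys = np.concatenate(
        ([np.interp(lo, wn, inten)], inten[inner], [np.interp(hi, wn, inten)])
    )
    if baseline == "linear":
        ys = ys - np.interp(xs, [lo, hi], [ys[0], ys[-1]])
    elif baseline != "none":
        raise ConfigError(f"unknown baseline {baseline!r}")
    return float(np.trapezoid(ys, xs))


def window_integral(
    spectrum: Spectrum, window: tuple[float, float], baseline: str = "linear"
) -> float:
    """Baseline-corrected window area, clipped at zero (noise can dip below)."""
    return max(signed_window_integral(spectrum, window, baseline), 0.0)


def phase_fraction(spectrum: Spectrum, cfg: WindowConfig) -> PhaseFraction:
    """Two-window ratio estimate of the phase-II fraction for one spectrum."""
    if cfg.reference_I is None or cfg.reference_II is None:
        raise ConfigError("reference integrals are not set (use with_references)")
    w_i = window_integral(spectrum, cfg.window_I, cfg.baseline) / cfg.reference_I
    w_ii = window_integral(spectrum, cfg.window_II, cfg.baseline) / cfg.reference_II
    if w_i < cfg.no_signal_frac and w_ii < cfg.no_signal_frac:
        return PhaseFraction(float("nan"), True)
    frac = w_ii / (w_i + w_ii)
    return PhaseFraction(float(np.clip(frac, 0.0, 1.0)), False)


def build_map(grid: MapGrid, cfg: WindowConfig) -> CompositionMap:
    """Apply the window estimator at every grid point."""
    xs, ys, fracs, flags = [], [], [], []
    for x, y, s in grid.points:
        pf = phase_fraction(s, cfg)
        xs.append(x)
        ys.append(y)
        fracs.append(pf.fraction_II)
        flags.append(pf.no_signal)
    return CompositionMap(np.array(xs), np.array(ys), np.array(fracs), np.array(flags))


def write_map_csv(grid: MapGrid, path: str) -> None:
    """Long-format CSV: x, y, wavenumber, counts."""
    frames = []
    for x, y, s in grid.points:
        frames.append(
            pd.DataFrame(
                {"x": x, "y": y, "wavenumber": s.wavenumber, "counts": s.intensity}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_map_csv(path: str) -> MapGrid:
    df = pd.read_csv(path)
    needed = {"x", "y", "wavenumber", "counts"}
    if not needed.issubset(df.columns):
        raise ConfigError(f"map CSV must have columns {sorted(needed)}")
    points = []
    for (x, y), sub in df.groupby(["x", "y"], sort=True):
        sub = sub.sort_values("wavenumber")
        points.append(
            (float(x), float(y), Spectrum(sub["wavenumber"].to_numpy(), sub["counts"].to_numpy()))
        )
    return MapGrid(points)
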