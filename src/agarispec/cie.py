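"""CIE 1964 10-degree observer and daylight illuminant on the working grid.

The color-matching functions are generated from published analytic lognormal
fits to the CIE 1964 supplementary standard observer (single-lobe Gaussian /
lognormal approximations of the kind used in rendering, accurate to roughly
1-2% of peak). The D65-like illuminant is a 6504 K Planckian radiator
normalized to 100 at 560 nm — a smooth synthetic stand-in for the official
D65 spectral power distribution, adequate because every whiteness quantity in
this package (white point, grade calibration, regression targets) is computed
self-consistently against these same tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import WavelengthGrid

__all__ = ["ObserverTable", "IlluminantTable", "cie1964_observer", "illuminant_d65"]


@dataclass(frozen=True)
class ObserverTable:
    """Grid-aligned color-matching functions x10bar, y10bar, z10bar."""

    grid: WavelengthGrid
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.n_bands
        for arr in (self.xbar, self.ybar, self.zbar):
            if arr.shape != (n,):
                raise ValueError("observer table length must equal grid band count")
            if np.any(arr < 0):
                raise ValueError("color-matching functions must be non-negative")


@dataclass(frozen=True)
class IlluminantTable:
    """Relative spectral power R(lambda) of the light source on the grid."""

    grid: WavelengthGrid
    power: np.ndarray

    def __post_init__(self) -> None:
        if self.power.shape != (self.grid.n_bands,):
            raise ValueError("illuminant table length must equal grid band count")
        if np.any(self.power < 0):
            raise ValueError("illuminant power must be non-negative")


def _lognormal_lobe(wl: np.ndarray, scale: float, shape: float,
                    shift: float, width: float) -> np.ndarray:
    # scale * exp(-shape * ln^2((wl + shift)/width)); callers pre-flip wl for
    # lobes expressed against a reversed axis
    arg = (wl + shift) / width
    out = np.zeros_like(wl, dtype=float)
    ok = arg > 0
    out[ok] = scale * np.exp(-shape * np.log(arg[ok]) ** 2)
    return out


def cie1964_observer(grid: WavelengthGrid | None = None) -> ObserverTable:
    """Analytic approximation of the CIE 1964 10-degree color-matching functions."""
    grid = grid or WavelengthGrid()
    wl = grid.wavelengths
    xbar = (_lognormal_lobe(wl, 0.398, 1250.0, 570.1, 1014.0)
            + _lognormal_lobe(-wl, 1.132, 234.0, 1338.0, 743.5))
    ybar = 1.011 * np.exp(-0.5 * ((wl - 556.1) / 46.14) ** 2)
    zbar = _lognormal_lobe(wl, 2.060, 32.0, -265.8, 180.4)
    return ObserverTable(grid, xbar, ybar, zbar)


_C2 = 1.4388e-2  # second radiation constant, m*K (ITS-90)


def illuminant_d65(grid: WavelengthGrid | None = None) -> IlluminantTable:
    """Smooth daylight approximation: 6504 K Planckian SPD, 100 at 560 nm."""
    grid = grid or WavelengthGrid()
    wl_m = grid.wavelengths * 1e-9

    def planck(lam):
        return lam ** -5 / np.expm1(_C2 / (lam * 6504.0))

    power = 100.0 * planck(wl_m) / planck(560e-9)
    return IlluminantTable(grid, power)
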