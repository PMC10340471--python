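"""Inter-instrument spectral calibration by a per-band mean offset.

A reference spectrometer and the portable device measure the same samples;
the per-band mean difference P-bar is learned from the pairs and added to
subsequent device spectra. Two sign conventions are provided:

* ``reference_minus_device`` (default): delta = P1 - P2, so that applying
  the offset moves device spectra onto the reference instrument's scale;
* ``paper_literal``: delta = P2 - P1, the literal printed form, kept for
  fidelity even though applying it moves device spectra away from the
  reference.

Calibration is offset-only; no gain term and no wavelength registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra import SpectrumSet, WavelengthGrid

__all__ = ["CalibrationOffset", "fit_offset", "apply_offset", "agreement_pearson"]

_CONVENTIONS = ("reference_minus_device", "paper_literal")


@dataclass
class CalibrationOffset:
    """Per-band mean difference between paired reference and device spectra."""

    grid: WavelengthGrid
    mean_delta: np.ndarray
    n_pairs: int
    sign_convention: str = "reference_minus_device"

    def __post_init__(self) -> None:
        self.mean_delta = np.asarray(self.mean_delta, dtype=float)
        if self.mean_delta.shape != (self.grid.n_bands,):
            raise ValueError("offset vector length must equal grid band count")
        if self.n_pairs < 1:
            raise ValueError("need at least one calibration pair")
        if self.sign_convention not in _CONVENTIONS:
            raise ValueError(f"sign_convention must be one of {_CONVENTIONS}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wavelength_nm": self.grid.wavelengths,
                             "mean_delta": self.mean_delta})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_pairs: int = 1,
                   sign_convention: str = "reference_minus_device") -> "CalibrationOffset":
        grid = WavelengthGrid.from_wavelengths(df["wavelength_nm"].to_numpy())
        return cls(grid, df["mean_delta"].to_numpy(), n_pairs, sign_convention)


def _check_aligned(a: SpectrumSet, b: SpectrumSet) -> None:
    if a.grid != b.grid:
        raise ValueError("spectrum sets live on different wavelength grids")
    if len(a) != len(b):
        raise ValueError(f"unpaired sets: {len(a)} vs {len(b)} samples")


def fit_offset(reference: SpectrumSet, device: SpectrumSet,
               sign_convention: str = "reference_minus_device") -> CalibrationOffset:
    """Mean per-band difference over all sample pairs."""
    _check_aligned(reference, device)
    if sign_convention == "reference_minus_device":
        delta = reference.values - device.values
    elif sign_convention == "paper_literal":
        delta = device.values - reference.values
    else:
        raise ValueError(f"sign_convention must be one of {_CONVENTIONS}")
    return CalibrationOffset(reference.grid, delta.mean(axis=0), len(reference),
                             sign_convention)


def apply_offset(device: SpectrumSet, offset: CalibrationOffset) -> SpectrumSet:
    """Calibrated spectra P' = P_device + P-bar (a pure per-band shift)."""
    if device.grid != offset.grid:
        raise ValueError("offset grid does not match spectra grid")
    return device.with_values(device.values + offset.mean_delta[None, :])


def agreement_pearson(a: SpectrumSet, b: SpectrumSet, *,
                      per_sample: bool = False):
    """Pearson r between paired instruments over all flattened values.

    With ``per_sample=True`` also returns the vector of per-sample r values.
    """
    _check_aligned(a, b)
    x = a.values.ravel()
    y = b.values.ravel()
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    if not per_sample:
        return r
    rs = np.array([stats.pearsonr(a.values[i], b.values[i]).statistic
                   for i in range(len(a))])
    return r, rs
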