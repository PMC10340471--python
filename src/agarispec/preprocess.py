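"""Spectral noise-reduction transforms: Savitzky-Golay, normalization, SNV, MSC.

All transforms preserve the band count and grid. SNV and normalization act
per spectrum; MSC is a set-level operation whose reference spectrum (by
default the mean of the fitting set) must be frozen on the training data and
reused for test spectra to avoid leakage — :class:`MscModel` holds it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "PreprocessConfig",
    "MscModel",
    "savitzky_golay",
    "normalize",
    "snv",
    "msc",
    "apply_preprocess",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Which transform to apply and its knobs.

    ``sg_window``/``sg_polyorder`` default to 7/2, a gentle smoother for
    1 nm-sampled visible spectra.
    """

    method: str = "msc"  # one of {"sg", "normalization", "snv", "msc"}
    sg_window: int = 7
    sg_polyorder: int = 2
    normalize_mode: str = "minmax"  # or "unit_vector"

    def __post_init__(self) -> None:
        if self.method not in ("sg", "normalization", "snv", "msc"):
            raise ValueError(f"unknown preprocessing method {self.method!r}")
        if self.sg_window < 3 or self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd and >= 3")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be below sg_window")


def _as_values(s) -> np.ndarray:
    return s.values if isinstance(s, (Spectrum, SpectrumSet)) else np.asarray(s, float)


def savitzky_golay(s: Spectrum, window: int = 7, polyorder: int = 2) -> Spectrum:
    """Local least-squares polynomial smoothing.

    Each band is replaced by the center value of a degree-``polyorder``
    polynomial fitted over ``window`` bands; edge bands take the fitted
    polynomial of the terminal window (scipy's 'interp' mode), keeping the
    spectrum length unchanged.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < polyorder + 1:
        raise ValueError("window must exceed the polynomial order")
    if s.values.size < window:
        raise ValueError("spectrum shorter than the smoothing window")
    out = savgol_filter(s.values, window, polyorder, mode="interp")
    return Spectrum(s.grid, out, s.sample_id)


def normalize(s: Spectrum, mode: str = "minmax") -> Spectrum:
    """Per-spectrum scaling: min-max to [0, 1] (default) or unit Euclidean norm."""
    v = s.values
    if mode == "minmax":
        rng = v.max() - v.min()
        if rng == 0:
            raise ValueError("constant spectrum: min-max normalization undefined")
        out = (v - v.min()) / rng
    elif mode == "unit_vector":
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise ValueError("zero spectrum: unit-vector normalization undefined")
        out = v / nrm
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return Spectrum(s.grid, out, s.sample_id)


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: (v - mean)/sd with the population (1/N) sd."""
    v = s.values
    sd = v.std()  # population convention, ddof=0
    if sd == 0:
        raise ValueError("constant spectrum: SNV undefined")
    return Spectrum(s.grid, (v - v.mean()) / sd, s.sample_id)


@dataclass
class MscModel:
    """Multiplicative scatter correction with a frozen reference spectrum."""

    reference: np.ndarray
    slope: np.ndarray = field(default=None)   # b_i of the last transform
    offset: np.ndarray = field(default=None)  # a_i of the last transform

    @classmethod
    def fit(cls, sset: SpectrumSet, reference: np.ndarray | None = None) -> "MscModel":
        if reference is None:
            if len(sset) < 2:
                raise ValueError("mean-spectrum MSC reference needs >= 2 spectra")
            reference = sset.values.mean(axis=0)
        reference = np.asarray(reference, dtype=float)
        if reference.shape != (sset.grid.n_bands,):
            raise ValueError("MSC reference must live on the set's grid")
        return cls(reference=reference)

    def transform(self, sset: SpectrumSet) -> SpectrumSet:
        """Fit each spectrum s = a + b*ref by OLS over bands; return (s - a)/b."""
        ref = self.reference
        rc = ref - ref.mean()
        denom = float(rc @ rc)
        V = sset.values
        b = (V - V.mean(axis=1, keepdims=True)) @ rc / denom
        if np.any(np.abs(b) < 1e-12):
            raise ValueError("MSC slope estimate is ~0 for at least one spectrum")
        a = V.mean(axis=1) - b * ref.mean()
        self.slope, self.offset = b, a
        return sset.with_values((V - a[:, None]) / b[:, None])


def msc(sset: SpectrumSet, reference: np.ndarray | None = None
        ) -> tuple[SpectrumSet, MscModel]:
    """One-shot MSC: fit the reference on ``sset`` and correct it."""
    model = MscModel.fit(sset, reference)
    return model.transform(sset), model


def apply_preprocess(sset: SpectrumSet, config: PreprocessConfig,
                     msc_model: MscModel | None = None
                     ) -> tuple[SpectrumSet, MscModel | None]:
    """Apply the configured transform to a whole set.

    For MSC, pass a previously fitted ``msc_model`` to reuse a training
    reference on new spectra; otherwise one is fitted on ``sset``.
    """
    if config.method == "msc":
        if msc_model is None:
            msc_model = MscModel.fit(sset)
        return msc_model.transform(sset), msc_model
    if config.method == "sg":
        rows = [savitzky_golay(sset[i], config.sg_window, config.sg_polyorder).values
                for i in range(len(sset))]
    elif config.method == "normalization":
        rows = [normalize(sset[i], config.normalize_mode).values
                for i in range(len(sset))]
    else:  # snv
        rows = [snv(sset[i]).values for i in range(len(sset))]
    return sset.with_values(np.vstack(rows)), None
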