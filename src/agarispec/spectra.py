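"""Core data model, I/O and shared metrics for reflectance spectra.

The whole pipeline trades in :class:`SpectrumSet` objects: a sample-by-band
reflectance matrix on a shared, strictly increasing wavelength grid, with
optional per-sample labels (gravimetric moisture content in %, whiteness
grade 1-4, or a continuous whiteness value).

The on-disk format is a plain UTF-8 CSV: ``sample_id`` first, one column per
wavelength (header is the wavelength in nm), then any label columns
(``moisture_pct``, ``grade``, ``whiteness``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectrumSet",
    "ModelMetrics",
    "MoistureSample",
    "SpectraFormatError",
    "read_spectra",
    "write_spectra",
    "moisture_content",
    "r2_score",
    "rmse",
    "split_train_test",
    "LABEL_COLUMNS",
]

LABEL_COLUMNS = ("moisture_pct", "grade", "whiteness")


class SpectraFormatError(ValueError):
    """Raised when a spectra CSV violates the on-disk contract."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nm; defaults cover 450-760 nm at 1 nm (311 bands)."""

    start_nm: float = 450.0
    end_nm: float = 760.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not (self.start_nm < self.end_nm):
            raise ValueError("grid start must be below end")
        if not (self.step_nm > 0):
            raise ValueError("grid step must be positive")
        n = (self.end_nm - self.start_nm) / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError("grid span must be an integer number of steps")

    @property
    def n_bands(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_bands)

    @classmethod
    def from_wavelengths(cls, wl: np.ndarray) -> "WavelengthGrid":
        wl = np.asarray(wl, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise SpectraFormatError("need at least two wavelength columns")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise SpectraFormatError("non-monotone grid: wavelengths must strictly increase")
        if not np.allclose(steps, steps[0], atol=1e-6):
            raise SpectraFormatError("non-uniform grid: wavelength spacing varies")
        return cls(float(wl[0]), float(wl[-1]), float(steps[0]))


@dataclass
class Spectrum:
    """A single reflectance spectrum on a grid; values are reflectance fractions."""

    grid: WavelengthGrid
    values: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bands,):
            raise ValueError(
                f"spectrum has {self.values.size} values for a {self.grid.n_bands}-band grid"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")


@dataclass
class SpectrumSet:
    """An ordered collection of spectra sharing one grid, with optional labels.

    ``values`` is the (n_samples, n_bands) reflectance matrix — the natural
    currency for chemometric operations. ``labels`` holds any of the columns
    in :data:`LABEL_COLUMNS`, aligned row-for-row with ``values``.
    """

    grid: WavelengthGrid
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.grid.n_bands and self.values.size > 0:
            raise ValueError(
                f"value matrix has {self.values.shape[1]} bands, grid has {self.grid.n_bands}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length does not match number of spectra")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain non-finite values")
        if self.labels is not None:
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("label count does not match spectrum count")
            self.labels = self.labels.reset_index(drop=True)

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.values[i], self.sample_ids[i])

    def subset(self, idx) -> "SpectrumSet":
        idx = np.asarray(idx)
        labels = self.labels.iloc[idx] if self.labels is not None else None
        return SpectrumSet(
            self.grid,
            self.values[idx],
            [self.sample_ids[i] for i in idx],
            labels,
        )

    def with_values(self, values: np.ndarray) -> "SpectrumSet":
        """Same samples and labels, new reflectance matrix (used by transforms)."""
        return SpectrumSet(self.grid, values, list(self.sample_ids), self.labels)

    def label(self, column: str) -> np.ndarray:
        if self.labels is None or column not in self.labels.columns:
            raise KeyError(f"label column {column!r} not present")
        return self.labels[column].to_numpy()


@dataclass
class ModelMetrics:
    """Train/test determination coefficients and RMSEs (RC2/RMSEC, Rp2/RMSEP)."""

    r2_train: float
    rmse_train: float
    r2_test: float
    rmse_test: float

    def as_dict(self) -> dict:
        return {
            "RC2": self.r2_train,
            "RMSEC": self.rmse_train,
            "Rp2": self.r2_test,
            "RMSEP": self.rmse_test,
        }


@dataclass(frozen=True)
class MoistureSample:
    """Fresh (m1) and oven-dry (m2) masses in grams for one sample cut."""

    m1: float
    m2: float

    def __post_init__(self) -> None:
        if not (self.m1 > 0):
            raise ValueError("fresh mass m1 must be positive")
        if self.m2 < 0:
            raise ValueError("dry mass m2 must be non-negative")
        if self.m2 > self.m1:
            raise ValueError("negative moisture: dry mass exceeds fresh mass")


def moisture_content(sample: MoistureSample | None = None, *, m1: float | None = None,
                     m2: float | None = None) -> float:
    """Wet-basis moisture content in percent: 100*(m1 - m2)/m1.

    Accepts either a :class:`MoistureSample` or the two masses as keywords.
    Warns (without failing) when the fresh cut falls outside the 4-7 g window
    the drying protocol expects.
    """
    if sample is None:
        if m1 is None or m2 is None:
            raise TypeError("provide a MoistureSample or both m1 and m2")
        sample = MoistureSample(m1, m2)
    if not (4.0 <= sample.m1 <= 7.0):
        warnings.warn(
            f"fresh mass {sample.m1:.3f} g outside the expected 4-7 g window",
            stacklevel=2,
        )
    return 100.0 * (sample.m1 - sample.m2) / sample.m1


def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("r2_score needs two equal-length vectors of size >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("undefined R2: y_true is constant")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error, in the units of the target variable."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("rmse needs two equal-length non-empty vectors")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def split_train_test(sset: SpectrumSet, seed: int, test_fraction: float = 0.2
                     ) -> tuple[SpectrumSet, SpectrumSet]:
    """Random disjoint 4:1 train/test partition, reproducible for a fixed seed.

    The test-set size is round(n * test_fraction); with the default 1/5
    fraction this reproduces 160/40 at n=200 and 128/32 at n=160.
    """
    n = len(sset)
    if n < 5:
        raise ValueError("need at least 5 samples to split 4:1")
    n_test = int(np.floor(n * test_fraction + 0.5))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:n_test])
    train_idx = np.sort(perm[n_test:])
    return sset.subset(train_idx), sset.subset(test_idx)


def read_spectra(path) -> SpectrumSet:
    """Read a spectra CSV (see module docstring for the dialect)."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 3 or df.columns[0] != "sample_id":
        raise SpectraFormatError("expected 'sample_id' first, then wavelength columns")
    wl_cols, label_cols = [], []
    for c in df.columns[1:]:
        if c in LABEL_COLUMNS:
            label_cols.append(c)
        else:
            try:
                float(c)
            except ValueError:
                raise SpectraFormatError(f"unrecognized column {c!r}") from None
            wl_cols.append(c)
    grid = WavelengthGrid.from_wavelengths(np.array([float(c) for c in wl_cols]))
    raw = df[wl_cols]
    values = np.empty((len(df), len(wl_cols)))
    for j, c in enumerate(wl_cols):
        col = pd.to_numeric(raw[c], errors="coerce")
        bad = np.nonzero(col.isna().to_numpy())[0]
        if bad.size:
            raise SpectraFormatError(
                f"row {bad[0]} (sample_id={df['sample_id'].iloc[bad[0]]!r}), "
                f"column {c}: missing or non-numeric value"
            )
        values[:, j] = col.to_numpy()
    labels = None
    if label_cols:
        labels = pd.DataFrame(
            {c: pd.to_numeric(df[c], errors="coerce") for c in label_cols}
        )
    return SpectrumSet(grid, values, df["sample_id"].tolist(), labels)


def write_spectra(sset: SpectrumSet, path) -> None:
    """Write a spectra CSV; fixed %.12g formatting makes output byte-stable."""
    wl = sset.grid.wavelengths
    header = ["sample_id"] + [f"{w:g}" for w in wl]
    if sset.labels is not None:
        header += list(sset.labels.columns)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(header) + "\n")
        for i in range(len(sset)):
            row = [sset.sample_ids[i]] + [f"{v:.12g}" for v in sset.values[i]]
            if sset.labels is not None:
                row += [f"{v:.12g}" for v in sset.labels.iloc[i]]
            fh.write(",".join(row) + "\n")
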