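"""CIE 1964 tristimulus values, Ganz whiteness and 4-level grading.

Tristimulus values are computed by the CIE equal-interval wavelength method
over 450-760 nm:

    X10 = K * sum( delta(l) * R(l) * x10bar(l) * dl )     (likewise Y10, Z10)

with delta the sample reflectance, R the illuminant power and, by default,
the standard normalization K = 100 / sum(R * y10bar * dl) so that a perfect
reflector has Y10 = 100 and real samples have Y10 < 100. A ``paper_literal_k``
flag instead folds the sample reflectance into K (which forces Y10 = 100 for
every sample); it exists only to reproduce that alternative convention.

Whiteness is the Ganz index W10 = Y10 + 800(xn - x10) + 1700(yn - y10)
relative to a reference white (default: the white point of the configured
illuminant/observer pair), graded into 4 browning levels via fixed thresholds
between the calibrated whiteness ranges of each grade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cie import IlluminantTable, ObserverTable, cie1964_observer, illuminant_d65
from .spectra import Spectrum, SpectrumSet, WavelengthGrid

__all__ = [
    "WhiteboardReference",
    "WhitenessResult",
    "GRADE_THRESHOLDS",
    "GRADE_RANGES",
    "tristimulus",
    "chromaticity",
    "ganz_whiteness",
    "grade_whiteness",
    "white_point",
    "whiteness_pipeline",
]

# Calibrated whiteness range per grade level 1-4 (pure white .. yellow-brown)
GRADE_RANGES = {
    1: (61.05, 81.84),
    2: (34.23, 49.70),
    3: (25.08, 34.66),
    4: (13.15, 22.81),
}
# Decision boundaries between adjacent grades: midpoints of the adjacent
# range endpoints (for grades 2/3 the printed ranges overlap slightly, so the
# midpoint of the overlap is used).
GRADE_THRESHOLDS = (55.375, 34.445, 23.945)


@dataclass(frozen=True)
class WhiteboardReference:
    """Chromaticity (xn, yn) of the standard whiteboard under the illuminant."""

    xn: float
    yn: float

    def __post_init__(self) -> None:
        if not (0 < self.xn < 1 and 0 < self.yn < 1):
            raise ValueError("whiteboard chromaticity must lie in (0, 1)")


@dataclass
class WhitenessResult:
    sample_id: str
    X10: float
    Y10: float
    Z10: float
    x10: float
    y10: float
    K: float
    W10: float
    grade: int
    flag: str = ""


def _check_grids(*grids: WavelengthGrid) -> None:
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise ValueError("spectrum, illuminant and observer must share one grid")


def tristimulus(spectrum: Spectrum, illuminant: IlluminantTable | None = None,
                observer: ObserverTable | None = None, *,
                paper_literal_k: bool = False) -> tuple[float, float, float, float]:
    """Return (X10, Y10, Z10, K) for one reflectance spectrum."""
    grid = spectrum.grid
    illuminant = illuminant or illuminant_d65(grid)
    observer = observer or cie1964_observer(grid)
    _check_grids(grid, illuminant.grid, observer.grid)
    dl = grid.step_nm
    # composite trapezoid weights: the color-matching functions are truncated
    # at the 450/760 nm range edges, where a plain rectangle sum over-weights
    # the endpoints
    w = np.ones(grid.n_bands)
    w[0] = w[-1] = 0.5
    R, d = illuminant.power, spectrum.values
    denom_weight = R * d if paper_literal_k else R
    denom = float(np.sum(w * denom_weight * observer.ybar) * dl)
    if denom <= 0:
        raise ValueError("normalization sum is zero (all-zero illuminant?)")
    K = 100.0 / denom
    X = K * float(np.sum(w * d * R * observer.xbar) * dl)
    Y = K * float(np.sum(w * d * R * observer.ybar) * dl)
    Z = K * float(np.sum(w * d * R * observer.zbar) * dl)
    return X, Y, Z, K


def chromaticity(X10: float, Y10: float, Z10: float) -> tuple[float, float]:
    """Projective chromaticity coordinates x10 = X/(X+Y+Z), y10 = Y/(X+Y+Z)."""
    s = X10 + Y10 + Z10
    if s <= 0:
        raise ValueError("chromaticity undefined: tristimulus sum is zero")
    return X10 / s, Y10 / s


def ganz_whiteness(Y10: float, x10: float, y10: float,
                   ref: WhiteboardReference) -> float:
    """Ganz whiteness W10 = Y10 + 800(xn - x10) + 1700(yn - y10), unclamped."""
    return Y10 + 800.0 * (ref.xn - x10) + 1700.0 * (ref.yn - y10)


def grade_whiteness(w10: float) -> tuple[int, str]:
    """Map a whiteness value to browning level 1-4.

    Returns ``(level, flag)`` where flag is '' for values inside a calibrated
    range, 'gap region' for values between ranges, and 'out of calibration'
    for values beyond the calibrated extremes (graded to the nearest level).
    """
    if not np.isfinite(w10):
        raise ValueError("whiteness value must be finite")
    t1, t2, t3 = GRADE_THRESHOLDS
    if w10 >= t1:
        level = 1
    elif w10 >= t2:
        level = 2
    elif w10 >= t3:
        level = 3
    else:
        level = 4
    lo, hi = GRADE_RANGES[4][0], GRADE_RANGES[1][1]
    if w10 > hi or w10 < lo:
        return level, "out of calibration"
    in_any = any(a <= w10 <= b for a, b in GRADE_RANGES.values())
    return level, ("" if in_any else "gap region")


def white_point(illuminant: IlluminantTable | None = None,
                observer: ObserverTable | None = None,
                grid: WavelengthGrid | None = None) -> WhiteboardReference:
    """Chromaticity of the perfect reflector — the default whiteboard."""
    grid = grid or (illuminant.grid if illuminant else WavelengthGrid())
    ones = Spectrum(grid, np.ones(grid.n_bands), "white")
    X, Y, Z, _ = tristimulus(ones, illuminant, observer)
    return WhiteboardReference(*chromaticity(X, Y, Z))


def whiteness_pipeline(sset: SpectrumSet, ref: WhiteboardReference | None = None,
                       illuminant: IlluminantTable | None = None,
                       observer: ObserverTable | None = None, *,
                       paper_literal_k: bool = False) -> list[WhitenessResult]:
    """Tristimulus -> chromaticity -> Ganz whiteness -> grade, per sample."""
    illuminant = illuminant or illuminant_d65(sset.grid)
    observer = observer or cie1964_observer(sset.grid)
    ref = ref or white_point(illuminant, observer)
    out = []
    for i in range(len(sset)):
        sp = sset[i]
        X, Y, Z, K = tristimulus(sp, illuminant, observer,
                                 paper_literal_k=paper_literal_k)
        x, y = chromaticity(X, Y, Z)
        w = ganz_whiteness(Y, x, y, ref)
        level, flag = grade_whiteness(w)
        out.append(WhitenessResult(sp.sample_id, X, Y, Z, x, y, K, w, level, flag))
    return out
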