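"""Standard-scattering-shift (SSS) axis correction — the comparator method.

Chemical standards with certified Raman peak positions (ASTM E1840:
acetaminophen and cyclohexane, packaged in ``data/astm_e1840_standards.csv``)
are measured on the instrument to be corrected. Each certified peak is
located in the measured spectrum, the displacement (measured - reference)
is fitted linearly against the reference position, and the spectrum's axis
is corrected by that linear model followed by linear interpolation onto
the master axis. Being linear in the axis, SSS cannot follow a genuinely
non-linear (piecewise) displacement; that is exactly the gap the
moving-window method closes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import Spectrum, resample_to_master

__all__ = [
    "StandardPeakTable",
    "LinearShiftModel",
    "load_standard_table",
    "pick_peaks",
    "fit_shift_model",
    "sss_correct",
]


@dataclass(frozen=True)
class StandardPeakTable:
    """Certified Raman shift positions of chemical standards."""

    table: pd.DataFrame  # columns: compound, shift_cm1, sd_cm1

    def __post_init__(self) -> None:
        required = {"compound", "shift_cm1"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"table must have columns {sorted(required)}")
        dup = self.table.duplicated(subset=["compound", "shift_cm1"])
        if dup.any():
            raise ValueError("duplicate (compound, shift) entries")

    @property
    def shifts(self) -> np.ndarray:
        return self.table["shift_cm1"].to_numpy(dtype=float)

    def for_compound(self, name: str) -> "StandardPeakTable":
        sub = self.table[self.table["compound"].str.lower() == name.lower()]
        if sub.empty:
            raise KeyError(f"no standard named {name!r}")
        return StandardPeakTable(sub.reset_index(drop=True))


def load_standard_table(path: str | Path | None = None) -> StandardPeakTable:
    """Load a standards table CSV; defaults to the packaged ASTM E1840 one."""
    if path is None:
        ref = resources.files("ramansync").joinpath("data/astm_e1840_standards.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    return StandardPeakTable(df)


@dataclass(frozen=True)
class LinearShiftModel:
    """displacement(x) = intercept + slope * x, in cm^-1."""

    slope: float
    intercept: float
    residuals: np.ndarray  # per-peak displacement residuals, cm^-1
    n_peaks: int

    def displacement(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def pick_peaks(
    s: Spectrum, expected: StandardPeakTable, tol: float = 10.0
) -> list[tuple[float, float]]:
    """Locate each certified peak in a measured (preprocessed) spectrum.

    For each table entry the local intensity maximum within ``tol`` cm^-1
    of the certified position is taken and its apex refined by a 3-point
    parabolic fit. Entries without a local maximum in range are skipped.
    Returns (reference_shift, measured_shift) pairs.

    The default tolerance, 10 cm^-1, is roughly three times the spectral
    resolution of typical portable instruments (3-3.5 cm^-1).
    """
    axis, y = s.axis, s.intensity
    pairs: list[tuple[float, float]] = []
    for ref_shift in expected.shifts:
        lo, hi = np.searchsorted(axis, [ref_shift - tol, ref_shift + tol])
        if hi - lo < 3:
            continue
        seg = y[lo:hi]
        k = int(np.argmax(seg)) + lo
        if k <= lo or k >= hi - 1:
            continue  # maximum on the search boundary: not a local peak
        if not (y[k] > y[k - 1] or y[k] > y[k + 1]):
            continue  # flat: no peak here
        measured = _parabolic_apex(axis[k - 1 : k + 2], y[k - 1 : k + 2])
        pairs.append((float(ref_shift), measured))
    if len(pairs) < 2:
        raise ValueError(f"only {len(pairs)} standard peaks found; need at least 2")
    return pairs


def _parabolic_apex(x3: np.ndarray, y3: np.ndarray) -> float:
    # vertex of the parabola through three points; falls back to the middle
    # sample when the points are collinear
    denom = (y3[0] - 2 * y3[1] + y3[2])
    if denom == 0:
        return float(x3[1])
    # assumes locally uniform spacing, exact for symmetric peaks
    delta = 0.5 * (y3[0] - y3[2]) / denom
    return float(x3[1] + delta * (x3[2] - x3[0]) / 2.0)


def fit_shift_model(pairs: list[tuple[float, float]]) -> LinearShiftModel:
    """Ordinary least squares of displacement against reference position."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 (reference, measured) pairs")
    ref = np.array([p[0] for p in pairs])
    measured = np.array([p[1] for p in pairs])
    if np.unique(ref).size < 2:
        raise ValueError("degenerate fit: all reference positions identical")
    disp = measured - ref
    fit = stats.linregress(ref, disp)
    residuals = disp - (fit.intercept + fit.slope * ref)
    return LinearShiftModel(float(fit.slope), float(fit.intercept), residuals, len(pairs))


def sss_correct(
    s: Spectrum, model: LinearShiftModel, master_axis: np.ndarray
) -> Spectrum:
    """Correct the axis by the fitted linear displacement and resample.

    Each measured axis value x is mapped to ``x - displacement(x)`` — the
    position it should have had on the master instrument — and the
    intensity is linearly re-interpolated onto the master axis.
    """
    corrected_axis = s.axis - model.displacement(s.axis)
    if np.any(np.diff(corrected_axis) <= 0):
        raise ValueError("corrected axis not strictly increasing; |slope| too large")
    moved = Spectrum(corrected_axis, s.intensity, {**s.meta, "sss_corrected": True})
    return resample_to_master(moved, np.asarray(master_axis, dtype=float))
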