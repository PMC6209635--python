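"""Reading, writing, validating and resampling Raman spectra.

A spectrum is a pair of equal-length vectors: a strictly increasing Raman
shift axis (cm^-1) and the measured intensity (arbitrary detector counts).
On disk a spectrum is a two-column delimited text file (comma or tab,
autodetected), with optional ``#``-prefixed comment lines; metadata may be
carried in those comments as ``# key: value`` pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumPair",
    "SpectrumIOError",
    "read_spectrum",
    "write_spectrum",
    "resample_to_master",
    "crop",
]


class SpectrumIOError(ValueError):
    """Raised when a spectrum file or vector pair violates the format contract."""


@dataclass(frozen=True)
class Spectrum:
    """One acquisition: Raman-shift axis plus intensity vector.

    Parameters
    ----------
    axis
        Raman shift values in cm^-1, strictly increasing, length N >= 2.
    intensity
        Detector counts (arbitrary units), same length as ``axis``.
    meta
        Free-form provenance (instrument id, sample id, replicate index, ...).
    """

    axis: np.ndarray
    intensity: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        if axis.ndim != 1 or intensity.ndim != 1:
            raise SpectrumIOError("axis and intensity must be 1-D vectors")
        if axis.size != intensity.size:
            raise SpectrumIOError(
                f"axis length {axis.size} != intensity length {intensity.size}"
            )
        if axis.size < 2:
            raise SpectrumIOError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(axis)) and np.all(np.isfinite(intensity))):
            raise SpectrumIOError("axis/intensity contain NaN or Inf")
        if np.any(np.diff(axis) <= 0):
            raise SpectrumIOError("axis must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.axis.size)

    def replace_intensity(self, intensity: np.ndarray, **meta: Any) -> "Spectrum":
        """Same axis, new intensity; extra keyword pairs merged into meta."""
        return Spectrum(self.axis, np.asarray(intensity, float), {**self.meta, **meta})

    def step(self) -> float:
        """Median axis spacing in cm^-1 (local spacing may vary slightly)."""
        return float(np.median(np.diff(self.axis)))


@dataclass(frozen=True)
class SpectrumPair:
    """A reference ("master"/primary) spectrum and the spectrum to be
    synchronized toward it ("slave"/secondary), on a common axis."""

    primary: Spectrum
    secondary: Spectrum

    def __post_init__(self) -> None:
        if self.primary.n != self.secondary.n or not np.array_equal(
            self.primary.axis, self.secondary.axis
        ):
            raise SpectrumIOError("pair members must share an identical axis")

    @property
    def axis(self) -> np.ndarray:
        return self.primary.axis

    @property
    def n(self) -> int:
        return self.primary.n


_META_RE = re.compile(r"^#\s*([\w.-]+)\s*:\s*(.*)$")


def read_spectrum(
    path: str | Path,
    *,
    delimiter: str | None = None,
    comment: str = "#",
) -> Spectrum:
    """Read a two-column (axis, intensity) delimited text spectrum.

    The delimiter is autodetected (comma, tab, semicolon or whitespace)
    unless given. Rows are sorted by axis; duplicate axis values are
    rejected. ``# key: value`` comment lines populate ``meta``.
    """
    path = Path(path)
    meta: dict[str, Any] = {"path": str(path)}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(comment):
                m = _META_RE.match(line)
                if m:
                    meta[m.group(1)] = m.group(2)
                continue
            sep = delimiter
            if sep is None:
                for cand in (",", "\t", ";"):
                    if cand in line:
                        sep = cand
                        break
            parts = line.split(sep) if sep else line.split()
            parts = [p for p in parts if p]
            if len(parts) < 2:
                raise SpectrumIOError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise SpectrumIOError(f"{path}:{lineno}: non-numeric value in {line!r}") from exc
    if len(rows) < 2:
        raise SpectrumIOError(f"{path}: fewer than 2 data rows")
    rows.sort(key=lambda t: t[0])
    axis = np.array([r[0] for r in rows])
    intensity = np.array([r[1] for r in rows])
    dup = np.flatnonzero(np.diff(axis) == 0)
    if dup.size:
        raise SpectrumIOError(
            f"{path}: duplicate axis value {axis[dup[0]]:g} (data row {dup[0] + 1})"
        )
    return Spectrum(axis, intensity, meta)


def write_spectrum(s: Spectrum, path: str | Path, *, delimiter: str = ",") -> None:
    """Write a spectrum as two-column delimited text with metadata comments."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in s.meta.items():
            if key == "path":
                continue
            fh.write(f"# {key}: {value}\n")
        for x, y in zip(s.axis, s.intensity):
            fh.write(f"{x:.6f}{delimiter}{y:.10g}\n")


def resample_to_master(s: Spectrum, master_axis: np.ndarray) -> Spectrum:
    """Linearly interpolate intensity onto ``master_axis``.

    Points outside the source range are filled with the nearest endpoint
    value (endpoint hold, no extrapolated signal) and flagged in meta.
    """
    master_axis = np.asarray(master_axis, dtype=float)
    if master_axis.ndim != 1 or master_axis.size < 2 or np.any(np.diff(master_axis) <= 0):
        raise SpectrumIOError("master axis must be a strictly increasing vector of length >= 2")
    if master_axis[-1] < s.axis[0] or master_axis[0] > s.axis[-1]:
        raise SpectrumIOError("no overlap between spectrum axis and master axis")
    if np.array_equal(master_axis, s.axis):
        return s
    intensity = np.interp(master_axis, s.axis, s.intensity)
    n_extrap = int(np.sum((master_axis < s.axis[0]) | (master_axis > s.axis[-1])))
    meta = dict(s.meta)
    meta["resampled"] = True
    if n_extrap:
        meta["endpoint_filled_points"] = n_extrap
    return Spectrum(master_axis, intensity, meta)


def crop(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep the points with ``lo <= axis <= hi`` (closed interval)."""
    if not lo < hi:
        raise SpectrumIOError(f"crop bounds must satisfy lo < hi, got {lo}, {hi}")
    mask = (s.axis >= lo) & (s.axis <= hi)
    if int(mask.sum()) < 2:
        raise SpectrumIOError(f"crop [{lo}, {hi}] leaves fewer than 2 points")
    if mask.all():
        return s
    return Spectrum(s.axis[mask], s.intensity[mask], {**s.meta, "cropped": (lo, hi)})


def common_pair(primary: Spectrum, secondary: Spectrum) -> SpectrumPair:
    """Put two spectra on the primary's axis (the master) and pair them."""
    return SpectrumPair(primary, resample_to_master(secondary, primary.axis))
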