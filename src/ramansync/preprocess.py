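"""Preprocessing applied before shift estimation and metric computation.

Pipeline order (when applied through :func:`preprocess_replicates`):
outlier screen -> replicate averaging -> baseline correction (airPLS) ->
Savitzky-Golay smoothing -> crop to the informative region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .spectra_io import Spectrum, crop as _crop

__all__ = [
    "PreprocessConfig",
    "baseline_airpls",
    "smooth_savgol",
    "average_replicates",
    "screen_outliers",
    "normalize",
    "preprocess_replicates",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    sg_window : odd Savitzky-Golay window length in points (default 9)
    sg_order : Savitzky-Golay polynomial order (default 2)
    airpls_lambda : Whittaker smoothness penalty; larger -> stiffer
        baseline (default 1e6, sized for ~2048-point spectra)
    airpls_maxiter : airPLS iteration cap
    crop_lo, crop_hi : informative spectral region bounds in cm^-1
    outlier_min_r : minimum Pearson correlation to the median replicate
    normalization : "minmax" or "unit" (unit-vector) scaling for distances
    """

    sg_window: int = 9
    sg_order: int = 2
    airpls_lambda: float = 1e6
    airpls_maxiter: int = 15
    crop_lo: float = 300.0
    crop_hi: float = 1700.0
    outlier_min_r: float = 0.95
    normalization: str = "minmax"

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if not self.sg_window > self.sg_order >= 1:
            raise ValueError("need sg_window > sg_order >= 1")
        if self.airpls_lambda <= 0:
            raise ValueError("airpls_lambda must be positive")
        if self.normalization not in ("minmax", "unit"):
            raise ValueError("normalization must be 'minmax' or 'unit'")


def _whittaker(y: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    # Penalized least squares with second-difference penalty:
    # minimize ||W^(1/2)(y - z)||^2 + lam ||D2 z||^2.
    n = y.size
    d = sparse.eye(n, format="csc")
    d = d[1:] - d[:-1]
    d = d[1:] - d[:-1]  # second differences, shape (n-2, n)
    wmat = sparse.diags(w, 0, format="csc")
    a = (wmat + lam * d.T @ d).tocsc()
    return spsolve(a, w * y)


def baseline_airpls(
    s: Spectrum, lam: float = 1e6, maxiter: int = 15
) -> tuple[Spectrum, Spectrum]:
    """Adaptive iteratively reweighted penalized least squares baseline.

    Fits a slowly varying baseline by Whittaker smoothing, iteratively
    down-weighting points that sit above the current baseline (peaks) and
    up-weighting points below it. Iteration stops when the summed magnitude
    of negative residuals drops below 0.1% of the total signal magnitude,
    or after ``maxiter`` rounds.

    Returns ``(corrected, baseline)`` with
    ``corrected.intensity == s.intensity - baseline.intensity``.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    y = s.intensity
    n = y.size
    total = np.abs(y).sum()
    w = np.ones(n)
    z = y.copy()
    prev_dssn = np.inf
    for it in range(1, maxiter + 1):
        z = _whittaker(y, w, lam)
        d = y - z
        neg = d[d < 0]
        dssn = np.abs(neg).sum()
        if dssn < 1e-3 * total or total == 0:
            break
        if dssn > 0.5 * prev_dssn:
            # stagnation guard: once the negative-residual mass stops
            # halving, further reweighting only chases noise valleys
            break
        prev_dssn = dssn
        # peaks (d >= 0) get zero weight; points below the baseline are
        # re-weighted exponentially, harder each iteration (exponent capped
        # against overflow)
        w = np.zeros(n)
        mask = d < 0
        w[mask] = np.exp(np.minimum(it * np.abs(d[mask]) / dssn, 50.0))
        w[0] = w[-1] = np.exp(min(it, 50))  # pin the ends to the signal
    baseline = s.replace_intensity(z, airpls=dict(lam=lam, iterations=it))
    corrected = s.replace_intensity(y - z, baseline_corrected=True)
    return corrected, baseline


def smooth_savgol(s: Spectrum, window: int = 9, order: int = 2) -> Spectrum:
    """Savitzky-Golay least-squares polynomial smoothing."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not window > order:
        raise ValueError("window must exceed polynomial order")
    if window > s.n:
        raise ValueError(f"window {window} exceeds spectrum length {s.n}")
    return s.replace_intensity(
        savgol_filter(s.intensity, window, order), smoothed=(window, order)
    )


def average_replicates(replicates: list[Spectrum]) -> Spectrum:
    """Pointwise mean intensity of replicates sharing one axis."""
    if not replicates:
        raise ValueError("need at least one replicate")
    first = replicates[0]
    for r in replicates[1:]:
        if not np.array_equal(r.axis, first.axis):
            raise ValueError("replicates must share an identical axis")
    if len(replicates) == 1:
        return first
    mean = np.mean([r.intensity for r in replicates], axis=0)
    return Spectrum(first.axis, mean, {**first.meta, "n_replicates": len(replicates)})


def screen_outliers(
    replicates: list[Spectrum], min_r: float = 0.95
) -> tuple[list[Spectrum], list[Spectrum]]:
    """Drop replicates that do not correlate with the rest.

    Each replicate is compared (Pearson r) with the pointwise median of the
    other replicates; those below ``min_r`` are dropped, worst first, but
    never more than half of the set. With fewer than 3 replicates screening
    does not apply and the input passes through.
    """
    if len(replicates) < 3:
        return list(replicates), []
    kept = list(replicates)
    dropped: list[Spectrum] = []
    max_drop = len(replicates) // 2
    while len(dropped) < max_drop:
        stack = np.stack([r.intensity for r in kept])
        rs = []
        for i in range(len(kept)):
            others = np.delete(stack, i, axis=0)
            med = np.median(others, axis=0)
            rs.append(_pearson(stack[i], med))
        worst = int(np.argmin(rs))
        if rs[worst] >= min_r:
            break
        bad = kept.pop(worst)
        dropped.append(bad.replace_intensity(bad.intensity, outlier_r=float(rs[worst])))
    return kept, dropped


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(a @ b / denom)


def normalize(s: Spectrum, method: str = "minmax") -> Spectrum:
    """Scale intensities into a common range before distance computation.

    ``minmax`` maps the intensity onto [0, 1]; ``unit`` divides by the
    Euclidean norm. A constant spectrum cannot be normalized.
    """
    y = s.intensity
    if np.ptp(y) == 0:
        raise ValueError("cannot normalize a constant spectrum")
    if method == "minmax":
        out = (y - y.min()) / np.ptp(y)
    elif method == "unit":
        out = y / np.linalg.norm(y)
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return s.replace_intensity(out, normalized=method)


def preprocess_replicates(
    replicates: list[Spectrum], cfg: PreprocessConfig = PreprocessConfig()
) -> Spectrum:
    """Full chain: screen -> average -> baseline -> smooth -> crop."""
    kept, _ = screen_outliers(replicates, cfg.outlier_min_r)
    avg = average_replicates(kept)
    corrected, _ = baseline_airpls(avg, cfg.airpls_lambda, cfg.airpls_maxiter)
    smoothed = smooth_savgol(corrected, cfg.sg_window, cfg.sg_order)
    return _crop(smoothed, cfg.crop_lo, cfg.crop_hi)
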