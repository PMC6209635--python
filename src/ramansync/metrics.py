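"""Synchronization-quality metrics.

Similarity before and after correction is measured by the Pearson
correlation coefficient between paired intensity vectors (``r`` before,
``R`` after — one formula, two inputs), and by the mean Euclidean distance

    D_mean = (1/n) * sum_i sqrt( sum_j (Xp[i, j] - Xs[i, j])^2 )

over n spectrum pairs on a common k-point axis. Correlation is
scale-invariant; the distance is not, so spectra are normalized (see
:func:`ramansync.preprocess.normalize`) before computing D_mean. A
corrected spectrum passes when R reaches the conventional 0.95
hit-quality-index threshold used in library identification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import normalize
from .spectra_io import Spectrum, SpectrumPair

__all__ = [
    "PASS_THRESHOLD",
    "SyncReport",
    "correlation",
    "mean_euclidean_distance",
    "evaluate_pair",
]

PASS_THRESHOLD = 0.95


@dataclass(frozen=True)
class SyncReport:
    """Before/after similarity metrics for one spectrum pair."""

    r: float  # correlation before correction
    R: float  # correlation after correction
    d_mean_before: float
    d_mean_after: float
    passed: bool
    n_spectra: int = 1

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "R": self.R,
            "d_mean_before": self.d_mean_before,
            "d_mean_after": self.d_mean_after,
            "passed": self.passed,
            "n_spectra": self.n_spectra,
        }


def correlation(primary: Spectrum, other: Spectrum) -> float:
    """Pearson correlation of two intensity vectors on a common axis."""
    if not np.array_equal(primary.axis, other.axis):
        raise ValueError("spectra must share a common axis")
    a = primary.intensity - primary.intensity.mean()
    b = other.intensity - other.intensity.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("constant spectrum has no defined correlation")
    return float(np.clip(a @ b / denom, -1.0, 1.0))


def mean_euclidean_distance(
    primaries: list[Spectrum] | Spectrum, others: list[Spectrum] | Spectrum
) -> float:
    """Mean of the per-pair Euclidean distances between intensity vectors.

    Inputs are expected to be normalized onto a comparable range already;
    this function performs no scaling itself.
    """
    if isinstance(primaries, Spectrum):
        primaries = [primaries]
    if isinstance(others, Spectrum):
        others = [others]
    if len(primaries) != len(others) or not primaries:
        raise ValueError("need equal, nonzero numbers of spectra")
    total = 0.0
    for p, s in zip(primaries, others):
        if not np.array_equal(p.axis, s.axis):
            raise ValueError("spectra must share a common axis")
        total += float(np.linalg.norm(p.intensity - s.intensity))
    return total / len(primaries)


def evaluate_pair(
    pair: SpectrumPair, corrected: Spectrum, threshold: float = PASS_THRESHOLD
) -> SyncReport:
    """Fill a report with r (before), R (after), normalized D_mean values
    and the pass flag ``R >= threshold``."""
    if not np.array_equal(corrected.axis, pair.axis):
        raise ValueError("corrected spectrum must be on the pair's axis")
    r = correlation(pair.primary, pair.secondary)
    big_r = correlation(pair.primary, corrected)
    np_, ns, nc = (normalize(x) for x in (pair.primary, pair.secondary, corrected))
    d_before = mean_euclidean_distance(np_, ns)
    d_after = mean_euclidean_distance(np_, nc)
    return SyncReport(r, big_r, d_before, d_after, bool(big_r >= threshold))
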