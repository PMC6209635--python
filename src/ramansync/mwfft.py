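"""Moving-window FFT cross-correlation shift estimation and synchronization.

The method slides a short window over a pair of spectra on a common axis,
estimates one integer lag per window position by normalized FFT
cross-correlation, and accumulates those lags into a shift matrix: for
every spectral point, the multiset of lags contributed by every window
covering it. The per-point mode of that matrix is the shift profile — a
piecewise-constant integer displacement per point. Discontinuities of the
profile (change points) are relocated into intensity valleys so that the
insertions and deletions needed to translate each continuous region never
land on a peak, and the regions are then translated to produce the
synchronized spectrum. Peak shapes are preserved exactly: within each
region the output intensities are the input values, merely translated.

Complexity is O(N * w * log w / hop) for spectrum length N and window w.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .crosscorr import best_lag, n_tied, xcorr_fft
from .metrics import SyncReport, evaluate_pair
from .spectra_io import Spectrum, SpectrumPair

__all__ = [
    "WindowConfig",
    "ShiftMatrix",
    "ShiftProfile",
    "build_shift_matrix",
    "profile_from_matrix",
    "deflicker",
    "find_change_points",
    "merge_short_regions",
    "refine_regions",
    "prune_boundaries",
    "relocate_change_points",
    "synchronize",
    "mwfft_correct",
    "estimate_profile",
]

# windows whose segment spread falls below this fraction of the spectrum's
# global standard deviation carry no lag information and are skipped
LOW_VARIANCE_FLOOR = 1e-3

#: median-filter width used to suppress single-point flickers in raw profiles
DEFLICKER_WIDTH = 5


@dataclass(frozen=True)
class WindowConfig:
    """Moving-window parameters.

    window : window length in points (default 70)
    hop : stride between consecutive window starts (default 1, a window at
        every position)
    max_lag : per-window lag search bound; defaults to window // 3 so that
        the overlap at the extreme lag is still two-thirds of the window
    min_vote_corr : minimum best cross-correlation a window must reach for
        its lag to count as a vote; windows below it see only noise or
        featureless baseline, whose argmax lag is meaningless
    """

    window: int = 70
    hop: int = 1
    max_lag: int | None = None
    min_vote_corr: float = 0.7

    def __post_init__(self) -> None:
        if self.window < 4:
            raise ValueError("window must be at least 4 points")
        if not 1 <= self.hop <= self.window:
            raise ValueError("hop must be in [1, window]")
        if self.max_lag is not None and not 1 <= self.max_lag < self.window:
            raise ValueError("max_lag must be in [1, window)")
        if not 0.0 <= self.min_vote_corr < 1.0:
            raise ValueError("min_vote_corr must be in [0, 1)")

    @property
    def lag_bound(self) -> int:
        return self.max_lag if self.max_lag is not None else max(1, self.window // 3)


@dataclass(frozen=True)
class ShiftMatrix:
    """Per-point lag votes: counts[k, i] windows covering point i voted lag
    ``k - max_lag``."""

    counts: np.ndarray  # shape (2*max_lag + 1, N), non-negative ints
    max_lag: int
    window: int

    @property
    def n(self) -> int:
        return int(self.counts.shape[1])

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def column(self, i: int) -> dict[int, int]:
        """Lag -> vote count multiset for spectral point ``i``."""
        col = self.counts[:, i]
        nz = np.flatnonzero(col)
        return {int(k - self.max_lag): int(col[k]) for k in nz}


@dataclass(frozen=True)
class ShiftProfile:
    """Integer displacement per spectral point, piecewise constant."""

    shift: np.ndarray  # int, length N
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "shift", np.asarray(self.shift, dtype=int))

    @property
    def n(self) -> int:
        return int(self.shift.size)

    @property
    def change_points(self) -> list[int]:
        """Indices i (0-based) with shift[i] != shift[i-1]."""
        return [int(i) for i in np.flatnonzero(np.diff(self.shift)) + 1]

    def regions(self) -> list[tuple[int, int, int]]:
        """Maximal constant-shift runs as (start, stop, shift) with
        half-open [start, stop)."""
        bounds = [0, *self.change_points, self.n]
        return [
            (bounds[k], bounds[k + 1], int(self.shift[bounds[k]]))
            for k in range(len(bounds) - 1)
        ]


def build_shift_matrix(pair: SpectrumPair, cfg: WindowConfig = WindowConfig()) -> ShiftMatrix:
    """Slide a window over the pair and collect one lag vote per covered point.

    Two kinds of windows contribute nothing: nearly flat segments
    (standard deviation below ``LOW_VARIANCE_FLOOR`` of the global one) and
    windows whose best cross-correlation stays below
    ``cfg.min_vote_corr`` — both see only noise or featureless baseline, so
    their argmax lag carries no displacement information. Points covered by
    no voting window later inherit the nearest voted column's mode.
    """
    n = pair.n
    w, hop, max_lag = cfg.window, cfg.hop, cfg.lag_bound
    if n < w:
        raise ValueError(f"spectrum length {n} shorter than window {w}")
    ref = pair.primary.intensity
    qry = pair.secondary.intensity
    floor_r = LOW_VARIANCE_FLOOR * ref.std()
    floor_q = LOW_VARIANCE_FLOOR * qry.std()
    counts = np.zeros((2 * max_lag + 1, n), dtype=np.int32)
    for start in range(0, n - w + 1, hop):
        seg_r = ref[start : start + w]
        seg_q = qry[start : start + w]
        if seg_r.std() <= floor_r or seg_q.std() <= floor_q:
            continue
        cc = xcorr_fft(seg_r, seg_q, max_lag)
        if cc.best_value < cfg.min_vote_corr:
            continue
        if n_tied(cc) > 1:
            # several lags fit equally well (e.g. a self-similar band
            # tail): the window carries no displacement information
            continue
        counts[best_lag(cc) + max_lag, start : start + w] += 1
    return ShiftMatrix(counts, max_lag, w)


def profile_from_matrix(m: ShiftMatrix, min_support: int | None = None) -> ShiftProfile:
    """Column-wise mode of the shift matrix.

    Mode ties are broken toward the previous (left) column's resolved
    value — favoring a continuous profile — then toward the smallest
    absolute lag. A column's mode is only trusted when it is supported by
    at least ``min_support`` votes (default: 20% of the best-covered
    column) — an isolated vote or two in a band-free stretch is a noise
    fluke, not a displacement estimate. Untrusted and vote-free columns
    inherit the nearest trusted column's mode; the first and last
    half-window of points inherit the nearest interior column, whose
    windows see the spectrum symmetrically.
    """
    counts = m.counts
    n = m.n
    coverage = m.coverage
    if not coverage.any():
        raise ValueError("shift matrix is empty: every window was skipped")
    if min_support is None:
        min_support = max(1, round(0.2 * int(coverage.max())))
    lags = np.arange(-m.max_lag, m.max_lag + 1)
    # precedence on ties: smallest |lag|, then negative first
    tie_order = np.lexsort((lags, np.abs(lags)))

    shift = np.zeros(n, dtype=int)
    multiplicity = np.zeros(n, dtype=int)
    resolved = counts.max(axis=0) >= min_support
    if not resolved.any():
        resolved = coverage > 0  # degenerate coverage: fall back to any vote
    prev: int | None = None
    for i in range(n):
        if not resolved[i]:
            continue
        col = counts[:, i]
        top = col.max()
        tied = lags[col == top]
        if prev is not None and prev in tied:
            shift[i] = prev
        else:
            for k in tie_order:
                if col[k] == top:
                    shift[i] = lags[k]
                    break
        multiplicity[i] = top
        prev = int(shift[i])

    if not resolved.all():
        voted = np.flatnonzero(resolved)
        nearest = voted[np.argmin(np.abs(np.arange(n)[:, None] - voted[None, :]), axis=1)]
        shift = shift[nearest]
        multiplicity = multiplicity[nearest]

    half = m.window // 2
    if n > 2 * half:
        shift = shift.copy()
        shift[:half] = shift[half]
        shift[n - half :] = shift[n - half - 1]

    return ShiftProfile(
        shift, {"mode_multiplicity": multiplicity, "coverage": coverage, "window": m.window}
    )


def deflicker(p: ShiftProfile, width: int = DEFLICKER_WIDTH) -> ShiftProfile:
    """Median-filter the profile to suppress single-point flickers."""
    filtered = median_filter(p.shift, size=width, mode="nearest")
    return ShiftProfile(filtered.astype(int), dict(p.diagnostics))


def find_change_points(p: ShiftProfile, median_width: int = DEFLICKER_WIDTH) -> list[int]:
    """Indices where consecutive shifts differ, after flicker suppression."""
    return deflicker(p, median_width).change_points


def merge_short_regions(p: ShiftProfile, min_len: int) -> ShiftProfile:
    """Absorb constant-shift runs shorter than ``min_len`` into a neighbor.

    Mode profiles on noisy spectra can carry short spurious runs that
    survive the median filter; a genuine displacement regime spans many
    windows, so runs shorter than half a window are estimation noise. The
    shortest offending run is merged into its longer neighbor until every
    region reaches ``min_len`` (or one region remains).
    """
    shift = p.shift.copy()
    while True:
        regions = ShiftProfile(shift).regions()
        if len(regions) == 1:
            break
        lengths = [stop - start for start, stop, _ in regions]
        k = int(np.argmin(lengths))
        if lengths[k] >= min_len:
            break
        left_len = lengths[k - 1] if k > 0 else -1
        right_len = lengths[k + 1] if k + 1 < len(regions) else -1
        donor = k - 1 if left_len >= right_len else k + 1
        start, stop, _ = regions[k]
        shift[start:stop] = regions[donor][2]
    return ShiftProfile(shift, dict(p.diagnostics))


def refine_regions(
    pair: SpectrumPair, p: ShiftProfile, cfg: WindowConfig
) -> ShiftProfile:
    """Re-estimate each region's lag over its full extent.

    A window sees one band or two; a whole region sees every band it
    contains, so a single cross-correlation over the region confirms or
    corrects the windowed consensus with far better noise averaging —
    off-by-one runs contributed by weak narrow bands collapse back onto
    the region's true lag. A refined value is only accepted when its
    correlation clears the same quality gate as a window vote. Regions
    whose full-extent correlation clears the gate at no lag hold no bands
    at all — their windowed votes were noise flukes — and inherit the
    nearest confident region's lag instead.
    """
    ref = pair.primary.intensity
    qry = pair.secondary.intensity
    regions = p.regions()
    values: list[int] = []
    confident: list[bool] = []
    for start, stop, v in regions:
        max_lag = min(cfg.lag_bound, stop - start - 1)
        seg_r = ref[start:stop]
        seg_q = qry[start:stop]
        if max_lag < 1 or np.ptp(seg_r) == 0 or np.ptp(seg_q) == 0:
            values.append(v)
            confident.append(False)
            continue
        cc = xcorr_fft(seg_r, seg_q, max_lag)
        if cc.best_value >= cfg.min_vote_corr:
            values.append(best_lag(cc))
            confident.append(True)
        else:
            values.append(v)
            confident.append(False)
    if any(confident) and not all(confident):
        centers = np.array([(start + stop) / 2 for start, stop, _ in regions])
        good = np.flatnonzero(confident)
        for k in range(len(regions)):
            if not confident[k]:
                values[k] = values[good[np.argmin(np.abs(centers[good] - centers[k]))]]
    shift = p.shift.copy()
    for (start, stop, _), v in zip(regions, values):
        shift[start:stop] = v
    return ShiftProfile(shift, dict(p.diagnostics))


def prune_boundaries(
    pair: SpectrumPair, p: ShiftProfile, cfg: WindowConfig
) -> ShiftProfile:
    """Drop change points that noise, not displacement, put there.

    Broad Raman bands make the correlation nearly flat across one lag, so
    correlated noise can tilt a whole stretch to an off-by-one lag with
    high confidence. The test for a real boundary is asymmetry of fit: a
    region keeps its own lag only if switching to its neighbor's lag costs
    more than the region's own residual misfit ``1 - c_best`` (floored at
    0.05 — differences below that are sub-resolution). Otherwise the
    cheaper side adopts its neighbor's lag and the boundary disappears.
    Merging proceeds cheapest-first until every remaining boundary is
    load-bearing.
    """
    ref = pair.primary.intensity
    qry = pair.secondary.intensity

    def corr_pair(a: int, b: int, lag: int) -> tuple[float, float]:
        # (c at requested lag, best c) over region [a, b)
        max_lag = min(cfg.lag_bound, b - a - 1)
        if abs(lag) > max_lag or np.ptp(ref[a:b]) == 0 or np.ptp(qry[a:b]) == 0:
            return -1.0, 1.0
        cc = xcorr_fft(ref[a:b], qry[a:b], max_lag)
        return float(cc.values[lag + max_lag]), cc.best_value

    shift = p.shift.copy()
    while True:
        regions = ShiftProfile(shift).regions()
        if len(regions) == 1:
            break
        best_gain, best_merge = 0.0, None
        for k in range(len(regions) - 1):
            (a1, b1, v1), (a2, b2, v2) = regions[k], regions[k + 1]
            for (a, b, own, other) in ((a1, b1, v1, v2), (a2, b2, v2, v1)):
                c_other, c_best = corr_pair(a, b, other)
                cost = c_best - c_other
                tol = max(0.05, 1.0 - c_best)
                if cost < tol and tol - cost > best_gain:
                    best_gain, best_merge = tol - cost, (a, b, other)
        if best_merge is None:
            break
        a, b, other = best_merge
        shift[a:b] = other
    return ShiftProfile(shift, dict(p.diagnostics))


def relocate_change_points(
    p: ShiftProfile, s: Spectrum, search: int | None = None
) -> ShiftProfile:
    """Move each change point to the nearest intensity valley of ``s``.

    Insertions and deletions during synchronization happen only at change
    points; placing them in valleys (local minima of the secondary
    spectrum) keeps peak shapes untouched. The search range is +/- one
    window around the original position (falling back to the profile's
    recorded window, else 70). Where no valley exists in range — e.g. a
    flat stretch — the original position stands and is flagged.
    """
    if p.n != s.n:
        raise ValueError("profile and spectrum length mismatch")
    if search is None:
        search = int(p.diagnostics.get("window", 70))
    y = s.intensity
    interior = np.arange(1, s.n - 1)
    is_valley = (
        (y[interior] <= y[interior - 1])
        & (y[interior] <= y[interior + 1])
        & ((y[interior] < y[interior - 1]) | (y[interior] < y[interior + 1]))
    )
    valleys = interior[is_valley]

    bounds = [0, *p.change_points, p.n]
    values = [int(p.shift[b]) for b in bounds[:-1]]
    new_bounds = [0]
    flagged: list[int] = []
    for k, cp in enumerate(bounds[1:-1]):
        # the regions flanking this change point must stay longer than the
        # |shift| they will be translated by, and boundaries must not cross
        v_left, v_right = values[k], values[k + 1]
        gap_left = abs(v_left) + 1
        gap_right = abs(v_right) + 1
        lo = max(cp - search, new_bounds[-1] + gap_left)
        hi = min(cp + search, bounds[k + 2] - gap_right)
        in_range = valleys[(valleys >= lo) & (valleys <= hi)]
        if in_range.size == 0:
            flagged.append(cp)
            new = cp
        else:
            new = int(in_range[np.argmin(np.abs(in_range - cp))])
        if new <= new_bounds[-1]:
            new = cp
            flagged.append(cp)
        new_bounds.append(new)
    new_bounds.append(p.n)

    shift = np.empty(p.n, dtype=int)
    for k in range(len(values)):
        shift[new_bounds[k] : new_bounds[k + 1]] = values[k]
    diag = dict(p.diagnostics)
    if flagged:
        diag["unrelocated_change_points"] = flagged
    return ShiftProfile(shift, diag)


def synchronize(pair: SpectrumPair, p: ShiftProfile) -> Spectrum:
    """Translate each constant-shift region of the secondary spectrum.

    A region with shift ``v`` holds points displaced ``v`` indices toward
    higher index relative to the reference, so its intensities are copied
    ``v`` points back: ``out[i] = secondary[i + v]``. Where translated
    regions diverge, the gap is filled by linear interpolation between the
    flanking region endpoints (insertion); where they overlap, the points
    of the region with the smaller absolute shift are dropped (deletion).
    Within each region the output values are bit-identical to the input —
    no resampling ever touches a peak.
    """
    if p.n != pair.n:
        raise ValueError("profile length does not match pair")
    n = pair.n
    sec = pair.secondary.intensity
    out = np.full(n, np.nan)
    regions = p.regions()
    for start, stop, v in regions:
        if abs(v) >= stop - start:
            raise ValueError(
                f"shift {v} not smaller than region [{start}, {stop}) length {stop - start}"
            )
    # larger-|shift| regions written last win overlapping points
    for start, stop, v in sorted(regions, key=lambda r: abs(r[2])):
        lo = max(start - v, 0)
        hi = min(stop - v, n)
        if lo < hi:
            out[lo:hi] = sec[lo + v : hi + v]
    gaps = np.isnan(out)
    if gaps.any():
        idx = np.arange(n)
        out[gaps] = np.interp(idx[gaps], idx[~gaps], out[~gaps])
    return pair.secondary.replace_intensity(out, synchronized=True)


def mwfft_correct(
    pair: SpectrumPair, cfg: WindowConfig = WindowConfig()
) -> tuple[Spectrum, ShiftProfile, SyncReport]:
    """Full pipeline: shift matrix -> mode profile -> change-point
    relocation -> region translation -> before/after metrics."""
    matrix = build_shift_matrix(pair, cfg)
    profile = estimate_profile(pair, matrix, cfg)
    corrected = synchronize(pair, profile)
    report = evaluate_pair(pair, corrected)
    return corrected, profile, report


def estimate_profile(
    pair: SpectrumPair, matrix: ShiftMatrix, cfg: WindowConfig
) -> ShiftProfile:
    """Shift matrix -> final profile: mode, de-flicker, short-run merge,
    region refinement, boundary pruning, change-point relocation."""
    profile = merge_short_regions(deflicker(profile_from_matrix(matrix)), cfg.window)
    profile = refine_regions(pair, profile, cfg)
    profile = prune_boundaries(pair, profile, cfg)
    return relocate_change_points(profile, pair.secondary, cfg.window)
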