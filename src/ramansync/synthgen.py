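"""Synthetic Raman spectrum pairs with known ground-truth axis warps.

No public Raman standardization dataset pairs primary/secondary instrument
acquisitions, so every stage of the package is exercised on generated
spectra whose displacement is known exactly. A synthetic spectrum is a sum
of Gaussian or Lorentzian bands on a polynomial baseline plus white
detector noise, on the 2048-point, 175-2700 cm^-1 axis typical of portable
CCD instruments. The secondary member of a pair is an index-warped copy of
the same clean signal — each region translated by a piecewise-constant
integer shift, endpoint-filled at the ends — carrying independent noise,
emulating the non-linear Raman-shift displacement between two CCDs.

Ground truth (the applied shift profile and the band apex indices) is
returned alongside every pair, so shift-recovery, shape-preservation and
similarity-improvement properties can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mwfft import ShiftProfile
from .spectra_io import Spectrum, SpectrumPair

__all__ = [
    "Peak",
    "SyntheticSpec",
    "make_spectrum",
    "make_pair",
    "make_replicate_pair",
    "random_spec",
    "fixture",
    "FIXTURE_NAMES",
    "piecewise_shift",
]

#: default axis: CCD pixel count and spectral range of the emulated instruments
N_POINTS = 2048
AXIS_LO, AXIS_HI = 175.0, 2700.0

#: minimum warp-region length, two default windows
MIN_REGION = 140


@dataclass(frozen=True)
class Peak:
    center: float  # cm^-1
    height: float
    fwhm: float  # cm^-1
    shape: str = "gaussian"  # or "lorentzian"

    def profile(self, axis: np.ndarray) -> np.ndarray:
        if self.shape == "gaussian":
            sigma = self.fwhm / 2.3548200450309493
            return self.height * np.exp(-0.5 * ((axis - self.center) / sigma) ** 2)
        if self.shape == "lorentzian":
            gamma = self.fwhm / 2.0
            return self.height * gamma**2 / ((axis - self.center) ** 2 + gamma**2)
        raise ValueError(f"unknown peak shape {self.shape!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic spectrum (pair).

    ``baseline`` holds polynomial coefficients evaluated on the axis
    normalized to [0, 1]; ``warp`` is the per-point integer shift applied
    to produce the secondary spectrum (None or zeros for an identical
    pair); ``noise_sd`` is the additive white-noise standard deviation in
    the same units as peak heights.
    """

    peaks: tuple[Peak, ...]
    n_points: int = N_POINTS
    axis_lo: float = AXIS_LO
    axis_hi: float = AXIS_HI
    baseline: tuple[float, ...] = ()
    noise_sd: float = 0.0
    warp: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_points < 2:
            raise ValueError("need at least 2 points")
        for p in self.peaks:
            if not self.axis_lo < p.center < self.axis_hi:
                raise ValueError(f"peak center {p.center} outside axis range")
        if self.warp is not None:
            w = np.asarray(self.warp, dtype=int)
            if w.size != self.n_points:
                raise ValueError("warp length must equal n_points")
            object.__setattr__(self, "warp", w)
            for start, stop, _ in ShiftProfile(w).regions():
                if stop - start < MIN_REGION:
                    raise ValueError(
                        f"warp region [{start}, {stop}) shorter than {MIN_REGION} points"
                    )

    @property
    def axis(self) -> np.ndarray:
        return np.linspace(self.axis_lo, self.axis_hi, self.n_points)

    def clean_intensity(self) -> np.ndarray:
        axis = self.axis
        y = np.zeros(self.n_points)
        for p in self.peaks:
            y += p.profile(axis)
        if self.baseline:
            t = (axis - self.axis_lo) / (self.axis_hi - self.axis_lo)
            y += np.polynomial.polynomial.polyval(t, list(self.baseline))
        return y

    def apex_indices(self) -> np.ndarray:
        """Axis index nearest each band center (primary spectrum)."""
        axis = self.axis
        return np.array([int(np.argmin(np.abs(axis - p.center))) for p in self.peaks])


def piecewise_shift(n: int, boundaries: list[int], shifts: list[int]) -> np.ndarray:
    """Piecewise-constant shift vector: ``shifts[k]`` between consecutive
    boundaries (implicitly 0 and n at the ends)."""
    if len(shifts) != len(boundaries) + 1:
        raise ValueError("need one more shift than boundaries")
    out = np.empty(n, dtype=int)
    for k, (a, b) in enumerate(zip([0, *boundaries], [*boundaries, n])):
        out[a:b] = shifts[k]
    return out


def make_spectrum(spec: SyntheticSpec) -> Spectrum:
    """Peaks + baseline + seeded noise on the stated axis; deterministic."""
    rng = np.random.default_rng(spec.seed)
    y = spec.clean_intensity()
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=spec.n_points)
    return Spectrum(spec.axis, y, {"synthetic": True, "seed": spec.seed})


def _apply_warp(clean: np.ndarray, warp: np.ndarray) -> np.ndarray:
    # point i of the warped signal shows what the clean signal had at i - v:
    # a region with shift v > 0 appears displaced toward higher index
    n = clean.size
    src = np.clip(np.arange(n) - warp, 0, n - 1)  # endpoint fill at the edges
    return clean[src]


def make_pair(spec: SyntheticSpec) -> tuple[SpectrumPair, ShiftProfile]:
    """Primary spectrum plus an index-warped secondary with independent
    noise; returns the applied profile as ground truth."""
    warp = spec.warp if spec.warp is not None else np.zeros(spec.n_points, dtype=int)
    seed_p, seed_s = np.random.SeedSequence(spec.seed).spawn(2)
    clean = spec.clean_intensity()
    rng_p = np.random.default_rng(seed_p)
    rng_s = np.random.default_rng(seed_s)
    y_p = clean.copy()
    y_s = _apply_warp(clean, warp)
    if spec.noise_sd > 0:
        y_p = y_p + rng_p.normal(0.0, spec.noise_sd, size=spec.n_points)
        y_s = y_s + rng_s.normal(0.0, spec.noise_sd, size=spec.n_points)
    axis = spec.axis
    pair = SpectrumPair(
        Spectrum(axis, y_p, {"instrument": "primary", "seed": spec.seed}),
        Spectrum(axis, y_s, {"instrument": "secondary", "seed": spec.seed}),
    )
    return pair, ShiftProfile(warp)


def make_replicate_pair(
    spec: SyntheticSpec, n_replicates: int = 6
) -> tuple[list[Spectrum], list[Spectrum], ShiftProfile]:
    """Replicate acquisitions of one sample on both instruments.

    Emulates the measurement protocol — several spectra per sample per
    instrument, later screened and averaged — by drawing independent noise
    per replicate around the shared clean (warped) signal. Returns
    (primary replicates, secondary replicates, ground-truth profile).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    warp = spec.warp if spec.warp is not None else np.zeros(spec.n_points, dtype=int)
    clean = spec.clean_intensity()
    warped = _apply_warp(clean, warp)
    axis = spec.axis
    children = np.random.SeedSequence(spec.seed).spawn(2 * n_replicates)
    prim, sec = [], []
    for k in range(n_replicates):
        rng_p = np.random.default_rng(children[2 * k])
        rng_s = np.random.default_rng(children[2 * k + 1])
        noise_p = rng_p.normal(0.0, spec.noise_sd, spec.n_points) if spec.noise_sd else 0.0
        noise_s = rng_s.normal(0.0, spec.noise_sd, spec.n_points) if spec.noise_sd else 0.0
        prim.append(Spectrum(axis, clean + noise_p, {"instrument": "primary", "replicate": k}))
        sec.append(Spectrum(axis, warped + noise_s, {"instrument": "secondary", "replicate": k}))
    return prim, sec, ShiftProfile(warp)


def random_spec(
    seed: int,
    *,
    n_regions: int = 2,
    n_peaks_per_region: int = 8,
    max_shift: int = 15,
    snr: float = 20.0,
    margin: int = 70,
    baseline: tuple[float, ...] = (),
    shape: str = "gaussian",
) -> SyntheticSpec:
    """Draw a randomized recipe under the standard study conditions.

    Region boundaries are placed so every region spans at least two
    windows; band centers keep ``margin`` points (one window) away from
    region boundaries, reflecting that displacement discontinuities between
    CCDs fall between bands, not on them. Each boundary is flanked by one
    band on either side just beyond that margin: a displacement
    discontinuity is only localizable from data when bands bracket it, and
    pharmaceutical spectra are dense enough that they always do. ``snr``
    is the ratio of the tallest band height (1.0) to the noise standard
    deviation.
    """
    rng = np.random.default_rng(seed)
    n = N_POINTS
    step = (AXIS_HI - AXIS_LO) / (n - 1)

    # region boundaries, each region comfortably longer than MIN_REGION
    while True:
        bounds = sorted(rng.integers(2 * MIN_REGION, n - 2 * MIN_REGION, size=n_regions - 1))
        lengths = np.diff([0, *bounds, n])
        if (lengths >= 2 * MIN_REGION).all() and (np.diff(bounds) >= 2 * MIN_REGION).all():
            break

    # adjacent regimes differ by at least 3 points: a one-point regime step
    # is below the instrument line width and has no integer-lag signature
    shifts: list[int] = []
    for k in range(n_regions):
        while True:
            v = int(rng.integers(-max_shift, max_shift + 1))
            if not shifts or abs(v - shifts[-1]) >= 3:
                shifts.append(v)
                break
    warp = piecewise_shift(n, list(map(int, bounds)), shifts)

    peaks: list[Peak] = []
    region_edges = [0, *bounds, n]
    flankers: dict[int, list[int]] = {k: [] for k in range(n_regions)}
    for j, b in enumerate(bounds):
        flankers[j].append(int(b - rng.integers(margin, margin + 40)))
        flankers[j + 1].append(int(b + rng.integers(margin, margin + 40)))
    for k in range(n_regions):
        lo = region_edges[k] + margin
        hi = region_edges[k + 1] - margin
        centers: list[int] = list(flankers[k])
        tries = 0
        while len(centers) < n_peaks_per_region and tries < 2000:
            tries += 1
            c = int(rng.integers(lo, hi))
            if all(abs(c - o) >= 30 for o in centers):
                centers.append(c)
        for c in sorted(centers):
            peaks.append(
                Peak(
                    center=float(AXIS_LO + c * step),
                    height=float(rng.uniform(0.3, 1.0)),
                    fwhm=float(rng.uniform(6.0, 14.0)),
                    shape=shape,
                )
            )
    return SyntheticSpec(
        peaks=tuple(peaks),
        baseline=baseline,
        noise_sd=1.0 / snr,
        warp=warp,
        seed=seed,
    )


FIXTURE_NAMES = ("identity", "global-small", "global-90", "two-regime", "three-regime")


def fixture(name: str, seed: int = 0) -> SyntheticSpec:
    """Named deterministic fixtures covering the standard scenarios."""
    if name == "identity":
        spec = random_spec(seed, n_regions=1, max_shift=0)
        return replace(spec, warp=np.zeros(spec.n_points, dtype=int))
    if name == "global-small":
        spec = random_spec(seed, n_regions=1)
        return replace(spec, warp=np.full(spec.n_points, 5, dtype=int))
    if name == "global-90":
        spec = random_spec(seed, n_regions=1)
        return replace(spec, warp=np.full(spec.n_points, 90, dtype=int))
    if name == "two-regime":
        spec = random_spec(seed, n_regions=2)
        bounds = ShiftProfile(spec.warp).change_points
        return replace(spec, warp=piecewise_shift(spec.n_points, bounds, [2, 8]))
    if name == "three-regime":
        spec = random_spec(seed, n_regions=3, max_shift=12, baseline=(0.2, 0.6))
        return spec
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
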