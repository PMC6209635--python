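# Methods

## Overlap-normalized cross-correlation

For equal-length signals the correlation at lag j is the Pearson
coefficient of the two overlapping stretches, with means and norms taken
over that same overlap. This keeps c(j) in [−1, 1] and makes values at
different lags comparable; the alternative (zero-padded, full-length
normalization) biases against large lags. The FFT route obtains the raw
product sums for all lags from one frequency-domain correlation and the
per-lag means/norms from prefix sums; it agrees with the direct evaluation
to 1e-9 at every lag, which is also the scale used to call two lags
"tied". Ties break toward the smallest |lag| (preferring "no shift"), then
toward the negative lag, deterministically.

Degenerate overlaps (variance below 1e-30, e.g. |lag| = L−1 with a flat
stretch) get c(j) = 0 in both routes rather than an undefined value.

Sign convention, used everywhere: a positive lag means the query is
displaced toward higher index relative to the reference; translating it by
−lag aligns it.

## Shift-profile estimation

The moving window (default w = 70 points, hop 1, lag bound ⌊w/3⌋) votes
one lag per position, recorded for every point the window covers. Raw
column modes are not yet a usable profile at realistic noise levels; the
estimator therefore applies, in order:

1. **Vote gate** (`min_vote_corr`, default 0.7): a window's vote counts
   only if its best correlation reaches the gate. Windows seeing only
   noise or featureless baseline have a meaningless argmax; after
   9-point smoothing, the null maximum over ~47 lags of a 70-point noise
   window reaches ≈0.6 (smoothing cuts the effective sample count), so
   0.7 rejects noise while band-bearing windows typically exceed 0.9.
   Windows whose maximum is tied at several lags (self-similar
   exponential band tails) are likewise skipped, as are near-flat
   segments (sd below 1e-3 of the global sd).
2. **Mode support**: a column's mode is trusted only when backed by at
   least 20% of the votes of the best-covered column; isolated flukes in
   band-free gaps otherwise propagate. Untrusted columns inherit the
   nearest trusted column's mode; the outer half-window inherits the
   nearest interior column. Mode ties prefer the left neighbor's resolved
   value (profile continuity), then the smallest |lag|.
3. **De-flicker and short-run merge**: a width-5 median filter removes
   single-point flickers; runs shorter than one window are absorbed into
   the longer neighbor (a genuine displacement regime spans at least two
   windows).
4. **Region refinement**: each region's lag is re-estimated by one
   cross-correlation over its full extent, which averages noise far
   better than any single window; off-by-one runs contributed by weak
   broad bands (where c is nearly flat across ±1 lag and correlated noise
   tilts the argmax) collapse back to the true lag. Regions confident at
   no lag hold no bands; they inherit the nearest confident region.
5. **Boundary pruning**: a change point survives only if it is
   load-bearing — switching either flank to its neighbor's lag must cost
   more correlation than that flank's own residual misfit (1 − c_best,
   floored at 0.05). Measured on the synthetic battery, spurious
   off-by-one boundaries cost ≤ 0.03 while true regime boundaries cost
   ≥ 0.38, an order-of-magnitude separation.
6. **Change-point relocation**: surviving boundaries move to the nearest
   intensity valley of the secondary spectrum within ± one window
   (bounded so regions stay longer than the |lag| they are translated
   by), keeping insertions/deletions off the peaks. Flat stretches with
   no valley leave the boundary in place, flagged.

Synchronization then translates each region by −shift; gaps between
diverging regions are filled by linear interpolation between flanking
endpoints, overlaps resolved by dropping points from the smaller-|shift|
region. Within regions the output intensities are the input values,
bit-identical — peak shape is never resampled.

## Preprocessing

* **airPLS baseline**: iteratively reweighted Whittaker smoothing with a
  second-difference penalty; points above the current baseline get zero
  weight, points below an exponentially growing one. Iteration stops when
  the negative-residual mass falls below 0.1% of the total signal
  magnitude, when it fails to halve between iterations (a stagnation
  guard — beyond that point the reweighting only chases noise valleys),
  or at `maxiter` (15). The weight exponent is capped at 50 against
  overflow. The default penalty λ = 1e6 is sized for ~2048-point spectra:
  at 1e5 the baseline is flexible enough to dip into the undershoot beside
  isolated bands (4.6% ramp-removal error, 2.5% non-idempotence on the
  synthetic fixtures), while 1e6 brings both near 1%. airPLS presumes a
  dominant smooth background; the synthetic-workflow driver applies it
  only to recipes that include one, since on background-free signals any
  baseline it finds is spurious.
* **Savitzky–Golay smoothing**: 9-point window, order 2.
* **Replicate screen**: with ≥3 replicates, a replicate is dropped
  (worst-first, never more than half) when its Pearson correlation to the
  median of the others falls below 0.95 — mirroring the 0.95 similarity
  convention. Fewer than 3 replicates pass through.
* **Normalization** for distance computation: min-max to [0, 1]
  (unit-vector scaling available as a config switch). Correlations need no
  normalization, being scale-invariant.
* **Crop**: analysis restricted to 300–1700 cm⁻¹ for the file-based
  pipeline, the information-rich region of pharmaceutical spectra.

The measurement workflow (`ramansync.cli.run_synthetic`, and the `pipeline`
subcommand for files) is: replicates → outlier screen → average → baseline
→ smooth → synchronize → report. Averaging six replicates is part of the
protocol, not an optional nicety: at replicate SNR 20 a single acquisition
pair caps the achievable correlation near 0.95 from noise alone, however
good the synchronization.

## Synthetic data: what it emulates, what it does not

Spectra are sums of Gaussian (optionally Lorentzian) bands, heights
0.3–1.0, FWHM 6–14 cm⁻¹, on a 2048-point, 175–2700 cm⁻¹ axis (typical
portable-CCD geometry), with optional polynomial background and white
noise; SNR is defined as tallest-band height over noise sd, default 20,
six replicates per instrument. The secondary spectrum is an index-warped
copy (regions translated, endpoint fill) with independent noise.

Randomized warps follow the conditions the method is designed for: each
regime spans at least two windows; |shift| stays within the window lag
bound; eight bands per regime; adjacent regimes differ by at least 3
points — a one-point regime step is below the 3–3.5 cm⁻¹ instrument line
width and has no integer-lag signature; and one band flanks each regime
boundary just beyond one window, since a displacement discontinuity is
only localizable from data when bands bracket it (pharmaceutical spectra
are dense enough that they do).

Not emulated: detector response curves, etaloning, cosmic-ray spikes,
fluorescence photobleaching, wavelength-dependent resolution, or
sub-point (fractional) displacements. Passing the battery therefore shows
correctness of the displacement model and its estimator under realistic
noise, not robustness to every instrument artifact.

## SSS comparator

Certified positions ship as a packaged CSV (acetaminophen 19 bands,
cyclohexane 7, within 300–1700 cm⁻¹; duplicated rows in the source table
deduplicated). Peak matching searches ± 10 cm⁻¹ (≈3× the instrument
resolution) around each certified position, refines the apex by a 3-point
parabolic fit, regresses displacement = measured − reference on the
reference position by ordinary least squares, and corrects the axis by
x ↦ x − displacement(x) followed by linear interpolation onto the master
axis. On linear warps this round-trips to within one axis step; on
piecewise warps its residual apex displacement is, on every battery
fixture, at least that of the moving-window correction — the expected
failure mode of a linear model on a non-linear displacement.

## Problem sizes and determinism

The test battery runs 50 randomized two-regime trials at the default
2048-point size (the acceptance tests reuse one shared battery), 200
random pairs for the FFT/direct equivalence sweep, and a 2048- vs
4096-point pair for the runtime-scaling check (best of three timings; the
scaling fixture carries noise so that every window position performs its
cross-correlation, the regime the complexity statement describes). All
randomness flows through explicit seeds: generator recipes embed a seed,
replicate noise derives from it via seed sequences, and hypothesis
properties run derandomized.

## Known limitations

* Integer lags only; sub-point displacement correction is out of scope by
  design.
* Regime steps of 1–2 points between adjacent regions are sub-resolution
  and may be absorbed by boundary pruning.
* In long band-free stretches the profile is filled by inheritance; its
  exact value there is unidentifiable (and immaterial, as there is no
  signal to move).
* Change points falling exactly on a band (no valley within one window)
  are corrected in place and flagged; peak distortion is possible there.
* The SSS comparator assumes the standards and the sample share the
  instrument state; drift between acquisitions is not modelled.
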