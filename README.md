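# ramansync

Synchronization of Raman spectra across spectrometers by moving-window FFT
cross-correlation (MWFFT).

## The problem

Multivariate models and library searches built on Raman spectra assume that
a band always appears at the same Raman shift. Across two instruments —
even nominally identical ones — differences between CCD detectors displace
the wavenumber axis, and the displacement is usually *non-linear*: different
spectral regions are shifted by different amounts. A calibration model
trained on a "master" (primary) spectrometer then degrades badly on a
"slave" (secondary) one. This package estimates and removes such
displacements so that spectra from the secondary instrument can be used
with models and libraries built on the primary one. It is aimed at
chemometricians and analytical labs standardizing portable Raman
instruments, e.g. for pharmaceutical identification.

## The method

The similarity of a reference segment r and a query segment s under an
integer lag j is the normalized cross-correlation

    c(j) = Σᵢ (r(i) − r̄)(s(i+j) − s̄)
           ─────────────────────────────────────────────
           √( Σᵢ (r(i) − r̄)²  ·  Σᵢ (s(i+j) − s̄)² )

a Pearson coefficient computed over the overlap at each lag; the argmax
over j is the displacement of s relative to r. Computed via FFT this costs
O(w log w) per window of length w.

MWFFT slides a w-point window (default 70) over a spectrum pair on a
common axis and estimates one lag per window position. Every spectral
point collects the lags of all windows covering it — an N-column *shift
matrix* — and the column-wise mode gives the *shift profile*: a
piecewise-constant integer displacement per point. Discontinuities of the
profile (*change points*) are relocated into intensity valleys, and each
constant-shift region is then translated whole, with insertion/deletion
confined to the change points. Because regions are translated rather than
resampled, peak shapes are preserved bit-for-bit. Total cost is
O(N·w·log w).

Quality is judged by the Pearson correlation between primary and secondary
spectra before (r) and after (R) correction — 0.95 being the conventional
hit-quality-index pass threshold — and by the mean Euclidean distance
between min-max-normalized spectra,

    D_mean = (1/n) Σᵢ √( Σⱼ (Xᵖᵢⱼ − Xˢᵢⱼ)² ).

The classical comparator, the standard-scattering-shift (SSS) method, is
included: certified band positions of acetaminophen and cyclohexane (ASTM
E1840, packaged as `data/astm_e1840_standards.csv`) are located in a
measured standard spectrum, the displacements are fitted linearly against
position, and the axis is corrected by interpolation. Being linear, SSS
cannot follow a piecewise displacement — the gap MWFFT closes.

No public dataset pairs primary/secondary acquisitions, so the package
ships a synthetic generator (`ramansync.synthgen`) that emulates the
measurement: 2048-point spectra on 175–2700 cm⁻¹, Gaussian/Lorentzian
bands, polynomial background, replicate acquisitions at a chosen
signal-to-noise ratio, and piecewise-constant index warps with known
ground truth.

## Worked example

```python
from ramansync import random_spec
from ramansync.cli import run_synthetic

spec = random_spec(seed=42)   # two displacement regimes, 8 bands each
out = run_synthetic(spec)     # replicates -> average -> smooth -> MWFFT

report = out["report"]
print(out["profile"].regions())
print(f"r={report.r:.4f}  R={report.R:.4f}  "
      f"D_mean {report.d_mean_before:.4f} -> {report.d_mean_after:.4f}")
```

prints

```
[(0, 393, 8), (393, 2048, 5)]
r=0.4543  R=0.9884  D_mean 6.9275 -> 1.0287
```

The generated sample carries a two-regime warp (+8 points up to index 412,
+5 after). The estimated profile recovers both regimes, placing the
boundary 19 points away inside a band-free gap; after translating the two
regions, the correlation with the primary spectrum rises from 0.45 to
0.99 — past the 0.95 identification threshold — and the mean Euclidean
distance drops about sevenfold.

The same workflows are available from the shell:

```sh
ramansync simulate --fixture two-regime --seed 3 --out-dir fx/
ramansync sync --ref fx/primary.csv --qry fx/secondary.csv \
    --out corrected.csv --profile profile.csv
```

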