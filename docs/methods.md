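# Methods

## Signal model

A magnitude MR pixel reconstructed by root-sum-of-squares over `K`
phased-array channels, each carrying independent complex Gaussian noise of
per-channel SD `σ`, follows a noncentral chi distribution with `2K` degrees
of freedom. With the true signal nulled (normal myocardium at the correct
inversion time, or air background) this reduces to the central chi —
the "generalized Rayleigh" density

```
p(m) = m^(2K-1) / (2^(K-1) σ^(2K) (K-1)!) · exp(-m² / 2σ²),   m ≥ 0,
```

implemented as `scipy.stats.chi(df=2K, scale=σ)` (scipy evaluates the
log-density internally, so no overflow for large `K` or `m`). Closed forms
used throughout: mode `σ√(2K-1)`, mean `cσ` with
`c = √2·Γ(K+½)/Γ(K)`, SD `σ√(2K-c²)`. For `K = 8` (the default,
matching an 8-element cardiac coil): `c ≈ 3.938`, SD factor
`√(2K-c²) ≈ 0.701`.

## Estimating σ: two conventions

The scale σ is estimated from a square background ROI (default 25 × 25 mm,
placed in air near the chest wall). Two mappings from the ROI's sample SD to
the model scale are provided:

- `direct` (default of `estimate_sigma`): the sample SD is used verbatim as
  σ. This is the field convention — the published pipelines plug the
  measured background SD straight into the Rayleigh formula.
- `moment_corrected` (default of `quantify_all` and the CLI): the sample SD
  is divided by `√(2K-c²)`, the exact SD-to-scale factor of the chi
  distribution.

For ideal sum-of-squares noise these differ by ~1/0.701 ≈ 1.43 at `K = 8`,
and only the moment-corrected scale places the reference curve on top of the
actual nulled-myocardium histogram: with the direct convention the curve
mode sits at `0.701·SD·√15` instead of `SD·√15`, about 4 intensity units too
low, which would misclassify ~2% of normal myocardium and cap control
concordances near 40% on simulated data. Clinical magnitude images that have
undergone reconstruction filtering can have a background SD close to the
effective chi scale, which is presumably why the direct convention works in
practice; on this package's ideal simulator the matched estimator is the
self-consistent choice, so the pipeline defaults to it while keeping
`direct` available for real scanner data.

## The RC threshold

"Maximal signal intensity measurable in the Rayleigh curve" is undefined for
an unbounded density; it is operationalized as the `(1 - tail_mass)`
quantile (default `tail_mass = 1e-4`), rounded up to the next integer bin.
This matches where a rendered curve visually ends at histogram precision,
makes the cutoff increase with background noise, and bounds the expected
false-positive extent on noise-only myocardium by `100·tail_mass` percent.
The pre-rounding quantile is strictly increasing in σ; the integer cutoff is
nondecreasing (strict for well-separated σ, e.g. a doubling). As σ → 0 the
cutoff falls to the bottom of the intensity scale (the ceil leaves it at bin
1 rather than 0 for vanishingly small σ — one bin of conservatism).
Enhancement is strict: a pixel is enhanced iff its intensity is `>` the
threshold. SD2/SD6 thresholds are real-valued (mean + n·SD of the
normal-myocardium ROI, sample SD with `ddof=1`), not rounded.

## Histograms and concordance

Myocardial histograms are 256-bin percentage distributions on the 8-bit
grid. The reference curve integrates the model density per bin
(`[i-0.5, i+0.5)`, clipped at 0) rather than sampling the PDF at bin
centers, removing the O(bin-width) bias at small σ. Concordance is
`100·Σ min(measured_i, reference_i) / Σ reference_i` — computed bin-wise on
the integer grid so the statistic is exactly reproducible, and normalized by
the reference area (which is ≈100 by construction but kept in the
denominator as defined).

## Gaussian-approximation comparison

`fit_gaussian_to_histogram` fits `a·exp(-(x-μ)²/2s²)` to the percentage
curve by Levenberg–Marquardt, initialized at the histogram moments. The
fitting error is the normalized L1 residual, `Σ|resid| / Σ measured × 100`,
chosen for scale invariance. The measured-vs-fitted comparison is a
bin-paired t test over the union support; a constant nonzero difference
(zero variance) is reported as a degenerate case rather than an infinite t.
The pairing unit (bins) is a design choice — pixel-level pairings would be
equally defensible.

## 8-bit conversion

Fixed min-to-max windowing: an affine map sending the image minimum to 0 and
maximum to 255, rounded half-up. Per-slice by default. The map is invariant
under positive affine rescalings of the raw data, which is what makes
thresholds comparable across acquisitions. A constant image maps to zeros
with a warning.

## The phantom simulator

Each phantom is one short-axis slice built from K complex channels
(`amplitude/√K` + Gaussian noise per channel, root-sum-of-squares combine),
so every region follows the exact (non)central chi law of its amplitude:

- **geometry** — 256 × 256 matrix at 1.5625 mm/pixel (a 400 mm FOV),
  annulus with 22 mm endocardial / 40 mm epicardial radii (hypertrophic wall
  thickness, ≈1,400 annulus pixels per slice);
- **blood pool** — bright disc inside the endocardial contour (default
  amplitude 85× the chi scale). It pins the top of the display window so
  that, after 8-bit conversion, the background SD stays near 2 intensity
  units — the regime the method operates in clinically;
- **zero padding** — pixels outside the inscribed reconstruction circle are
  exactly zero, as scanner reconstructions produce; this anchors the min-max
  window at 0 and preserves the chi shape on the 8-bit scale;
- **noise calibration** — the per-channel σ is set to
  `sigma / √(2K-c²)` so that the *measured background magnitude SD* equals
  the phantom's `sigma` (default 2.05), keeping "the SD of the background ROI"
  the ground-truth quantity;
- **amplitudes** — lesion, blood and residual-nulling amplitudes are given
  in multiples of the chi scale (per-channel σ). On this scale the stated
  recovery property holds: lesions at ≥8× are detected nearly completely by
  the RC cutoff. (In multiples of the background *magnitude* SD, 8× would
  put the lesion mean almost exactly at the cutoff.)
- **cohorts** — `simulate_cohort` draws positives with one wedge lesion
  covering 20–40% of the annulus at 8–16× contrast (uniform), negatives
  noise-only, mirroring a 40-patient / 20-control design; a single master
  seed drives everything.

What the simulator does **not** emulate: realistic cardiac anatomy or
motion, coil-sensitivity shading, partial-volume edges (lesion borders are
hard by default), spatially correlated or filtered noise, inversion-recovery
signal equations. Passing tests therefore validate the statistical machinery
under ideal multi-coil noise, not robustness to those real-world effects —
in particular the direct-vs-corrected σ question above is exactly where real
scanner noise deviates from the ideal model.

## Numerical and design choices

- Pixel counts stand in for mass (uniform 8 mm slices).
- Per-subject extent aggregation is pooled pixels (vs mean of slices),
  configurable.
- ROC: disease is called when concordance < cutoff; candidate cutoffs are
  all observed values; AUC is the Mann–Whitney pairwise probability with
  ties counted ½ (`sklearn.metrics.roc_auc_score`; a brute-force all-pairs
  oracle and the trapezoid of the operating points verify it in tests).
  The optimal operating point maximizes Youden's J, ties broken toward
  higher specificity.
- The false-positive bound for the RC method
  (`extent ≤ 100·tail_mass·(1+5/√n)`) is checked per subject where the
  annulus has ≥10⁴ pixels and on pooled negatives for cohort-scale slices,
  where a single noise pixel would otherwise exceed the bound at n ≈ 1.4e3.
- Degenerate inputs fail loudly with typed errors: constant background ROI,
  empty masks, contours out of order, saturated noise (RC cutoff > 255),
  boxes outside the image.
- Problem sizes in tests: single 256×256 slices for pipeline checks, one
  400×400 phantom (≥10⁴ pixels per region) for recovery and ratio checks,
  10⁵ draws for estimator bias, a 60-subject cohort for the directional
  study-level checks.

## Known limitations

- The two-band "mild vs higher" report (RC-to-SD6, above-SD6) is an
  extension, not a published operational definition.
- No non-central chi *fitting* is provided (the simulator generates
  non-central data, but enhanced signal is only thresholded, not modelled).
- Concordance depends on the estimated σ; with a 25 × 25 mm background ROI
  (256 pixels at study spacing) the σ estimate carries ≈4% sampling error,
  which costs a few concordance points even for perfect phantoms — visible
  as control concordances of ≈90% rather than 100%.
- DICOM support covers single-frame magnitude images with standard
  PixelSpacing/Rescale tags only.
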