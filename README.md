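# lgequant

Quantification of **late gadolinium enhancement (LGE)** in cardiac MR for
conditions with patchy fibrosis such as hypertrophic cardiomyopathy (HCM).
The package is aimed at imaging researchers who need an operator-independent,
noise-adaptive scar threshold and a way to benchmark it against the common
fixed *n*SD cutoffs — plus a fully synthetic multi-coil phantom generator so
every step can be validated with known ground truth.

## The model

In an inversion-recovery LGE image the inversion time is chosen to null
normal myocardium, so its residual signal is pure noise. With `K`
phased-array coils combined by root-sum-of-squares, the noise-only magnitude
`m` follows a generalized Rayleigh density — a chi distribution with `2K`
degrees of freedom and scale `σ`:

```
p(m) = m^(2K-1) / (2^(K-1) σ^(2K) (K-1)!) · exp(-m² / 2σ²),   m ≥ 0
```

with `σ` estimated from a background ROI. From this curve the package derives:

- **RC method** — enhancement threshold at the practical maximum of the
  Rayleigh curve (the `1 - tail_mass` quantile, default `tail_mass = 1e-4`,
  rounded up to the next 8-bit intensity bin). The cutoff adapts to the image
  noise: noisier background, higher cutoff.
- **SD2 / SD6 methods** — classical fixed cutoffs at the mean of a
  normal-myocardium ROI plus 2 or 6 sample SDs.
- **Concordance** — the bin-wise intersection area between the measured
  myocardial intensity histogram and the Rayleigh curve, as a percentage of
  the area under the Rayleigh curve. Normal myocardium scores near 100%;
  enhancement shifts signal rightward and lowers it. Subject-level
  concordances feed a ROC analysis (disease = concordance below cutoff,
  Youden-optimal operating point).
- **Extent** — enhanced pixels as a percentage of the myocardial mass
  (pixel counts; uniform slice thickness makes area fraction = mass fraction).

All analysis happens after fixed min-to-max windowing to the 0–255 scale, so
display-window differences between acquisitions are nulled.

## Worked example

Simulate one short-axis slice with a wedge lesion covering 25% of the
myocardial annulus at 12× the noise scale, then quantify it with all three
methods:

```python
from lgequant import PhantomSpec, simulate_image, to_8bit, quantify_all
from lgequant.synthetic import wedge_for_fraction

spec = PhantomSpec(lesions=(wedge_for_fraction(0.25, 12.0),), seed=1)
img, seg, truth = simulate_image(spec)
analysis = quantify_all(to_8bit(img), seg)

annulus = seg.epi_mask & ~seg.endo_mask
print(f"true enhanced fraction: {100 * truth.sum() / annulus.sum():.1f}%")
print(f"estimated sigma: {analysis.model.sigma:.2f} (8-bit units, K={analysis.model.coils})")
print(f"concordance with Rayleigh curve: {analysis.concordance:.1f}%")
for method, res in analysis.results.items():
    print(f"{method}: threshold {res.threshold:.1f}, extent {res.extent_percent:.2f}% of myocardium")
```

prints

```
true enhanced fraction: 25.0%
estimated sigma: 3.01 (8-bit units, K=8)
concordance with Rayleigh curve: 74.9%
SD2: threshold 15.6, extent 27.22% of myocardium
SD6: threshold 23.8, extent 25.00% of myocardium
RC: threshold 21.0, extent 25.00% of myocardium
```

The noise-adaptive RC threshold recovers the true lesion burden exactly
here; the low SD2 cutoff also sweeps up normal myocardium (27.2% > 25%),
the overestimation that motivates the noise-based cutoff. The reduced
concordance (74.9% vs ≈90% for a lesion-free phantom) flags the subject as
diseased.

The same pipeline is available from the shell:

```
lgequant simulate --seed 1 --out sim/
lgequant quantify --image sim/image.npy --endo sim/endo.png --epi sim/epi.png \
    --myo-roi sim/myo_roi.png --bg-row 120 --bg-col 2 --out out/
lgequant roc --subjects subjects.csv --out roc/
```

`quantify` writes a per-slice CSV (threshold, extent, concordance per
method), three-color parametric maps (black = outside LV, gray = normal
myocardium, pink = enhanced), and a run-metadata JSON; `roc` writes the
operating points and an AUC/cutoff summary.

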