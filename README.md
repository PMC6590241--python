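# msiqc

Quality control for MALDI mass-spectrometry imaging (MSI) of
formalin-fixed paraffin-embedded (FFPE) tissue.

On-slide tryptic digestion of FFPE sections is the step that makes or
breaks peptide MSI: wet preparation delocalizes analytes laterally and
uncontrolled humidity produces condensation droplets, both of which
destroy the spatial information the measurement exists to capture.
`msiqc` implements the computational side of a digestion-workflow QC
battery — metrics that quantify *how much* spatial resolution and
spectral quality a given preparation actually delivers — together with a
synthetic phantom generator with known ground truth, so every metric is
validated against a dataset whose right answer is known.

## What it computes

**Mixed-pixel spatial-resolution score.** Choose two analytes specific
to adjacent tissue regions (here: m/z 944.6 for intestinal villi/lumen,
m/z 1105.6 for crypts/muscle), extract their ion images, clip each
channel to its 3rd/97th intensity percentiles over on-tissue pixels, and
classify every pixel:

    lo = min(red, green),  hi = max(red, green)
    YELLOW  if lo >= 0.70 * hi      (both signals present — "mixed" pixel)
    else the colour of the stronger channel

The score is `100 * |YELLOW| / (|RED| + |GREEN| + |YELLOW|)`. With sharp
localization few pixels carry both markers, so a low score means good
effective spatial resolution; delocalization (blur, droplets) raises it.

**Spectral quality.** Sample 100 random on-tissue spectra, pick peaks
(SNAP-style monoisotopic picking, min S/N 1, ≤ 10 000 peaks), and report
medians with percentile-bootstrap 95% CIs for: peaks per spectrum, peaks
above S/N 3, peaks over m/z 1500 and over m/z 2000.

**Peak-intensity CV.** Across repeated runs, match target peptide m/z
values in each run's TIC-normalized average spectrum (picked at S/N 3)
and report mean ± SD and CV% per target — the reproducibility monitor
for multi-site / multi-day studies.

**Spatial segmentation & PCA.** Peak-aligned, TIC-normalized feature
matrices are clustered by bisecting k-means with correlation distance
(d = 1 − Pearson r) and ordinated by PCA with unit-variance scaling, to
check that structure in pooled data follows tissue regions rather than
acquisition batch.

**Phantom generator.** A two-region tissue phantom (50 µm pixels,
m/z 600–3200) with controllable Gaussian delocalization blur,
condensation-droplet artifacts, per-pixel and per-run log-normal
intensity jitter, and full ground truth (region labels, noiseless
analyte maps, mask).

## Worked example

`examples/01_resolution_score.py` scores one phantom clean, blurred and
droplet-corrupted:

```text
clean preparation        score =  0.00% yellow pixels
blurred (sigma = 2 px)   score =  8.88% yellow pixels
boundary droplet         score =  1.63% yellow pixels
```

With hard region edges and no noise, no pixel receives both markers and
the score is 0%; two pixels of delocalization blur turn ~9% of the
tissue into mixed pixels; a single droplet on the region boundary is
visible as a ~1.6-point increase. `examples/04_segmentation_pca.py`
pools five replicate runs:

```text
first split vs tissue regions:  ARI = 1.000
first split vs replicate id:    ARI = -0.001
silhouette by region:    0.930
silhouette by replicate: 0.056
```

meaning the first bisection recovers the two tissue regions exactly
while replicates are statistically indistinguishable — clustering
follows biology, not batch. The other examples print the spectral-quality
medians and the CV table the same way.

A thin CLI wraps the same calls:

```bash
msiqc simulate --spec spec.yaml --out phantom/
msiqc score-resolution --imzml phantom/phantom.imzML --mask phantom/mask.png \
      --red-mz 944.6 --green-mz 1105.6 --out-prefix report
msiqc quality --imzml phantom/phantom.imzML --mask phantom/mask.png --n 100
```

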