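# Methods

This note documents the models, estimators and numerical choices behind
`msiqc`, what the synthetic phantom does and does not emulate, and the
design decisions taken where the underlying procedures are conventions
rather than published algorithms.

## Data model and conventions

An MSI dataset is a rectangular grid of pixels (default pitch 50 µm),
each with one mass spectrum over m/z 600–3200. Internally all pixel
coordinates are 0-based `(col, row)` with origin top-left; imzML's
1-based coordinates are converted at the I/O boundary. Missing pixels
inside the bounding box are allowed (sparse acquisition) and every
per-pixel statistic iterates over measured pixels only. Ion-image
extraction uses a closed m/z window of fixed half-width in Th (default
0.25 Th; a fixed-Th window is reproducible on TOF data, unlike an
unspecified vendor window), with `sum` as the default reducer because a
windowed sum is proportional to the ion count; `mean` and `max` are
available for sensitivity analysis. When no optical-image mask is
supplied, a fallback mask keeps pixels whose TIC *strictly* exceeds a
quantile (default 0.2) of all measured-pixel TICs; on a constant TIC
field this yields an all-off mask with a warning rather than an
arbitrary split.

## Mixed-pixel spatial-resolution score

Both channels are clipped to their [P3, P97] percentiles before
classification. Two points here were genuinely open:

* *"Set to the percentile"* is read as **clamping** (floor at P3,
  ceiling at P97), not affine rescaling to [0, 1]. Clamping is the
  minimal interpretation, and the 70% ratio rule only compares the two
  channels within a pixel, where a per-channel rescale would silently
  change scores. The alternative reading is available behind
  `rescale_after_clip` so both are testable.
* Percentiles are computed **over on-tissue measured pixels only**
  (linear interpolation between order statistics). Including off-tissue
  background would let the empty margin set the floor of every channel.

Exact ties — including pixels where both clipped channels sit at the
common floor — classify as YELLOW (`lo >= 0.7*hi` holds with equality);
there is no signal floor in the rule itself, and an optional
`min_signal_fraction`-style exclusion was deliberately not made the
default. The score is invariant under swapping the channels and under
scaling both channels by a positive constant.

## Noise estimation and peak picking

Noise is `1.4826 × MAD` of the intensities in a sliding 50 Th window
(MAD is robust to the peaks themselves); the rolling median of the same
window serves as the local baseline. A peak's S/N is its apex height
*above that baseline* divided by the local noise. The estimate is floored
at a machine-epsilon multiple of the maximum intensity so ratios stay
finite on idealized noise-free inputs.

Candidate apexes are located on a lightly Gaussian-smoothed trace
(σ = 0.15 Th by default) while the noise level comes from the raw
signal. This asymmetry is deliberate: raw white noise over ~10⁴ axis
points contains a dozen excursions above 3σ *by construction*, so a
picker thresholding raw maxima at S/N 3 can never achieve a low false
discovery rate. Smoothing suppresses single-point noise excursions by
~1/√(2√π σ_pts) while barely attenuating real peaks that are several
points wide, which is what yields recall ≥ 0.95 at true S/N ≥ 5 together
with FDR ≈ 0 at threshold 3 on the planted-peak suite. Vendor pickers do
the same implicitly; since the vendor noise estimator is unpublished,
S/N values are comparable only within this implementation.

Monoisotopic reduction ("SNAP-style") collapses chains of peaks spaced
≈ 1.00235 Th (charge 1; all relevant species are singly protonated
peptides) whose intensity profile matches the averagine envelope —
composition C₄.₉₃₈₄H₇.₇₅₈₃N₁.₃₅₇₇O₁.₄₇₇₃S₀.₀₄₁₇ per 111.1254 Da,
isotopologue abundances by truncated polynomial expansion (5 terms) —
to the chain's lowest-mass member. Chain agreement is Pearson r ≥ 1 −
`envelope_tol` (default 0.15) for chains of ≥ 3; for two-member chains,
where Pearson degenerates to ±1, the observed second/first ratio must
lie within a factor of two of the predicted one. Duplicate maxima within
0.1 Th merge to the strongest. Reduction never increases the peak count.

`filter_by_snr` keeps `snr >= threshold` by default; the quality metrics
below use the strict `>` reading of "above S/N 3" (boundary peaks are
measure-zero in practice; both comparisons are config-exposed).

## Spectral quality and bootstrap CIs

The QC report samples n = 100 on-tissue spectra uniformly without
replacement (seeded), picks peaks at min S/N 1 / max 10 000, and
summarises four per-spectrum counts — total peaks, peaks with S/N > 3,
peaks with m/z > 1500, m/z > 2000 — as medians with percentile-bootstrap
95% CIs: 1000 resamples with replacement, median of each, CI = 2.5th and
97.5th percentiles of the bootstrap medians. The percentile method (not
BCa) is the simplest defensible choice for a median CI; its empirical
coverage for the median of 50 normal samples measures ≈ 0.95 in the
acceptance run. Fewer than 100 replicates triggers an instability
warning.

## Peak-intensity CV across runs

Each run's average spectrum is TIC-normalized and picked at S/N 3;
each target m/z must match at most one peak within ±0.25 Th (two matches
raise an ambiguity error listing the candidates). Unmatched targets
contribute intensity 0 and lower the per-target `n_matched` flag instead
of being dropped — silent dropping would bias the CV downward. CV% =
100 × sample SD (n − 1) / mean, appropriate for ~10-run designs. TIC
normalization makes the table invariant to any common per-run scale
factor (site effects, laser power drift).

## Segmentation and PCA

The feature matrix is built per dataset by TIC-normalizing all spectra,
picking peaks on the dataset mean spectrum (S/N 3), and merging peak
positions across datasets into consensus bins by single linkage within
0.3 Th (TOF jitter scale). Per pixel, intensity is integrated ±0.25 Th
around each consensus position after an optional 3-point moving average
("weak denoising" — the weakest sensible smoother; width 0 disables).

Bisecting k-means: repeatedly split the leaf with the largest
within-cluster sum of correlation distances to its centroid (the
standard bisecting heuristic, stated explicitly so trees are
reproducible) using 2-means with correlation-distance assignment,
arithmetic-mean centroids, and 10 restarts seeded from the stream RNG
with a random pair of distinct rows; the best restart by within-cluster
distance sum wins. Splitting stops at `max_depth` or when no leaf holds
two distinct rows. Zero-variance rows inside k-means are assigned by a
Euclidean fallback; the public `correlation_distance` raises on them
instead of guessing.

PCA standardizes columns to unit variance (numerically-constant columns
are dropped with a warning), so components are eigenvectors of the
feature correlation matrix; explained-variance fractions are eigenvalues
over the number of retained columns, non-increasing and summing to ≤ 1.
Requests beyond the matrix rank are reduced with a warning.

## The phantom: what it emulates, what it does not

Geometry: 100×100 grid, 10% off-tissue margin, an outer "muscle" band
covering 20% of the tissue width, inner "villi" area — the smallest
geometry with enough boundary pixels for stable scores. One marker
peptide per region (944.6 villi, 1105.6 muscle, both at mean intensity
40) plus eight shared peptides spanning the mass range (including the
trypsin-autolysis masses 842.51 and 2211.10). Spectra are synthesized on
a shared 0.1 Th axis over m/z 600–3200 (26 001 points) with Gaussian
peak shapes at constant resolving power R = 10 000 and optional
averagine isotope envelopes.

Corruption models are phenomenological, not physical:

* **Delocalization blur**: Gaussian filter of the analyte maps
  (σ in pixels). The blurred edge profile follows the analytic error
  function, verified against an erf oracle.
* **Droplets**: inside a disc, every analyte map is replaced by its disc
  mean and re-blurred with a smear σ — signal is locally homogenized,
  not deleted, which is what turns boundary-straddling droplets into
  mixed (YELLOW) pixels.
* **Noise**: additive baseline drawn as |N(0, σ)| (the instrument
  subtracts baseline during acquisition, so only a small non-negative
  residual is modelled — this also keeps intensities non-negative), and
  per-pixel multiplicative log-normal jitter (σ_ln = 0.1).
* **Run-level variation**: `replicate_cohort` additionally draws one
  log-normal factor per analyte per run (σ_ln = 0.2 by default) plus an
  overall per-run site effect. The distinction matters: per-pixel jitter
  averages out over ~10³ pixels in a mean spectrum (residual CV < 1%),
  so only the run-level factor survives averaging and drives the
  cross-run CV, which then matches the analytic log-normal value
  √(exp(σ²) − 1) ≈ 20.2% at σ_ln = 0.2. The measured median CV sits
  slightly below that (≈ 16–18%) because the TIC-normalized apex sits on
  a small constant baseline shared by all runs.

The phantom does **not** model digestion kinetics, matrix
crystallization, ionization suppression, mass-calibration drift, or
chemical noise structure; passing tests therefore demonstrate that the
*estimators* behave correctly on data with known truth, not that any
particular real preparation will hit a particular score. Realistic blur
and droplet magnitudes for "good" vs "bad" preparations are not
derivable from first principles; the phantom targets the qualitative
ordering (clean < blurred, clean < droplet-corrupted), which is what the
tests assert.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds; pipeline stages derive
independent seeds from one master seed via a documented counter scheme
(`msiqc.config.stage_seed`). Generating the same spec and seed twice is
bitwise identical, and the full simulate-plus-QC pipeline reruns
byte-identically.

Test and acceptance runs use scaled-down phantoms — 32×32 grids on an
m/z 800–1300 axis for resolution/segmentation properties, 24×24 on the
full axis for cohort CVs — chosen so the whole battery exercises the
identical code paths at desk scale; the end-to-end determinism check
runs the full-size 100×100 / m/z 600–3200 default once (twice, for the
rerun comparison). Statistical acceptance bands (bootstrap coverage
0.91–0.98, cohort median CV 15–27%, ARI ≥ 0.9, recall ≥ 0.95,
FDR ≤ 0.05) are properties of the stated study conditions, not tuned
constants.

## Known limitations

* S/N values are estimator-specific; do not compare them numerically
  against vendor software.
* Charge state is fixed at 1; no charge deconvolution, no ppm-level
  mass-accuracy modelling, no centroid recalibration.
* The segmentation preprocessing is a documented stand-in for
  unpublished vendor pipelines; batch-vs-biology conclusions are
  asserted only on phantom data where truth is known.
* `correlation_distance` requires non-constant vectors; constant spectra
  are only handled inside k-means (Euclidean fallback).
* The mixed-pixel score is defined for exactly two channels; no
  multi-channel generalization or sub-pixel boundary estimation.
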