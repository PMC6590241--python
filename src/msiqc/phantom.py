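"""Synthetic MSI phantom with known ground truth.

The default phantom mimics a small-intestine cross-section imaged at
50 µm pixel pitch: an off-tissue margin, an outer "muscle" band and an
inner "villi" area.  One marker peptide is placed in each region
(m/z 944.6 in villi, m/z 1105.6 in muscle) plus a set of shared peptides
present across the whole tissue.  Corruption models are phenomenological:

* Gaussian *delocalization blur* of the analyte maps (lateral analyte
  spread during wet preparation steps);
* *condensation droplets* that locally homogenize the analyte maps inside
  a disc (delocalized, not lost, signal);
* per-pixel multiplicative log-normal intensity jitter and an additive
  non-negative baseline (|N(0, σ)|; the instrument subtracts baseline
  during acquisition, so only a small non-negative residual remains).

Spectra are synthesized on a shared m/z axis with Gaussian peak shapes of
constant resolving power and optional averagine isotope envelopes; every
dataset is bit-reproducible given the spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .core import MSIDataset, MassSpectrum, TissueMask
from .peaks import ISOTOPE_SPACING, averagine_envelope

__all__ = [
    "Analyte",
    "Droplet",
    "PhantomSpec",
    "PhantomTruth",
    "REGION_OFF",
    "REGION_MUSCLE",
    "REGION_VILLI",
    "default_analytes",
    "build_truth",
    "apply_droplet_artifact",
    "synthesize_dataset",
    "generate_phantom",
    "replicate_cohort",
    "truth_channel_map",
    "synthetic_peak_spectrum",
]

REGION_OFF = 0
REGION_MUSCLE = 1
REGION_VILLI = 2

_REGION_CODES = {"off": REGION_OFF, "muscle": REGION_MUSCLE, "villi": REGION_VILLI}


@dataclass(frozen=True)
class Analyte:
    """One analyte: monoisotopic m/z, mean on-region intensity, host region
    ("villi", "muscle" or "all"), and whether to synthesize its isotope envelope."""

    mz: float
    mean_intensity: float
    region: str = "all"
    isotopes: bool = True


@dataclass(frozen=True)
class Droplet:
    """Condensation-droplet artifact: disc center (col, row), radius and
    post-homogenization smear σ, all in pixels."""

    center: tuple[int, int]
    radius_px: float
    smear_sigma: float = 1.0


def default_analytes(mz_min: float | None = None, mz_max: float | None = None) -> list[Analyte]:
    """The default analyte panel, optionally restricted to an axis range
    (for scaled-down phantoms on a narrower m/z axis)."""
    panel = _default_analytes()
    if mz_min is not None:
        panel = [a for a in panel if a.mz >= mz_min]
    if mz_max is not None:
        panel = [a for a in panel if a.mz <= mz_max]
    return panel


def _default_analytes() -> list[Analyte]:
    # region markers (villi/lumen vs crypt/muscle) plus shared tryptic
    # peptides spread over the acquisition range; 842.51 and 2211.10 are the
    # classic trypsin-autolysis masses
    return [
        Analyte(944.60, 40.0, "villi"),
        Analyte(1105.60, 40.0, "muscle"),
        Analyte(842.51, 25.0, "all"),
        Analyte(1045.56, 18.0, "all"),
        Analyte(1296.68, 22.0, "all"),
        Analyte(1570.68, 15.0, "all"),
        Analyte(1765.80, 12.0, "all"),
        Analyte(2211.10, 10.0, "all"),
        Analyte(2465.20, 9.0, "all"),
        Analyte(2932.59, 8.0, "all"),
    ]


@dataclass
class PhantomSpec:
    """Full recipe for one synthetic dataset.

    Geometry defaults: 100×100 grid at 50 µm pitch with a 10% off-tissue
    margin and an outer muscle band covering 20% of the tissue width.
    """

    n_cols: int = 100
    n_rows: int = 100
    pixel_size_um: float = 50.0
    margin_frac: float = 0.10
    band_frac: float = 0.20
    analytes: list[Analyte] = field(default_factory=_default_analytes)
    baseline_sigma: float = 1.0
    jitter_sigma_ln: float = 0.1
    blur_sigma_px: float = 0.0
    droplets: list[Droplet] = field(default_factory=list)
    mz_min: float = 600.0
    mz_max: float = 3200.0
    mz_step: float = 0.1
    resolving_power: float = 10_000.0
    n_isotopes: int = 5
    seed: int = 0

    def mz_axis(self) -> np.ndarray:
        n = int(round((self.mz_max - self.mz_min) / self.mz_step)) + 1
        return self.mz_min + self.mz_step * np.arange(n)

    def validate(self) -> None:
        if self.n_cols < 4 or self.n_rows < 4:
            raise ValueError("grid must be at least 4x4")
        for a in self.analytes:
            if a.region not in ("villi", "muscle", "all"):
                raise ValueError(f"unknown region {a.region!r} for analyte {a.mz}")
            if not (self.mz_min <= a.mz <= self.mz_max):
                raise ValueError(
                    f"analyte m/z {a.mz} outside axis range "
                    f"[{self.mz_min}, {self.mz_max}]"
                )


@dataclass
class PhantomTruth:
    """Ground truth for a generated phantom: region labels, the per-analyte
    spatial intensity fields before noise, the tissue mask, and the spec."""

    region_labels: np.ndarray  # (n_rows, n_cols) of REGION_* codes
    analyte_maps: dict[float, np.ndarray]  # analyte mz -> (n_rows, n_cols) field
    mask: TissueMask
    spec: PhantomSpec


def _region_geometry(spec: PhantomSpec) -> np.ndarray:
    labels = np.full((spec.n_rows, spec.n_cols), REGION_OFF, dtype=np.int8)
    mc = int(round(spec.margin_frac * spec.n_cols))
    mr = int(round(spec.margin_frac * spec.n_rows))
    tissue_w = spec.n_cols - 2 * mc
    tissue_h = spec.n_rows - 2 * mr
    if tissue_w < 3 or tissue_h < 3:
        raise ValueError("margins leave too little tissue")
    band = max(1, int(round(spec.band_frac * min(tissue_w, tissue_h))))
    labels[mr : spec.n_rows - mr, mc : spec.n_cols - mc] = REGION_MUSCLE
    r0, r1 = mr + band, spec.n_rows - mr - band
    c0, c1 = mc + band, spec.n_cols - mc - band
    if r1 > r0 and c1 > c0:
        labels[r0:r1, c0:c1] = REGION_VILLI
    return labels


def build_truth(spec: PhantomSpec) -> PhantomTruth:
    """Construct the noiseless ground truth: region geometry, blurred analyte
    maps, droplet artifacts, and the tissue mask."""
    spec.validate()
    labels = _region_geometry(spec)
    mask = TissueMask(labels != REGION_OFF)
    maps: dict[float, np.ndarray] = {}
    for a in spec.analytes:
        if a.region == "all":
            indicator = (labels != REGION_OFF).astype(np.float64)
        else:
            indicator = (labels == _REGION_CODES[a.region]).astype(np.float64)
        m = indicator * a.mean_intensity
        if spec.blur_sigma_px > 0:
            m = gaussian_filter(m, spec.blur_sigma_px)
        maps[a.mz] = m
    truth = PhantomTruth(labels, maps, mask, spec)
    for d in spec.droplets:
        truth = apply_droplet_artifact(truth, d.center, d.radius_px, d.smear_sigma)
    return truth


def apply_droplet_artifact(
    truth: PhantomTruth,
    center: tuple[int, int],
    radius_px: float,
    smear_sigma: float = 1.0,
) -> PhantomTruth:
    """Homogenize every analyte map inside a disc (condensation droplet).

    Inside the disc each map is replaced by its disc mean, then re-blurred
    with ``smear_sigma``; pixels outside the disc are unchanged.  Signal is
    delocalized, not deleted.
    """
    if radius_px <= 0:
        raise ValueError("droplet radius must be positive")
    n_rows, n_cols = truth.region_labels.shape
    c0, r0 = center
    cc, rr = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    disc = (cc - c0) ** 2 + (rr - r0) ** 2 <= radius_px**2
    if not disc.any():
        raise ValueError(
            f"droplet at {center} with radius {radius_px} lies fully off the grid"
        )
    new_maps: dict[float, np.ndarray] = {}
    for mz, m in truth.analyte_maps.items():
        hom = m.copy()
        hom[disc] = m[disc].mean()
        if smear_sigma > 0:
            sm = gaussian_filter(hom, smear_sigma)
            hom = np.where(disc, sm, m)
        else:
            hom = np.where(disc, hom, m)
        new_maps[mz] = hom
    return PhantomTruth(truth.region_labels, new_maps, truth.mask, truth.spec)


def _peak_template(
    axis: np.ndarray, analyte: Analyte, spec: PhantomSpec
) -> tuple[int, np.ndarray]:
    """Sampled spectral footprint of one analyte (apex height 1 at the
    monoisotopic peak): returns (start index, template values)."""
    sigma = analyte.mz / spec.resolving_power / 2.3548
    if analyte.isotopes:
        weights = averagine_envelope(analyte.mz, spec.n_isotopes)
        weights = weights / weights[0]
        centers = analyte.mz + ISOTOPE_SPACING * np.arange(len(weights))
    else:
        weights = np.array([1.0])
        centers = np.array([analyte.mz])
    lo_mz = centers[0] - 5 * sigma
    hi_mz = centers[-1] + 5 * sigma
    lo = int(np.searchsorted(axis, lo_mz, side="left"))
    hi = int(np.searchsorted(axis, hi_mz, side="right"))
    window = axis[lo:hi]
    template = np.zeros(len(window))
    for w, c in zip(weights, centers):
        template += w * np.exp(-0.5 * ((window - c) / sigma) ** 2)
    return lo, template


def synthesize_dataset(truth: PhantomTruth, seed: int | None = None) -> MSIDataset:
    """Render spectra from ground truth: per pixel, the jittered analyte
    peaks plus a folded-normal baseline, on the shared m/z axis."""
    spec = truth.spec
    if seed is None:
        seed = spec.seed
    axis = spec.mz_axis()
    n_pts = len(axis)
    coords = [(c, r) for r in range(spec.n_rows) for c in range(spec.n_cols)]
    n_px = len(coords)
    rng = np.random.default_rng(seed)

    matrix = np.empty((n_px, n_pts), dtype=np.float32)
    if spec.baseline_sigma > 0:
        chunk = max(1, int(5e7) // n_pts)
        for start in range(0, n_px, chunk):
            stop = min(n_px, start + chunk)
            matrix[start:stop] = np.abs(
                rng.normal(0.0, spec.baseline_sigma, size=(stop - start, n_pts))
            ).astype(np.float32)
    else:
        matrix[:] = 0.0

    for a in spec.analytes:
        amp = truth.analyte_maps[a.mz].ravel()  # row-major == coords order
        if spec.jitter_sigma_ln > 0:
            jitter = rng.lognormal(0.0, spec.jitter_sigma_ln, size=n_px)
        else:
            jitter = np.ones(n_px)
        lo, template = _peak_template(axis, a, spec)
        if len(template) == 0:
            continue
        contrib = (amp * jitter)[:, None] * template[None, :]
        matrix[:, lo : lo + len(template)] += contrib.astype(np.float32)

    return MSIDataset.from_matrix(
        axis, matrix, coords, spec.n_cols, spec.n_rows, spec.pixel_size_um
    )


def generate_phantom(spec: PhantomSpec) -> tuple[MSIDataset, PhantomTruth]:
    """Build ground truth and synthesize the corresponding dataset."""
    truth = build_truth(spec)
    return synthesize_dataset(truth, spec.seed), truth


def replicate_cohort(
    spec: PhantomSpec,
    n_runs: int,
    site_effects: Sequence[float] | None = None,
    seed: int = 0,
    run_jitter_sigma_ln: float = 0.2,
) -> list[tuple[MSIDataset, PhantomTruth]]:
    """Repeated acquisitions of the same geometry.

    Each run is an independent noise/jitter realization; in addition every
    analyte receives a per-run multiplicative log-normal factor
    (σ = ``run_jitter_sigma_ln``, acquisition-day variability — this
    run-level factor, not the per-pixel jitter, is what survives averaging
    over pixels and drives cross-run CVs) and the whole run is scaled by
    its ``site_effects`` entry.  Run seeds derive from the master seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if site_effects is None:
        site_effects = [1.0] * n_runs
    if len(site_effects) != n_runs:
        raise ValueError("need one site effect per run")
    base_truth = build_truth(spec)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_runs + 1)
    factor_rng = np.random.default_rng(children[0])
    out = []
    for k in range(n_runs):
        maps = {}
        for mz, m in base_truth.analyte_maps.items():
            f = (
                factor_rng.lognormal(0.0, run_jitter_sigma_ln)
                if run_jitter_sigma_ln > 0
                else 1.0
            )
            maps[mz] = m * f * site_effects[k]
        truth_k = PhantomTruth(
            base_truth.region_labels, maps, base_truth.mask, spec
        )
        run_seed = int(children[k + 1].generate_state(1)[0] % (2**31))
        out.append((synthesize_dataset(truth_k, run_seed), truth_k))
    return out


def truth_channel_map(
    truth: PhantomTruth, mz_center: float, mz_tol: float
) -> np.ndarray:
    """Noiseless channel intensity from ground truth: the sum of analyte
    maps whose monoisotopic m/z lies in the closed extraction window.
    The geometric boundary set of two channels is where both are > 0."""
    total = np.zeros_like(truth.region_labels, dtype=np.float64)
    for a in truth.spec.analytes:
        if abs(a.mz - mz_center) <= mz_tol:
            total += truth.analyte_maps[a.mz]
    return total


def synthetic_peak_spectrum(
    peak_mzs: Sequence[float],
    snrs: Sequence[float],
    *,
    mz_min: float = 600.0,
    mz_max: float = 1600.0,
    mz_step: float = 0.1,
    noise_sigma: float = 1.0,
    peak_sigma: float = 0.2,
    seed: int = 0,
) -> MassSpectrum:
    """Flat-noise spectrum with Gaussian peaks of known true S/N planted at
    given positions (no isotope envelopes) — the fixture generator for
    picker recall/precision checks.  True S/N is apex amplitude over the
    noise σ."""
    rng = np.random.default_rng(seed)
    n = int(round((mz_max - mz_min) / mz_step)) + 1
    axis = mz_min + mz_step * np.arange(n)
    intensity = np.abs(rng.normal(0.0, noise_sigma, size=n))
    for mz0, snr in zip(peak_mzs, snrs):
        intensity += snr * noise_sigma * np.exp(-0.5 * ((axis - mz0) / peak_sigma) ** 2)
    return MassSpectrum(axis, intensity, _validate=False)
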