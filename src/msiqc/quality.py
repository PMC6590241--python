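"""Spectral-quality QC and cross-run peak-intensity variability.

The QC workflow samples a fixed number of on-tissue spectra (100 by
default), picks peaks on each, and summarises four per-spectrum counts —
total peaks, peaks above S/N 3, peaks over m/z 1500 and over m/z 2000 —
as medians with percentile-bootstrap 95% confidence intervals.  The m/z
and S/N cutoffs use strict ``>`` ("above"/"over"); boundary peaks are
measure-zero in practice and both cutoffs are configurable.

Cross-run reproducibility is quantified by the coefficient of variation
(CV, sample SD over mean) of matched peak intensities across the
TIC-normalized average spectra of repeated acquisitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DegenerateInputError, MassSpectrum, MSIDataset, TissueMask, tic_normalize
from .peaks import PeakList, pick_peaks

__all__ = [
    "SpectralQualityReport",
    "IntensityCVTable",
    "sample_spectra",
    "quality_metrics",
    "bootstrap_median_ci",
    "intensity_cv",
    "spectral_quality",
]

METRIC_NAMES = (
    "peaks_per_spectrum",
    "peaks_snr_gt3",
    "peaks_mz_gt1500",
    "peaks_mz_gt2000",
)


@dataclass
class SpectralQualityReport:
    """Medians and bootstrap CIs of the four per-spectrum QC counts."""

    n_sampled: int
    metrics: dict  # name -> {"median": float, "ci_lo": float, "ci_hi": float}
    seed: int
    n_boot: int
    per_spectrum_counts: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "n_sampled": self.n_sampled,
            "seed": self.seed,
            "n_boot": self.n_boot,
            "metrics": self.metrics,
        }


@dataclass
class IntensityCVTable:
    """Per-target mean ± SD and CV% of matched peak intensities across runs."""

    table: pd.DataFrame  # columns: target_mz, mean, sd, cv_percent, n_matched
    intensities: np.ndarray  # (n_runs, n_targets)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sample_spectra(
    dataset: MSIDataset,
    mask: TissueMask,
    n: int = 100,
    seed: int = 0,
) -> list[MassSpectrum]:
    """Uniform sample of ``n`` on-tissue spectra without replacement,
    reproducible given the seed."""
    mask.check_against(dataset)
    population = [cr for cr in dataset.coords if mask.grid[cr[1], cr[0]]]
    if n > len(population):
        raise ValueError(
            f"requested n={n} spectra but only {len(population)} on-tissue "
            "measured pixels are available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(population), size=n, replace=False)
    return [dataset[population[i]] for i in idx]


def bootstrap_median_ci(
    values: Sequence[float],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile-bootstrap confidence interval for the median.

    Draws ``n_boot`` resamples with replacement, takes the median of each,
    and returns the ((1−level)/2, 1−(1−level)/2) percentiles of those
    bootstrap medians.
    """
    values = np.asarray(values, dtype=np.float64)
    if len(values) < 2:
        raise DegenerateInputError("bootstrap CI requires at least 2 values")
    if not (0 < level < 1):
        raise ValueError(f"level must be in (0, 1), got {level}")
    if n_boot < 100:
        warnings.warn(
            f"n_boot={n_boot} < 100 gives an unstable confidence interval",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(medians, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def quality_metrics(
    peaklists: Sequence[PeakList],
    *,
    snr_cutoff: float = 3.0,
    mz_cutoffs: tuple[float, float] = (1500.0, 2000.0),
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> SpectralQualityReport:
    """Summarise per-spectrum peak counts as medians with bootstrap CIs.

    Counts per spectrum: total peaks; peaks with S/N strictly above
    ``snr_cutoff``; peaks with m/z strictly above each of ``mz_cutoffs``.
    """
    if len(peaklists) == 0:
        raise DegenerateInputError("quality_metrics requires at least one peaklist")
    rows = []
    for pl in peaklists:
        snr = pl.snr
        mz = pl.mz
        rows.append(
            {
                "peaks_per_spectrum": len(pl),
                "peaks_snr_gt3": int(np.count_nonzero(snr > snr_cutoff)),
                "peaks_mz_gt1500": int(np.count_nonzero(mz > mz_cutoffs[0])),
                "peaks_mz_gt2000": int(np.count_nonzero(mz > mz_cutoffs[1])),
            }
        )
    counts = pd.DataFrame(rows)
    metrics = {}
    for k, name in enumerate(METRIC_NAMES):
        vals = counts[name].to_numpy()
        med = float(np.median(vals))
        if len(vals) >= 2:
            lo, hi = bootstrap_median_ci(vals, n_boot=n_boot, level=level, seed=seed + k)
        else:
            lo = hi = med
        metrics[name] = {"median": med, "ci_lo": lo, "ci_hi": hi}
    return SpectralQualityReport(
        n_sampled=len(peaklists),
        metrics=metrics,
        seed=seed,
        n_boot=n_boot,
        per_spectrum_counts=counts,
    )


def spectral_quality(
    dataset: MSIDataset,
    mask: TissueMask,
    n: int = 100,
    seed: int = 0,
    *,
    min_snr: float = 1.0,
    max_peaks: int = 10_000,
    n_boot: int = 1000,
    level: float = 0.95,
    **pick_kwargs,
) -> SpectralQualityReport:
    """Convenience pipeline: sample spectra → pick peaks → quality metrics."""
    spectra = sample_spectra(dataset, mask, n=n, seed=seed)
    peaklists = [pick_peaks(s, min_snr=min_snr, max_peaks=max_peaks, **pick_kwargs) for s in spectra]
    return quality_metrics(peaklists, n_boot=n_boot, level=level, seed=seed)


def intensity_cv(
    average_spectra: Sequence[MassSpectrum],
    target_mzs: Sequence[float],
    tol: float = 0.25,
    min_snr: float = 3.0,
    **pick_kwargs,
) -> IntensityCVTable:
    """Coefficient of variation of target-peak intensities across runs.

    Each run's average spectrum is TIC-normalized and peak-picked at
    ``min_snr``; for every target m/z the single matching peak within
    ``tol`` Th contributes its intensity (0 with a completeness flag if
    unmatched — dropping silently would bias the CV downward).  Across
    runs the table reports mean, sample SD (n−1) and CV% = 100 × SD/mean.
    """
    if len(average_spectra) < 2:
        raise DegenerateInputError("intensity_cv requires at least 2 average spectra")
    target_mzs = np.asarray(target_mzs, dtype=np.float64)
    n_runs, n_t = len(average_spectra), len(target_mzs)
    intensities = np.zeros((n_runs, n_t))
    for i, spec in enumerate(average_spectra):
        norm = tic_normalize(spec)
        pl = pick_peaks(norm, min_snr=min_snr, **pick_kwargs)
        pk_mz = pl.mz
        pk_int = pl.intensity
        for j, t in enumerate(target_mzs):
            hits = np.flatnonzero(np.abs(pk_mz - t) <= tol)
            if len(hits) > 1:
                cands = ", ".join(f"{pk_mz[h]:.4f}" for h in hits)
                raise ValueError(
                    f"target m/z {t:.4f} matched by {len(hits)} peaks within "
                    f"±{tol} Th in run {i}: {cands}"
                )
            if len(hits) == 1:
                intensities[i, j] = pk_int[hits[0]]
    mean = intensities.mean(axis=0)
    sd = intensities.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    table = pd.DataFrame(
        {
            "target_mz": target_mzs,
            "mean": mean,
            "sd": sd,
            "cv_percent": cv,
            "n_matched": (intensities > 0).sum(axis=0),
        }
    )
    return IntensityCVTable(table=table, intensities=intensities)
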