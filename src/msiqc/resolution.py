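"""Mixed-pixel spatial-resolution scoring for two-channel MSI images.

Two ion images are chosen for analytes specific to adjacent tissue regions
(a "red" and a "green" channel).  Each channel is clipped to its 3rd/97th
intensity percentiles over on-tissue pixels; a pixel whose weaker channel
reaches at least 70% of its stronger channel is a "yellow" (mixed) pixel,
otherwise it takes the colour of the stronger channel.  The score is the
percentage of yellow pixels among classified on-tissue pixels — a proxy
for analyte delocalization: the blurrier the preparation, the more pixels
receive both region-specific signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .core import (
    DegenerateInputError,
    IonImage,
    MSIDataset,
    TissueMask,
    extract_ion_image,
)

__all__ = [
    "PixelLabel",
    "MixedPixelResult",
    "clip_channel",
    "classify_pixels",
    "spatial_resolution_score",
]


class PixelLabel(IntEnum):
    EXCLUDED = 0
    RED = 1
    GREEN = 2
    YELLOW = 3


@dataclass
class MixedPixelResult:
    """Per-pixel RED/GREEN/YELLOW/EXCLUDED labels plus the scalar score.

    ``score_percent`` is 100 × |YELLOW| / (|RED| + |GREEN| + |YELLOW|).
    """

    labels: np.ndarray  # int8 raster of PixelLabel values
    score_percent: float
    params: dict

    def counts(self) -> dict[str, int]:
        return {
            lab.name: int(np.count_nonzero(self.labels == lab))
            for lab in PixelLabel
        }


def clip_channel(
    image: IonImage,
    mask: TissueMask,
    low_pct: float = 3.0,
    high_pct: float = 97.0,
    *,
    rescale_after_clip: bool = False,
) -> IonImage:
    """Clamp a channel to its [low_pct, high_pct] percentiles.

    Percentiles are computed over on-tissue measured pixels only (linear
    interpolation between order statistics); values below the floor are
    raised to it and values above the ceiling lowered to it.  Off-tissue
    pixels are left untouched.  With ``rescale_after_clip`` the clamped
    on-tissue values are additionally mapped affinely onto [0, 1] — an
    alternative reading of "set to the percentile" that changes nothing
    for the ratio rule unless channels are compared across images.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError(f"need 0 <= low_pct < high_pct <= 100, got {low_pct}, {high_pct}")
    if image.values.shape != mask.grid.shape:
        raise ValueError(
            f"image shape {image.values.shape} != mask shape {mask.grid.shape}"
        )
    sel = mask.grid & image.valid
    n_sel = int(np.count_nonzero(sel))
    if n_sel < 2:
        raise DegenerateInputError(
            f"need at least 2 on-tissue measured pixels to clip, got {n_sel}"
        )
    vals = image.values[sel]
    p_lo, p_hi = np.percentile(vals, [low_pct, high_pct])
    out = image.values.copy()
    if p_lo == p_hi:
        warnings.warn(
            f"percentiles P{low_pct:g} and P{high_pct:g} coincide at {p_lo:g}; "
            "channel is constant after clipping",
            stacklevel=2,
        )
        out[sel] = p_lo
    else:
        out[sel] = np.clip(vals, p_lo, p_hi)
        if rescale_after_clip:
            out[sel] = (out[sel] - p_lo) / (p_hi - p_lo)
    return IonImage(out, image.valid.copy(), image.mz_center, image.mz_tol)


def classify_pixels(
    red: IonImage,
    green: IonImage,
    mask: TissueMask,
    ratio: float = 0.70,
) -> MixedPixelResult:
    """Label each on-tissue pixel RED, GREEN or YELLOW by the intensity-ratio rule.

    Per pixel with red value *a* and green value *b*: if min(a, b) ≥
    ratio × max(a, b) the pixel is YELLOW, otherwise it takes the colour
    of the larger channel.  Exact ties (including both-zero pixels) are
    YELLOW by this rule.  Off-mask and unmeasured pixels are EXCLUDED.
    Channels are expected to be percentile-clipped already.
    """
    if not (0 < ratio <= 1):
        raise ValueError(f"ratio must be in (0, 1], got {ratio}")
    if red.values.shape != green.values.shape or red.values.shape != mask.grid.shape:
        raise ValueError(
            f"dimension mismatch: red {red.values.shape}, green {green.values.shape}, "
            f"mask {mask.grid.shape}"
        )
    a, b = red.values, green.values
    sel = mask.grid & red.valid & green.valid
    labels = np.full(mask.grid.shape, PixelLabel.EXCLUDED, dtype=np.int8)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    yellow = sel & (lo >= ratio * hi)
    red_px = sel & ~yellow & (a > b)
    green_px = sel & ~yellow & (b > a)
    labels[yellow] = PixelLabel.YELLOW
    labels[red_px] = PixelLabel.RED
    labels[green_px] = PixelLabel.GREEN
    n_classified = int(np.count_nonzero(sel))
    if n_classified == 0:
        raise DegenerateInputError("no on-tissue measured pixels to classify")
    score = 100.0 * np.count_nonzero(yellow) / n_classified
    return MixedPixelResult(labels, score, {"ratio": ratio})


def spatial_resolution_score(
    dataset: MSIDataset,
    mask: TissueMask,
    red_mz: float,
    green_mz: float,
    *,
    mz_tol: float = 0.25,
    low_pct: float = 3.0,
    high_pct: float = 97.0,
    ratio: float = 0.70,
    reducer: str = "sum",
    rescale_after_clip: bool = False,
) -> MixedPixelResult:
    """Full mixed-pixel pipeline: extract both channels, clip, classify.

    The result's ``params`` record every parameter used.
    """
    mask.check_against(dataset)
    red = extract_ion_image(dataset, red_mz, mz_tol, reducer)
    green = extract_ion_image(dataset, green_mz, mz_tol, reducer)
    red = clip_channel(red, mask, low_pct, high_pct, rescale_after_clip=rescale_after_clip)
    green = clip_channel(green, mask, low_pct, high_pct, rescale_after_clip=rescale_after_clip)
    result = classify_pixels(red, green, mask, ratio)
    result.params = {
        "red_mz": red_mz,
        "green_mz": green_mz,
        "mz_tol": mz_tol,
        "low_pct": low_pct,
        "high_pct": high_pct,
        "ratio": ratio,
        "reducer": reducer,
        "rescale_after_clip": rescale_after_clip,
    }
    return result
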