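"""Core data model and I/O for MALDI mass-spectrometry imaging datasets.

An MSI dataset is a rectangular raster of pixels, each carrying one mass
spectrum.  Internally everything uses 0-based ``(col, row)`` pixel
coordinates with the origin at the top-left, matching raster-image
convention; imzML's 1-based coordinates are converted at the I/O boundary.
Rasters (masks, ion images) are stored as numpy arrays of shape
``(n_rows, n_cols)`` indexed ``[row, col]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np

__all__ = [
    "MassSpectrum",
    "MSIDataset",
    "TissueMask",
    "IonImage",
    "read_imzml",
    "write_imzml",
    "read_mask",
    "write_mask",
    "tic_normalize",
    "extract_ion_image",
    "mask_from_tic",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but unusable (e.g. all-zero spectrum)."""


class MassSpectrum:
    """A single mass spectrum: m/z values (Th) and non-negative intensities.

    Parameters
    ----------
    mz
        Strictly increasing mass-to-charge axis in thomson.
    intensity
        Non-negative abundances, same length as ``mz``.
    pixel_index
        Optional ``(col, row)`` grid coordinate of the acquiring pixel.
    """

    __slots__ = ("mz", "intensity", "pixel_index")

    def __init__(self, mz, intensity, pixel_index=None, *, _validate=True):
        mz = np.asarray(mz, dtype=np.float64)
        intensity = np.asarray(intensity)
        if not np.issubdtype(intensity.dtype, np.floating):
            intensity = intensity.astype(np.float64)
        if _validate:
            if mz.ndim != 1 or intensity.ndim != 1:
                raise ValueError("mz and intensity must be 1-D arrays")
            if len(mz) != len(intensity):
                raise ValueError(
                    f"mz and intensity length mismatch: {len(mz)} vs {len(intensity)}"
                )
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise ValueError("mz axis must be strictly increasing")
            if np.any(intensity < 0):
                raise ValueError("intensities must be non-negative")
        self.mz = mz
        self.intensity = intensity
        self.pixel_index = pixel_index

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def tic(self) -> float:
        """Total ion current (sum of intensities)."""
        return float(self.intensity.sum())

    def __repr__(self) -> str:
        return (
            f"MassSpectrum(n={len(self)}, "
            f"mz=[{self.mz[0]:.4g}..{self.mz[-1]:.4g}], pixel={self.pixel_index})"
        )


class MSIDataset:
    """Pixel-indexed collection of mass spectra on a rectangular grid.

    Missing pixels inside the bounding box are permitted (sparse
    acquisition); all per-pixel statistics iterate over measured pixels
    only.  In ``continuous`` mode all spectra share an identical m/z axis.
    """

    def __init__(
        self,
        spectra: Mapping[tuple[int, int], MassSpectrum] | Iterable[MassSpectrum],
        n_cols: int,
        n_rows: int,
        pixel_size_um: float = 50.0,
        mode: Literal["continuous", "processed"] = "continuous",
        mz_range: tuple[float, float] | None = None,
    ):
        if isinstance(spectra, Mapping):
            items = dict(spectra)
        else:
            items = {}
            for s in spectra:
                if s.pixel_index is None:
                    raise ValueError("spectra passed as a sequence must carry pixel_index")
                key = tuple(s.pixel_index)
                if key in items:
                    raise ValueError(f"duplicate spectrum for pixel {key}")
                items[key] = s
        for (c, r) in items:
            if not (0 <= c < n_cols and 0 <= r < n_rows):
                raise ValueError(
                    f"pixel ({c},{r}) outside grid {n_cols}x{n_rows}"
                )
        self._spectra = items
        self.n_cols = int(n_cols)
        self.n_rows = int(n_rows)
        self.pixel_size_um = float(pixel_size_um)
        self.mode = mode
        self._matrix: np.ndarray | None = None
        self._matrix_coords: list[tuple[int, int]] | None = None
        if mode == "continuous" and items:
            first = next(iter(items.values()))
            self._shared_mz = first.mz
            for s in items.values():
                if s.mz is not first.mz and not np.array_equal(s.mz, first.mz):
                    raise ValueError("continuous mode requires an identical mz axis for all spectra")
        else:
            self._shared_mz = None
        if mz_range is None and items:
            lo = min(float(s.mz[0]) for s in items.values())
            hi = max(float(s.mz[-1]) for s in items.values())
            mz_range = (lo, hi)
        self.mz_range = mz_range

    # -- construction -----------------------------------------------------
    @classmethod
    def from_matrix(
        cls,
        mz: np.ndarray,
        intensities: np.ndarray,
        coords: list[tuple[int, int]],
        n_cols: int,
        n_rows: int,
        pixel_size_um: float = 50.0,
    ) -> "MSIDataset":
        """Build a continuous-mode dataset from a dense pixel × m/z matrix.

        Row *i* of ``intensities`` is the spectrum of ``coords[i]``.  The
        matrix is retained for vectorised operations; spectra are views.
        """
        mz = np.asarray(mz, dtype=np.float64)
        if len(mz) > 1 and not np.all(np.diff(mz) > 0):
            raise ValueError("mz axis must be strictly increasing")
        if intensities.shape != (len(coords), len(mz)):
            raise ValueError("intensities shape must be (n_pixels, n_mz)")
        spectra = {}
        for i, (c, r) in enumerate(coords):
            spectra[(c, r)] = MassSpectrum(mz, intensities[i], (c, r), _validate=False)
        ds = cls(spectra, n_cols, n_rows, pixel_size_um, mode="continuous")
        ds._matrix = intensities
        ds._matrix_coords = [tuple(c) for c in coords]
        return ds

    # -- access ------------------------------------------------------------
    @property
    def coords(self) -> list[tuple[int, int]]:
        """Measured pixel coordinates in row-major order."""
        return sorted(self._spectra, key=lambda cr: (cr[1], cr[0]))

    @property
    def spectra(self) -> dict[tuple[int, int], MassSpectrum]:
        return self._spectra

    @property
    def shared_mz(self) -> np.ndarray | None:
        return self._shared_mz

    def __len__(self) -> int:
        return len(self._spectra)

    def __getitem__(self, key: tuple[int, int]) -> MassSpectrum:
        return self._spectra[tuple(key)]

    def __contains__(self, key) -> bool:
        return tuple(key) in self._spectra

    def intensity_matrix(self) -> tuple[np.ndarray, list[tuple[int, int]]]:
        """Dense ``(n_pixels, n_mz)`` matrix and its coordinate order.

        Only available for continuous-mode datasets.  Row order follows
        :attr:`coords` unless the dataset was built with
        :meth:`from_matrix`, whose original order is preserved.
        """
        if self.mode != "continuous":
            raise ValueError("intensity_matrix requires continuous mode")
        if self._matrix is not None:
            return self._matrix, list(self._matrix_coords)
        order = self.coords
        mat = np.vstack([self._spectra[c].intensity for c in order])
        return mat, order

    def tic_image(self) -> "IonImage":
        """Total-ion-current raster over the grid."""
        values = np.zeros((self.n_rows, self.n_cols))
        valid = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        if self._matrix is not None:
            tics = self._matrix.sum(axis=1)
            for (c, r), t in zip(self._matrix_coords, tics):
                values[r, c] = t
                valid[r, c] = True
        else:
            for (c, r), s in self._spectra.items():
                values[r, c] = s.tic
                valid[r, c] = True
        return IonImage(values, valid, mz_center=float("nan"), mz_tol=float("nan"))

    def __repr__(self) -> str:
        return (
            f"MSIDataset({self.n_cols}x{self.n_rows} grid, {len(self)} spectra, "
            f"{self.pixel_size_um:g} um pixels, mode={self.mode!r})"
        )


@dataclass
class TissueMask:
    """Binary on-tissue raster aligned to the MSI pixel grid (True = on tissue)."""

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D (n_rows, n_cols)")

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    def check_against(self, dataset: MSIDataset) -> None:
        if (self.n_rows, self.n_cols) != (dataset.n_rows, dataset.n_cols):
            raise ValueError(
                f"mask shape {self.grid.shape} does not match dataset grid "
                f"({dataset.n_rows}, {dataset.n_cols})"
            )


@dataclass
class IonImage:
    """2-D intensity raster for one m/z window.

    ``valid`` marks pixels that had a measured spectrum; values at invalid
    pixels are meaningless and must not be interpreted as zeros.
    """

    values: np.ndarray
    valid: np.ndarray
    mz_center: float
    mz_tol: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid rasters must have the same shape")


# ---------------------------------------------------------------------------
# imzML I/O (delegated to pyimzml)
# ---------------------------------------------------------------------------

def read_imzml(path) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Grid extents are inferred from the maximum 1-based pixel coordinates;
    continuous vs processed mode is taken from the file metadata.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    if not path.exists():
        raise IOError(f"imzML file not found: {path}")
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # lxml/struct errors from corrupt files
        raise IOError(f"failed to parse imzML file {path}: {exc}") from exc

    params = parser.metadata.file_description.param_by_name
    mode = "continuous" if "continuous" in params else "processed"

    n_cols = max(x for x, y, z in parser.coordinates)
    n_rows = max(y for x, y, z in parser.coordinates)
    spectra: dict[tuple[int, int], MassSpectrum] = {}
    shared_mz: np.ndarray | None = None
    for i, (x, y, _z) in enumerate(parser.coordinates):
        mzs, ints = parser.getspectrum(i)
        mzs = np.asarray(mzs, dtype=np.float64)
        if mode == "continuous":
            if shared_mz is None:
                shared_mz = mzs
            elif np.array_equal(mzs, shared_mz):
                mzs = shared_mz  # share one axis object
        if len(mzs) > 1 and not np.all(np.diff(mzs) > 0):
            raise ValueError(
                f"non-monotone m/z axis in spectrum at pixel (col={x - 1}, row={y - 1})"
            )
        spectra[(x - 1, y - 1)] = MassSpectrum(
            mzs, np.asarray(ints, dtype=np.float64), (x - 1, y - 1), _validate=False
        )
    return MSIDataset(spectra, n_cols, n_rows, mode=mode)


def write_imzml(dataset: MSIDataset, path) -> None:
    """Write a dataset as a standard imzML/ibd pair (float64 m/z, float32 intensity)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    if len(dataset) == 0:
        raise ValueError("refusing to write a dataset with zero measured pixels")
    path = Path(path)
    try:
        with ImzMLWriter(str(path), mode=dataset.mode) as writer:
            for (c, r) in dataset.coords:
                s = dataset[(c, r)]
                writer.addSpectrum(s.mz, s.intensity, (c + 1, r + 1, 1))
    except OSError as exc:
        raise IOError(f"cannot write imzML to {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Mask I/O: PNG/TIFF binary raster or plain-text RLE sidecar
# ---------------------------------------------------------------------------

def read_mask(path) -> TissueMask:
    """Read a tissue mask from a PNG/TIFF raster (nonzero = on tissue) or a
    text run-length file (first line ``n_cols n_rows``, then alternating
    off/on run lengths in row-major order, starting with an off run)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"mask file not found: {path}")
    if path.suffix.lower() in {".png", ".tif", ".tiff"}:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
        return TissueMask(arr > 0)
    tokens = path.read_text().split()
    if len(tokens) < 2:
        raise ValueError(f"malformed RLE mask file {path}")
    n_cols, n_rows = int(tokens[0]), int(tokens[1])
    runs = [int(t) for t in tokens[2:]]
    flat = np.zeros(n_cols * n_rows, dtype=bool)
    pos, on = 0, False
    for run in runs:
        flat[pos : pos + run] = on
        pos += run
        on = not on
    if pos != n_cols * n_rows:
        raise ValueError(
            f"RLE runs cover {pos} pixels, expected {n_cols * n_rows} in {path}"
        )
    return TissueMask(flat.reshape(n_rows, n_cols))


def write_mask(mask: TissueMask, path) -> None:
    """Write a mask as PNG (``.png``) or text RLE (any other suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        Image.fromarray((mask.grid.astype(np.uint8)) * 255).save(path)
        return
    flat = mask.grid.ravel()
    runs = []
    on = False
    count = 0
    for v in flat:
        if bool(v) == on:
            count += 1
        else:
            runs.append(count)
            on = bool(v)
            count = 1
    runs.append(count)
    path.write_text(
        f"{mask.n_cols} {mask.n_rows}\n" + " ".join(str(r) for r in runs) + "\n"
    )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def tic_normalize(spectrum: MassSpectrum) -> MassSpectrum:
    """Normalize a spectrum to unit total ion current.

    Idempotent and scale-invariant; raises :class:`DegenerateInputError`
    on an all-zero spectrum rather than producing NaNs.
    """
    total = spectrum.intensity.sum()
    if not total > 0:
        raise DegenerateInputError("cannot TIC-normalize a spectrum with zero total intensity")
    return MassSpectrum(
        spectrum.mz,
        spectrum.intensity / total,
        spectrum.pixel_index,
        _validate=False,
    )


_REDUCERS = {"sum": np.sum, "max": np.max, "mean": np.mean}


def extract_ion_image(
    dataset: MSIDataset,
    mz_center: float,
    mz_tol: float,
    reducer: Literal["sum", "max", "mean"] = "sum",
) -> IonImage:
    """Extract a 2-D ion image for the closed window [center−tol, center+tol].

    Per measured pixel the reducer is applied to intensities whose m/z lies
    in the window; pixels without spectra are flagged invalid.  An empty
    window at every pixel yields a warning and an all-zero image.
    """
    if reducer not in _REDUCERS:
        raise ValueError(f"unknown reducer {reducer!r}; choose from {sorted(_REDUCERS)}")
    lo_mz, hi_mz = mz_center - mz_tol, mz_center + mz_tol
    values = np.zeros((dataset.n_rows, dataset.n_cols))
    valid = np.zeros((dataset.n_rows, dataset.n_cols), dtype=bool)
    any_points = False

    if dataset.mode == "continuous" and dataset.shared_mz is not None:
        mz = dataset.shared_mz
        lo = int(np.searchsorted(mz, lo_mz, side="left"))
        hi = int(np.searchsorted(mz, hi_mz, side="right"))
        mat, order = dataset.intensity_matrix()
        if hi > lo:
            any_points = True
            window = mat[:, lo:hi]
            if reducer == "sum":
                red = window.sum(axis=1)
            elif reducer == "max":
                red = window.max(axis=1)
            else:
                red = window.mean(axis=1)
        else:
            red = np.zeros(len(order))
        for (c, r), v in zip(order, red):
            values[r, c] = v
            valid[r, c] = True
    else:
        for (c, r), s in dataset.spectra.items():
            lo = int(np.searchsorted(s.mz, lo_mz, side="left"))
            hi = int(np.searchsorted(s.mz, hi_mz, side="right"))
            if hi > lo:
                any_points = True
                values[r, c] = _REDUCERS[reducer](s.intensity[lo:hi])
            valid[r, c] = True

    if not any_points:
        warnings.warn(
            f"m/z window [{lo_mz:.4g}, {hi_mz:.4g}] contains no data points in any "
            "spectrum; returning an all-zero image",
            stacklevel=2,
        )
    return IonImage(values, valid, mz_center=mz_center, mz_tol=mz_tol)


def mask_from_tic(dataset: MSIDataset, quantile_threshold: float) -> TissueMask:
    """Fallback tissue mask: a pixel is on-tissue iff its TIC strictly exceeds
    the given quantile of all measured-pixel TICs.

    A quantile of 0 keeps every measured pixel.  On a constant TIC field
    with quantile > 0 the strict comparison turns every pixel off; this
    degenerate outcome is reported with a warning.
    """
    if len(dataset) == 0:
        raise DegenerateInputError("dataset has no measured pixels")
    if not (0 <= quantile_threshold < 1):
        raise ValueError(
            f"quantile_threshold must be in [0, 1), got {quantile_threshold}"
        )
    tic = dataset.tic_image()
    grid = np.zeros((dataset.n_rows, dataset.n_cols), dtype=bool)
    tics = tic.values[tic.valid]
    if quantile_threshold == 0:
        grid[tic.valid] = True
        return TissueMask(grid)
    cut = float(np.quantile(tics, quantile_threshold))
    grid[tic.valid] = tic.values[tic.valid] > cut
    if not grid.any():
        warnings.warn(
            "TIC-quantile mask is empty (constant TIC field?); all pixels off-tissue",
            stacklevel=2,
        )
    return TissueMask(grid)
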