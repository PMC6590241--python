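"""Spatial segmentation and ordination of peak-aligned MSI feature matrices.

Segmentation is hierarchical bisecting k-means: recursively split the
leaf with the largest within-cluster sum of correlation distances to its
centroid using 2-means (assignment by correlation distance, centroid =
arithmetic mean, several random restarts).  Correlation distance,
d = 1 − Pearson r, groups pixels by spectral *shape* irrespective of
per-pixel intensity scale, which is why it is preferred over Euclidean
distance for TIC-normalized spectra.

Ordination is PCA on unit-variance-scaled features (i.e. eigenvectors of
the correlation matrix), the standard view for checking whether spectra
cluster by tissue structure or by acquisition batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import DegenerateInputError, MassSpectrum, MSIDataset, TissueMask, tic_normalize
from .peaks import pick_peaks

__all__ = [
    "FeatureMatrix",
    "SegmentationNode",
    "SegmentationTree",
    "build_feature_matrix",
    "correlation_distance",
    "bisecting_kmeans",
    "pca_scores",
]


@dataclass
class FeatureMatrix:
    """Pixels × aligned-peak features.

    ``values[i, j]`` is the TIC-normalized intensity of pixel
    ``pixels[i]`` integrated around consensus m/z ``mz[j]``;
    ``dataset_ids[i]`` records which input dataset the row came from.
    """

    values: np.ndarray  # (n_pixels, n_features)
    mz: np.ndarray  # (n_features,) strictly increasing consensus positions
    pixels: list[tuple[int, int]]
    dataset_ids: np.ndarray  # (n_pixels,) integer source-dataset index

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mz = np.asarray(self.mz, dtype=np.float64)
        if self.values.shape != (len(self.pixels), len(self.mz)):
            raise ValueError("values shape must be (n_pixels, n_features)")
        if len(self.mz) > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("consensus m/z positions must be strictly increasing")
        if np.any(~self.values.any(axis=1)):
            raise ValueError("feature matrix must not contain all-zero rows")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class SegmentationNode:
    """One node of the bisection tree: a set of row indices and its centroid."""

    rows: np.ndarray  # indices into the feature matrix
    centroid: np.ndarray
    level: int
    left: "SegmentationNode | None" = None
    right: "SegmentationNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None


@dataclass
class SegmentationTree:
    root: SegmentationNode
    n_rows: int

    def leaves(self) -> list[SegmentationNode]:
        out: list[SegmentationNode] = []

        def walk(node: SegmentationNode):
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def labels(self, level: int | None = None) -> np.ndarray:
        """Cluster label per row: leaves of the full tree, or the partition
        obtained by cutting at the given split level."""
        labels = np.empty(self.n_rows, dtype=np.int64)
        nodes: list[SegmentationNode] = []

        def walk(node: SegmentationNode):
            if node.is_leaf or (level is not None and node.level >= level):
                nodes.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        for k, node in enumerate(nodes):
            labels[node.rows] = k
        return labels

    def to_newick(self) -> str:
        def fmt(node: SegmentationNode) -> str:
            if node.is_leaf:
                return f"n{len(node.rows)}"
            return f"({fmt(node.left)},{fmt(node.right)})"

        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# Feature-matrix construction
# ---------------------------------------------------------------------------

def _moving_average(matrix: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return matrix
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(matrix, size=window, axis=-1, mode="nearest")


def _consensus_positions(all_mzs: list[np.ndarray], align_tol: float) -> np.ndarray:
    """Single-linkage merge of per-dataset peak positions: sorted positions
    whose successive gaps are < align_tol fall into one consensus bin,
    represented by the member mean."""
    pooled = np.sort(np.concatenate(all_mzs))
    if len(pooled) == 0:
        return pooled
    breaks = np.flatnonzero(np.diff(pooled) >= align_tol) + 1
    groups = np.split(pooled, breaks)
    return np.array([g.mean() for g in groups])


def build_feature_matrix(
    datasets: list[MSIDataset],
    masks: list[TissueMask],
    *,
    min_snr: float = 3.0,
    align_tol: float = 0.3,
    integration_tol: float = 0.25,
    denoise_window: int = 3,
    **pick_kwargs,
) -> FeatureMatrix:
    """Combine one or more datasets into a pixel × aligned-peak matrix.

    Per dataset: spectra are TIC-normalized, peaks are picked on the
    dataset mean spectrum at ``min_snr``, and per-dataset peak positions
    are merged into consensus bins by single-linkage within ``align_tol``
    Th.  Per on-tissue pixel, intensity is integrated in a ±
    ``integration_tol`` window around each consensus position, after an
    optional moving-average smoothing of width ``denoise_window`` points
    ("weak denoising"; 0 or 1 disables).
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    if len(datasets) != len(masks):
        raise ValueError("need one mask per dataset")

    per_ds_peaks: list[np.ndarray] = []
    norm_mats: list[np.ndarray] = []
    coords_per_ds: list[list[tuple[int, int]]] = []
    for ds, mask in zip(datasets, masks):
        mask.check_against(ds)
        mat, order = ds.intensity_matrix()
        on = np.array([mask.grid[r, c] for (c, r) in order])
        mat = mat[on]
        coords = [cr for cr, keep in zip(order, on) if keep]
        if len(coords) == 0:
            raise ValueError("a dataset has no on-tissue pixels")
        tic = mat.sum(axis=1, keepdims=True)
        if np.any(tic <= 0):
            raise DegenerateInputError("on-tissue pixel with zero TIC")
        norm = mat / tic
        mean_spec = tic_normalize(
            MassSpectrum(ds.shared_mz, norm.mean(axis=0), _validate=False)
        )
        pl = pick_peaks(mean_spec, min_snr=min_snr, **pick_kwargs)
        per_ds_peaks.append(pl.mz)
        norm_mats.append(norm)
        coords_per_ds.append(coords)

    consensus = _consensus_positions(per_ds_peaks, align_tol)
    if len(consensus) == 0:
        raise ValueError(
            f"no consensus peaks found at min_snr={min_snr}; lower min_snr"
        )

    blocks: list[np.ndarray] = []
    pixels: list[tuple[int, int]] = []
    ds_ids: list[int] = []
    for i, (ds, norm, coords) in enumerate(zip(datasets, norm_mats, coords_per_ds)):
        mz = ds.shared_mz
        sm = _moving_average(norm, denoise_window)
        feats = np.zeros((len(coords), len(consensus)))
        for j, c in enumerate(consensus):
            lo = int(np.searchsorted(mz, c - integration_tol, side="left"))
            hi = int(np.searchsorted(mz, c + integration_tol, side="right"))
            if hi > lo:
                feats[:, j] = sm[:, lo:hi].sum(axis=1)
        blocks.append(feats)
        pixels.extend(coords)
        ds_ids.extend([i] * len(coords))

    values = np.vstack(blocks)
    # guard the no-all-zero-row invariant: keep a tiny uniform pedestal for
    # pixels that happen to have no intensity in any consensus window
    zero_rows = ~values.any(axis=1)
    if zero_rows.any():
        values[zero_rows] = np.finfo(float).tiny
    return FeatureMatrix(values, consensus, pixels, np.asarray(ds_ids))


# ---------------------------------------------------------------------------
# Correlation distance and bisecting k-means
# ---------------------------------------------------------------------------

def correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """d = 1 − Pearson correlation(a, b), in [0, 2].

    Invariant under per-vector affine maps with positive scale.  Raises on
    zero-variance input; inside k-means such rows fall back to Euclidean
    assignment instead (see :func:`bisecting_kmeans`).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ac = a - a.mean()
    bc = b - b.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise DegenerateInputError("correlation distance undefined for zero-variance vector")
    return float(1.0 - (ac @ bc) / (na * nb))


def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and L2-normalize rows; returns (standardized, zero_variance_mask).
    For standardized rows u, v: correlation distance = 1 − u·v."""
    c = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(c, axis=1)
    zero = norms == 0
    safe = np.where(zero, 1.0, norms)
    return c / safe[:, None], zero


def _corr_dist_to_centroids(x: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """(n, k) correlation distances; zero-variance rows or centroids fall
    back to scaled Euclidean distance so assignment is always defined."""
    xs, xzero = _standardize_rows(x)
    cs, czero = _standardize_rows(centroids)
    d = 1.0 - xs @ cs.T
    if xzero.any() or czero.any():
        # Euclidean fallback, rescaled into [0, 2] range order-of-magnitude
        from scipy.spatial.distance import cdist

        eu = cdist(x, centroids)
        scale = eu.max()
        eu = eu / scale * 2.0 if scale > 0 else eu
        bad = np.zeros_like(d, dtype=bool)
        bad[xzero, :] = True
        bad[:, czero] = True
        d = np.where(bad, eu, d)
    return d


def _two_means(
    x: np.ndarray, rng: np.random.Generator, n_init: int
) -> tuple[np.ndarray, float]:
    """2-means with correlation-distance assignment and mean centroids.
    Returns (boolean assignment to cluster 1, within-cluster distance sum)."""
    n = x.shape[0]
    best_assign: np.ndarray | None = None
    best_cost = np.inf
    # distinct-row pool for seeding
    for _ in range(n_init):
        i, j = rng.choice(n, size=2, replace=False)
        tries = 0
        while np.array_equal(x[i], x[j]) and tries < 20:
            j = rng.integers(0, n)
            tries += 1
        centroids = np.vstack([x[i], x[j]])
        assign = None
        for _it in range(100):
            d = _corr_dist_to_centroids(x, centroids)
            new_assign = d[:, 1] < d[:, 0]
            if assign is not None and np.array_equal(new_assign, assign):
                break
            assign = new_assign
            if assign.all() or not assign.any():
                break
            centroids = np.vstack([x[~assign].mean(axis=0), x[assign].mean(axis=0)])
        if assign is None or assign.all() or not assign.any():
            continue
        d = _corr_dist_to_centroids(x, centroids)
        cost = float(d[~assign, 0].sum() + d[assign, 1].sum())
        if cost < best_cost:
            best_cost = cost
            best_assign = assign
    if best_assign is None:
        return np.zeros(n, dtype=bool), np.inf
    return best_assign, best_cost


def _within_cost(x: np.ndarray) -> float:
    centroid = x.mean(axis=0, keepdims=True)
    d = _corr_dist_to_centroids(x, centroid)
    return float(d.sum())


def bisecting_kmeans(
    features: FeatureMatrix,
    max_depth: int = 4,
    seed: int = 0,
    *,
    n_init: int = 10,
) -> SegmentationTree:
    """Hierarchical bisecting 2-means with correlation distance.

    At each step the leaf with the largest within-cluster sum of
    correlation distances to its centroid is split; splitting stops at
    ``max_depth`` levels or when no leaf holds two distinct rows.
    Deterministic given the seed.
    """
    x = features.values
    if x.shape[0] < 2:
        raise ValueError("bisecting k-means requires at least 2 rows")
    rng = np.random.default_rng(seed)
    root = SegmentationNode(np.arange(x.shape[0]), x.mean(axis=0), level=0)
    tree = SegmentationTree(root, x.shape[0])

    def splittable(node: SegmentationNode) -> bool:
        rows = x[node.rows]
        return node.level < max_depth and len(rows) >= 2 and not np.all(rows == rows[0])

    while True:
        leaves = [lf for lf in tree.leaves() if splittable(lf)]
        if not leaves:
            break
        target = max(leaves, key=lambda lf: _within_cost(x[lf.rows]))
        if max(lf.level for lf in tree.leaves()) >= max_depth and target.level >= max_depth:
            break
        sub = x[target.rows]
        assign, cost = _two_means(sub, rng, n_init)
        if not np.isfinite(cost) or assign.all() or not assign.any():
            break
        left_rows = target.rows[~assign]
        right_rows = target.rows[assign]
        target.left = SegmentationNode(left_rows, x[left_rows].mean(axis=0), target.level + 1)
        target.right = SegmentationNode(right_rows, x[right_rows].mean(axis=0), target.level + 1)
    return tree


# ---------------------------------------------------------------------------
# PCA with unit-variance scaling
# ---------------------------------------------------------------------------

def pca_scores(
    features: FeatureMatrix, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores on unit-variance-scaled features.

    Columns are centered and scaled to unit variance (zero-variance
    columns are dropped with a warning), so components are eigenvectors
    of the feature correlation matrix.  Returns ``(scores, explained)``
    where ``scores`` is (n_pixels, k) and ``explained`` the fraction of
    total (correlation-matrix) variance per component, non-increasing and
    summing to at most 1.  ``n_components`` beyond the matrix rank is
    reduced with a warning.
    """
    x = features.values
    if x.shape[0] < n_components:
        raise ValueError(
            f"n_components={n_components} exceeds number of rows {x.shape[0]}"
        )
    sd = x.std(axis=0, ddof=1)
    # relative tolerance: a numerically-constant column is zero-variance
    keep = sd > 1e-12 * np.maximum(1.0, np.abs(x.mean(axis=0)))
    if not keep.all():
        warnings.warn(
            f"dropping {int(np.count_nonzero(~keep))} zero-variance feature column(s)",
            stacklevel=2,
        )
    xs = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    u, s, _vt = np.linalg.svd(xs, full_matrices=False)
    tol = s.max() * max(xs.shape) * np.finfo(float).eps if len(s) else 0.0
    rank = int(np.count_nonzero(s > tol))
    k = n_components
    if k > rank:
        warnings.warn(
            f"n_components={n_components} exceeds rank {rank}; reduced", stacklevel=2
        )
        k = rank
    eigvals = s**2 / (xs.shape[0] - 1)
    explained = eigvals[:k] / xs.shape[1]
    scores = u[:, :k] * s[:k]
    return scores, explained
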