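"""Per-localization feature vectors for double-line classification.

Each localization is described by a fixed-length vector built from its k
nearest neighbors *within a random subset* of the data:

* the 350 sorted nearest-neighbor distances (nm), which encode local density
  and the transition from structure to background at large ranks; and
* a 30-bin histogram of neighbor directions (12 deg bins over the full
  circle), smoothed with a circular 3-bin boxcar, circularly shifted so
  the bin holding the global maximum sits at the bin centered on -pi/6
  (which removes the dependence on strand orientation), and normalized to
  unit mean per bin (sum == 30), which removes the dependence on k while
  keeping the classifier inputs near unit scale.

Subsets are drawn so that each double-line structure contributes roughly 300
localizations, keeping the tail of the distance vector in the noise regime
regardless of the labelling density of a particular protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "DEFAULT_K",
    "N_BINS",
    "Subset",
    "InsufficientLocalizationsError",
    "partition_subsets",
    "knn_distances",
    "knn_indices",
    "direction_histogram",
    "feature_vector",
    "compute_features",
]

DEFAULT_K = 350
N_BINS = 30
SMOOTH_WIDTH = 3
ALIGN_TARGET = -np.pi / 6.0


class InsufficientLocalizationsError(RuntimeError):
    """Raised when a region holds too few localizations to featurize; the
    caller is expected to expand the region and retry."""


@dataclass
class Subset:
    """A random subset of localization indices featurized together."""

    member_indices: np.ndarray
    parent_roi: int | None = None

    def __post_init__(self):
        self.member_indices = np.asarray(self.member_indices, dtype=np.int64)
        if len(np.unique(self.member_indices)) != self.member_indices.size:
            raise ValueError("subset indices must be unique")

    def __len__(self) -> int:
        return self.member_indices.size


def partition_subsets(
    indices,
    object_count_estimate: float,
    target_per_object: int = 300,
    min_subset: int = DEFAULT_K + 1,
    rng_seed=0,
    parent_roi: int | None = None,
) -> list[Subset]:
    """Randomly partition ``indices`` into near-equal subsets such that each
    double-line structure contributes ~``target_per_object`` localizations.

    ``object_count_estimate`` is the estimated number of localizations
    belonging to one structure (e.g. the count inside its detection box).
    The subset count is reduced until every part can feed a full k-NN query
    (``min_subset`` members); with fewer than ``min_subset`` localizations in
    total an :class:`InsufficientLocalizationsError` is raised.
    """
    indices = np.asarray(indices, dtype=np.int64)
    if indices.size == 0:
        raise ValueError("indices must be non-empty")
    if object_count_estimate < 1:
        raise ValueError("object_count_estimate must be >= 1")
    if indices.size < min_subset:
        raise InsufficientLocalizationsError(
            f"{indices.size} localizations < minimum subset size {min_subset}"
        )
    n_subsets = max(1, int(np.floor(object_count_estimate / target_per_object + 0.5)))
    while n_subsets > 1 and indices.size // n_subsets < min_subset:
        n_subsets -= 1
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(indices)
    return [
        Subset(part, parent_roi=parent_roi)
        for part in np.array_split(perm, n_subsets)
    ]


def _neighbor_order(coords, query_index):
    """Indices of all other points sorted by distance, ties by index."""
    coords = np.asarray(coords, dtype=float)
    delta = coords - coords[query_index]
    dist = np.hypot(delta[:, 0], delta[:, 1])
    order = np.lexsort((np.arange(len(coords)), dist))
    return order[order != query_index], dist


def knn_distances(coords, query_index: int, k: int = DEFAULT_K) -> np.ndarray:
    """Sorted Euclidean distances to the ``k`` nearest neighbors (self
    excluded); distance ties are broken by localization index."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < k + 1:
        raise ValueError(f"need at least {k + 1} points, got {len(coords)}")
    order, dist = _neighbor_order(coords, query_index)
    return dist[order[:k]]


def knn_indices(coords, query_index: int, k: int = DEFAULT_K) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if len(coords) < k + 1:
        raise ValueError(f"need at least {k + 1} points, got {len(coords)}")
    order, _ = _neighbor_order(coords, query_index)
    return order[:k]


def _histogram_from_angles(angles, n_bins, smooth_width, align_to, normalize):
    """Shared binning/smoothing/alignment for single and batch paths.

    ``angles`` has shape (m, k); returns (m, n_bins).
    """
    width = 2.0 * np.pi / n_bins
    bins = np.floor((angles + np.pi) / width).astype(np.int64) % n_bins
    m = bins.shape[0]
    flat = bins + np.arange(m)[:, None] * n_bins
    hist = np.bincount(flat.ravel(), minlength=m * n_bins).reshape(m, n_bins).astype(float)
    # circular boxcar smoothing
    smoothed = hist.copy()
    half = smooth_width // 2
    for s in range(1, half + 1):
        smoothed += np.roll(hist, s, axis=1) + np.roll(hist, -s, axis=1)
    smoothed /= smooth_width
    # shift the global-maximum bin onto the bin whose center is nearest align_to
    centers = -np.pi + (np.arange(n_bins) + 0.5) * width
    target = int(np.argmin(np.abs(centers - align_to)))
    maxbin = np.argmax(smoothed, axis=1)  # ties -> lowest bin index
    shift = (target - maxbin) % n_bins
    cols = (np.arange(n_bins)[None, :] - shift[:, None]) % n_bins
    aligned = smoothed[np.arange(m)[:, None], cols]
    if normalize:
        # unit-mean bins (sum == n_bins): removes the dependence on k while
        # keeping the values near 1, which conditions the classifier input
        totals = aligned.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        aligned = aligned / totals * n_bins
    return aligned


def direction_histogram(
    coords,
    query_index: int,
    k: int = DEFAULT_K,
    n_bins: int = N_BINS,
    smooth_width: int = SMOOTH_WIDTH,
    align_to: float = ALIGN_TARGET,
    normalize: bool = True,
) -> np.ndarray:
    """Smoothed, orientation-aligned histogram of neighbor directions.

    Directions are atan2 angles over the full circle [-pi, pi) binned at
    2*pi/``n_bins``; see the module docstring for the smoothing/alignment
    steps.
    """
    coords = np.asarray(coords, dtype=float)
    nbr = knn_indices(coords, query_index, k)
    delta = coords[nbr] - coords[query_index]
    angles = np.arctan2(delta[:, 1], delta[:, 0])[None, :]
    return _histogram_from_angles(angles, n_bins, smooth_width, align_to, normalize)[0]


def feature_vector(
    coords,
    query_index: int,
    k: int = DEFAULT_K,
    n_bins: int = N_BINS,
    smooth_width: int = SMOOTH_WIDTH,
    align_to: float = ALIGN_TARGET,
) -> np.ndarray:
    """The (k + n_bins)-element descriptor: sorted NN distances then the
    aligned direction histogram (380 elements at defaults)."""
    return np.concatenate(
        [
            knn_distances(coords, query_index, k),
            direction_histogram(coords, query_index, k, n_bins, smooth_width, align_to),
        ]
    )


def _batch_features(coords, k, n_bins, smooth_width, align_to, normalize):
    """Vectorized features for every point of one subset via a k-d tree."""
    coords = np.asarray(coords, dtype=float)
    m = len(coords)
    if m < k + 1:
        raise InsufficientLocalizationsError(
            f"subset of {m} points cannot supply {k} neighbors"
        )
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=k + 1, workers=1)
    rows = np.arange(m)
    # drop the self entry (distance 0, first column for distinct points)
    self_col = np.argmax(idx == rows[:, None], axis=1)
    keep = np.ones((m, k + 1), dtype=bool)
    keep[rows, self_col] = False
    dist = dist[keep].reshape(m, k)
    idx = idx[keep].reshape(m, k)
    delta = coords[idx] - coords[:, None, :]
    angles = np.arctan2(delta[:, :, 1], delta[:, :, 0])
    hist = _histogram_from_angles(angles, n_bins, smooth_width, align_to, normalize)
    return np.concatenate([dist, hist], axis=1)


def compute_features(
    coords,
    subsets: list[Subset] | None = None,
    k: int = DEFAULT_K,
    n_bins: int = N_BINS,
    smooth_width: int = SMOOTH_WIDTH,
    align_to: float = ALIGN_TARGET,
    normalize: bool = True,
    dtype=np.float32,
) -> np.ndarray:
    """Feature matrix, one row per localization, aligned with ``coords``.

    When ``subsets`` is given, each localization's neighbors are restricted
    to its own subset; rows of localizations not in any subset are NaN.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    out = np.full((n, k + n_bins), np.nan, dtype=dtype)
    if subsets is None:
        subsets = [Subset(np.arange(n))]
    for sub in subsets:
        members = sub.member_indices
        out[members] = _batch_features(
            coords[members], k, n_bins, smooth_width, align_to, normalize
        )
    return out
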