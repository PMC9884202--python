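"""Refinement of classifier-positive localizations into per-object clusters.

Applied in fixed order on measurement-mode data (never on the simulated
corpus used to score the classifier itself):

1. nearest-neighbor outlier rule — drop localizations whose mean distance
   to their first 10 neighbors exceeds 5x the median of that statistic;
2. DBSCAN (eps = 50 nm, minPts = 5) and keep the most populous cluster —
   one double-line object per ROI;
3. quality gates on the fit metadata — Gaussian sigma within [112, 160] nm
   and Thompson localization precision at most 20 nm.

Convex-hull perimeter/area of the surviving cluster are reported as
morphological summaries suitable for further filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

__all__ = [
    "ClassifiedObject",
    "NoClusterError",
    "nn_outlier_filter",
    "dbscan_largest",
    "convex_hull_stats",
    "thompson_precision",
    "quality_filter",
    "filter_report",
]

SIGMA_RANGE = (112.0, 160.0)  # nm, Gaussian-fit width gate
PRECISION_MAX = 20.0  # nm, Thompson precision gate
DBSCAN_EPS = 50.0  # nm
DBSCAN_MIN_PTS = 5


class NoClusterError(RuntimeError):
    """DBSCAN found no cluster; the candidate object is rejected."""


@dataclass
class ClassifiedObject:
    """One accepted double-line object after the full filter chain."""

    roi_id: int | None
    member_indices: np.ndarray
    hull_perimeter: float
    hull_area: float
    n_discarded_by_stage: dict = field(default_factory=dict)


def nn_outlier_filter(coords, m: int = 10, multiplier: float = 5.0, nn_means=None):
    """Discard localizations whose mean distance to their first ``m``
    neighbors exceeds ``multiplier`` times the median of that statistic.

    ``nn_means`` allows reuse of already-computed per-localization mean
    distances (e.g. the first ``m`` entries of the feature vectors).
    Returns ``(kept_idx, discarded_idx)``.  With fewer than ``m + 1``
    points the stage is skipped with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if nn_means is None:
        if n < m + 1:
            warnings.warn(
                f"nn_outlier_filter skipped: {n} points < m+1 = {m + 1}",
                stacklevel=2,
            )
            return np.arange(n), np.array([], dtype=int)
        tree = cKDTree(coords)
        dist, _ = tree.query(coords, k=m + 1, workers=1)
        nn_means = dist[:, 1:].mean(axis=1)
    else:
        nn_means = np.asarray(nn_means, dtype=float)
    median = np.median(nn_means)
    keep = nn_means <= multiplier * median
    return np.flatnonzero(keep), np.flatnonzero(~keep)


def dbscan_largest(coords, eps: float = DBSCAN_EPS, min_pts: int = DBSCAN_MIN_PTS):
    """Cluster with DBSCAN and keep the most populous cluster.

    Ties between equally large clusters go to the lowest cluster label
    (i.e. the cluster whose first core point appears earliest).  Raises
    :class:`NoClusterError` when every point is DBSCAN noise.
    Returns ``(kept_idx, discarded_idx)``.
    """
    coords = np.asarray(coords, dtype=float)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(coords)
    cluster_ids = np.unique(labels[labels >= 0])
    if cluster_ids.size == 0:
        raise NoClusterError(
            f"no DBSCAN cluster at eps={eps} nm, minPts={min_pts} "
            f"for {len(coords)} points"
        )
    sizes = np.array([(labels == c).sum() for c in cluster_ids])
    best = cluster_ids[np.argmax(sizes)]  # argmax -> lowest label on ties
    keep = labels == best
    return np.flatnonzero(keep), np.flatnonzero(~keep)


def convex_hull_stats(points):
    """Convex-hull (perimeter nm, area nm^2) of a point set.

    Collinear sets have zero area and perimeter 2x the largest pairwise
    distance (the degenerate hull traversed out and back).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("convex hull needs at least 2 points")
    try:
        hull = ConvexHull(points)
        return float(hull.area), float(hull.volume)  # 2-D: area==perimeter
    except QhullError:
        span = pdist(points).max()
        return 2.0 * float(span), 0.0


def thompson_precision(sigma, photons, pixel_size: float = 160.0, background: float = 0.0):
    """Thompson localization precision (nm) from the Gaussian-fit width,
    photon count, camera pixel size and per-pixel background:

        var = s^2/N + a^2/(12 N) + 8 pi s^4 b^2 / (a^2 N^2)
    """
    sigma = np.asarray(sigma, dtype=float)
    photons = np.asarray(photons, dtype=float)
    if np.any(sigma <= 0) or np.any(photons <= 0) or pixel_size <= 0:
        raise ValueError("sigma, photons and pixel_size must be positive")
    if background < 0:
        raise ValueError("background must be >= 0")
    var = (
        sigma**2 / photons
        + pixel_size**2 / (12.0 * photons)
        + 8.0 * np.pi * sigma**4 * background**2 / (pixel_size**2 * photons**2)
    )
    return np.sqrt(var)


def quality_filter(
    locs,
    sigma_range: tuple[float, float] = SIGMA_RANGE,
    precision_max: float = PRECISION_MAX,
    pixel_size: float = 160.0,
    background: float = 0.0,
):
    """Keep localizations with sigma inside ``sigma_range`` (closed
    interval) and precision at most ``precision_max`` nm.

    Missing precision is computed from sigma/photons via
    :func:`thompson_precision`; an uncomputable gate raises an error naming
    the missing columns.  Returns ``(kept_idx, discarded_idx)``.
    """
    if "sigma_nm" not in locs.columns:
        raise ValueError("quality_filter requires a 'sigma_nm' column")
    sigma = locs["sigma_nm"].to_numpy(dtype=float)
    if "precision_nm" in locs.columns and not locs["precision_nm"].isna().all():
        precision = locs["precision_nm"].to_numpy(dtype=float)
    elif "photons" in locs.columns:
        precision = thompson_precision(
            sigma, locs["photons"].to_numpy(dtype=float), pixel_size, background
        )
    else:
        raise ValueError(
            "quality_filter needs 'precision_nm' or 'photons' (to derive the "
            "Thompson precision); neither column is present"
        )
    keep = (
        (sigma >= sigma_range[0])
        & (sigma <= sigma_range[1])
        & (precision <= precision_max)
    )
    return np.flatnonzero(keep), np.flatnonzero(~keep)


def filter_report(stage_discards: dict, total: int, kept: int) -> dict:
    """Per-stage discard ratios in the two defensible conventions.

    ``ratio_of_total`` divides each stage's discards by the localization
    count entering classification; ``ratio_of_stage_input`` divides by the
    count entering that stage.  ``kept`` plus all discards must equal
    ``total`` (conservation).
    """
    discarded_sum = sum(stage_discards.values())
    if discarded_sum + kept != total:
        raise ValueError(
            f"count conservation violated: {discarded_sum} discarded + "
            f"{kept} kept != {total} total"
        )
    report = {"total": total, "kept": kept, "stages": {}}
    entering = total
    for stage, n in stage_discards.items():
        report["stages"][stage] = {
            "discarded": n,
            "ratio_of_total": n / total if total else 0.0,
            "ratio_of_stage_input": n / entering if entering else 0.0,
        }
        entering -= n
    report["kept_fraction"] = kept / total if total else 0.0
    return report
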