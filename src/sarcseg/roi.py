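"""Region-of-interest detection on rendered localization images.

Measurement files contain hundreds of thousands of localizations; feature
vectors are only computed inside candidate regions.  Candidates are found on
a pixelated rendering of the point cloud, which is where standard object
detectors operate.  The default detector is classical (blur -> Otsu ->
morphological closing -> connected components filtered by elongation and
size); any callable with the same signature — for example a trained deep
detector — can be plugged in via the ``backend`` argument.

Detected boxes are expanded by a fixed margin so they encompass the whole
object plus surrounding noise, then grown in fixed increments until they
hold enough localizations for a full k-NN feature query.  Boxes are
min-corner/max-corner tuples in nm, half-open on the upper edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import closing, footprint_rectangle

from .features import Subset, InsufficientLocalizationsError, partition_subsets

__all__ = [
    "ROI",
    "ROIRejectedError",
    "render_image",
    "detect_boxes",
    "select_contrast",
    "expand_roi",
    "merge_roi_labels",
]


class ROIRejectedError(RuntimeError):
    """A detection box never accumulated enough localizations."""


@dataclass
class ROI:
    """One accepted analysis region.

    ``detect_box`` is the raw detection; ``analysis_box`` the expanded
    region whose localizations are featurized; both (x_min, y_min, x_max,
    y_max) in nm.  ``est_object_locs`` is the localization count inside the
    detection box, used to size the random subsets.
    """

    detect_box: tuple[float, float, float, float]
    analysis_box: tuple[float, float, float, float]
    est_object_locs: int
    subsets: list[Subset] = field(default_factory=list)
    contrast_setting: float | None = None
    roi_id: int | None = None

    def __post_init__(self):
        d, a = self.detect_box, self.analysis_box
        if not (a[0] <= d[0] and a[1] <= d[1] and a[2] >= d[2] and a[3] >= d[3]):
            raise ValueError("analysis_box must contain detect_box")

    @property
    def member_indices(self) -> np.ndarray:
        if not self.subsets:
            return np.array([], dtype=np.int64)
        return np.concatenate([s.member_indices for s in self.subsets])


def _coords(locs) -> np.ndarray:
    if hasattr(locs, "columns"):
        return locs[["x_nm", "y_nm"]].to_numpy(dtype=float)
    return np.asarray(locs, dtype=float)


def render_image(locs, pixel_size_nm: float = 100.0, contrast_percentile: float = 99.5):
    """2-D count histogram of the localizations at ``pixel_size_nm``.

    Intensities are clipped at the given upper percentile of the occupied
    pixels and scaled to [0, 1].  Returns ``(image, pixel_size_nm)``; pixel
    (row i, col j) covers [j*p, (j+1)*p) x [i*p, (i+1)*p) nm, so the image
    is indexed [y, x] with the origin at the field's lower-left corner.
    """
    xy = _coords(locs)
    if xy.size == 0:
        raise ValueError("cannot render an empty localization set")
    if pixel_size_nm <= 0:
        raise ValueError("pixel size must be positive")
    p = float(pixel_size_nm)
    nx = max(int(np.floor(xy[:, 0].max() / p)) + 1, 1)
    ny = max(int(np.floor(xy[:, 1].max() / p)) + 1, 1)
    # localizations jittered marginally below the field origin land in the
    # edge pixel rather than being dropped
    ix = np.clip(np.floor(xy[:, 0] / p).astype(int), 0, nx - 1)
    iy = np.clip(np.floor(xy[:, 1] / p).astype(int), 0, ny - 1)
    img = np.bincount(iy * nx + ix, minlength=ny * nx).reshape(ny, nx).astype(float)
    occupied = img[img > 0]
    ceiling = np.percentile(occupied, contrast_percentile)
    if ceiling <= 0:
        ceiling = occupied.max()
    img = np.clip(img, 0.0, ceiling) / ceiling
    return img, p


def pixel_to_nm(i: int, j: int, pixel_size_nm: float) -> tuple[float, float]:
    """Lower-left corner of pixel (row ``i``, col ``j``) in nm."""
    return j * pixel_size_nm, i * pixel_size_nm


def nm_to_pixel(x: float, y: float, pixel_size_nm: float) -> tuple[int, int]:
    return int(np.floor(y / pixel_size_nm)), int(np.floor(x / pixel_size_nm))


def detect_boxes(
    image,
    backend="classical",
    pixel_size_nm: float = 100.0,
    expected_diameter_nm: float = 1500.0,
    min_aspect: float = 2.0,
    blur_sigma_px: float = 1.0,
) -> list[tuple[int, int, int, int]]:
    """Axis-aligned candidate boxes around double-line objects, pixel space.

    The classical backend keeps connected components whose major axis falls
    within [0.5, 2] x the expected line length and whose aspect ratio is at
    least ``min_aspect`` — double lines are strongly elongated while vesicle
    clusters are compact.  A custom callable ``backend(image) -> boxes``
    may replace it.  Boxes are (x_min, y_min, x_max, y_max), half-open.
    """
    image = np.asarray(image, dtype=float)
    if callable(backend):
        return backend(image)
    if backend != "classical":
        raise ValueError(f"unknown detection backend {backend!r}")
    if image.max() <= 0:
        return []
    smoothed = gaussian(image, sigma=blur_sigma_px)
    thr = threshold_otsu(smoothed)
    bw = closing(smoothed > thr, footprint_rectangle((3, 3)))
    labelled = cc_label(bw)
    lo = 0.5 * expected_diameter_nm / pixel_size_nm
    hi = 2.0 * expected_diameter_nm / pixel_size_nm
    boxes = []
    for region in regionprops(labelled):
        major = region.axis_major_length
        minor = region.axis_minor_length
        if not (lo <= major <= hi):
            continue
        if major / max(minor, 1.0) < min_aspect:
            continue
        r0, c0, r1, c1 = region.bbox
        boxes.append((c0, r0, c1, r1))
    return boxes


def boxes_to_nm(boxes_px, pixel_size_nm: float):
    p = pixel_size_nm
    return [(x0 * p, y0 * p, x1 * p, y1 * p) for x0, y0, x1, y1 in boxes_px]


def select_contrast(
    locs,
    percentile_grid=(99.0, 99.5, 99.9),
    pixel_size_nm: float = 100.0,
    **detect_kwargs,
):
    """Run render+detect at every contrast setting and keep the best one.

    Settings are ranked lexicographically by (number of boxes, total box
    area) descending; ties go to the lower percentile.  Returns
    ``(best_percentile, boxes_nm)``.
    """
    grid = sorted(percentile_grid)
    if not grid:
        raise ValueError("percentile grid must be non-empty")
    best = None
    for pct in grid:
        img, p = render_image(locs, pixel_size_nm, contrast_percentile=pct)
        boxes = detect_boxes(img, pixel_size_nm=p, **detect_kwargs)
        area = sum((x1 - x0) * (y1 - y0) for x0, y0, x1, y1 in boxes)
        key = (len(boxes), area)
        if best is None or key > best[0]:
            best = (key, pct, boxes)
    _, pct, boxes = best
    return pct, boxes_to_nm(boxes, pixel_size_nm)


def _inside(xy, box):
    x0, y0, x1, y1 = box
    return (
        (xy[:, 0] >= x0) & (xy[:, 0] < x1) & (xy[:, 1] >= y0) & (xy[:, 1] < y1)
    )


def _dilate(box, margin):
    x0, y0, x1, y1 = box
    return (x0 - margin, y0 - margin, x1 + margin, y1 + margin)


def expand_roi(
    detect_box,
    locs,
    margin_nm: float = 1000.0,
    increment_nm: float = 500.0,
    target_per_object: int = 300,
    min_subset: int = 351,
    max_increments: int = 10,
    rng_seed=0,
    roi_id: int | None = None,
    contrast_setting: float | None = None,
) -> ROI:
    """Expand a detection box into an analysis ROI with featurizable subsets.

    The box is dilated by ``margin_nm`` on all sides (so the whole object
    plus surrounding noise is included), then repeatedly by ``increment_nm``
    until the enclosed localizations can be partitioned into subsets of at
    least ``min_subset`` members; after ``max_increments`` growth steps the
    ROI is rejected.
    """
    xy = _coords(locs)
    est = int(np.count_nonzero(_inside(xy, detect_box)))
    box = _dilate(detect_box, margin_nm)
    last_err = None
    for attempt in range(max_increments + 1):
        members = np.flatnonzero(_inside(xy, box))
        try:
            subsets = partition_subsets(
                members,
                max(est, 1),
                target_per_object=target_per_object,
                min_subset=min_subset,
                rng_seed=rng_seed,
                parent_roi=roi_id,
            )
            return ROI(
                detect_box=tuple(detect_box),
                analysis_box=box,
                est_object_locs=est,
                subsets=subsets,
                contrast_setting=contrast_setting,
                roi_id=roi_id,
            )
        except (InsufficientLocalizationsError, ValueError) as err:
            last_err = err
            box = _dilate(box, increment_nm)
    raise ROIRejectedError(
        f"ROI at {detect_box} still insufficient after {max_increments} "
        f"increments of {increment_nm} nm: {last_err}"
    )


def merge_roi_labels(per_roi_predictions, n_total: int):
    """Combine per-ROI binary labels into one per-localization label.

    ``per_roi_predictions`` is an iterable of ``(indices, labels)`` pairs
    (global localization indices + booleans).  A localization covered by
    several overlapping ROIs counts as object if ANY ROI classified it as
    object; the downstream largest-cluster filter removes spurious
    positives.  Returns ``(labels, covered)`` boolean arrays of length
    ``n_total``; localizations outside every ROI have ``covered = False``.
    """
    labels = np.zeros(n_total, dtype=bool)
    covered = np.zeros(n_total, dtype=bool)
    for indices, pred in per_roi_predictions:
        indices = np.asarray(indices, dtype=np.int64)
        pred = np.asarray(pred, dtype=bool)
        labels[indices] |= pred
        covered[indices] = True
    return labels, covered
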