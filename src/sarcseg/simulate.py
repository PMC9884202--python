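"""Localization-level simulator for sarcomeric double-line dSTORM data.

Myofibrils carry many sarcomeric proteins in disc pairs repeating along the
fiber axis.  Imaged edge-on in 2D, each disc pair projects to a *double line*:
two short parallel lines of length ``D`` (the disc diameter, ~1.5 µm)
separated by ``d`` (~120 nm) along the strand, with consecutive pairs spaced
``L`` (~3.4 µm) apart.  The simulator emits labelled localization tables
(object + noise) directly at the localization level: epitopes are placed on
the projected disc segments, each epitope spawns fluorescent labels displaced
by the antibody linker, each label blinks one or more times, and every blink
is jittered by its drawn localization precision.  Fit metadata (Gaussian
sigma, photon count, precision) is drawn so that the Thompson precision
computed from sigma/photons matches the drawn precision, which keeps the
downstream quality filters meaningful.

Tables are pandas DataFrames with columns
``frame, x_nm, y_nm, sigma_nm, photons, precision_nm, label, object_id``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "DoubleLineSpec",
    "NoiseSpec",
    "LOCALIZATION_COLUMNS",
    "simulate_double_lines",
    "simulate_noise",
    "simulate_field",
    "merge_with_exclusion",
    "split_train_val_test",
]

LOCALIZATION_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "sigma_nm",
    "photons",
    "precision_nm",
    "label",
    "object_id",
]

#: camera pixel size used to invert the Thompson formula, nm
CAMERA_PIXEL_NM = 160.0
#: background photons per pixel implied by the camera model (EMCCD counts
#: converted to photons); feeds the Thompson inversion
DEFAULT_BACKGROUND = 19.0


@dataclass
class DoubleLineSpec:
    """Geometry and labelling parameters of one simulated double-line strand.

    Defaults follow the dimensions of Drosophila IFM sarcomeres measured by
    dSTORM: ``L`` = 3.4 µm pair spacing, ``D`` = 1.5 µm disc diameter,
    ``d`` ~ 120 nm line separation, epitope density 30-50 per µm² of disc
    face, 27 disc pairs per strand.
    """

    L: float = 3400.0  # nm, spacing of disc pairs along the strand
    D: float = 1500.0  # nm, disc diameter == projected line length
    d: float = 120.0  # nm, separation of the two lines within a pair
    epitope_density: float = 40.0  # epitopes per um^2 of disc face
    # when set, per-pair density is drawn uniformly from this range,
    # emulating labelling-density variation across structures/simulations
    epitope_density_range: tuple[float, float] | None = None
    n_pairs: int = 27
    strand_angle: float = 0.0  # radians, strand axis direction
    labels_per_epitope_mean: float = 5.0
    labels_per_epitope_var: float = 2.0
    linker_length: float = 25.0  # nm, antibody linker displacement
    blinks_per_label_mean: float = 1.5
    loc_precision_mean: float = 12.0  # nm
    loc_precision_sd: float = 4.0  # nm
    sigma_range: tuple[float, float] = (105.0, 170.0)  # nm, brackets [112,160]
    chord_weighted: bool = True  # disc-projection density along the line
    jitter_scale: float = 1.0  # 0 disables positional jitter (geometry tests)
    origin: tuple[float, float] | None = None  # nm, first pair center
    n_frames: int = 15000

    def validate(self) -> None:
        if not (self.L > self.d > 0):
            raise ValueError(f"need L > d > 0, got L={self.L}, d={self.d}")
        if self.D <= 0:
            raise ValueError("disc diameter D must be positive")
        if self.epitope_density < 0:
            raise ValueError("epitope_density must be >= 0")
        if self.epitope_density_range is not None:
            lo, hi = self.epitope_density_range
            if not (0 <= lo <= hi):
                raise ValueError("epitope_density_range must satisfy 0 <= lo <= hi")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.labels_per_epitope_mean < 0 or self.labels_per_epitope_var < 0:
            raise ValueError("label count moments must be >= 0")
        if self.linker_length < 0:
            raise ValueError("linker_length must be >= 0")
        if self.blinks_per_label_mean < 0:
            raise ValueError("blinks_per_label_mean must be >= 0")
        if self.loc_precision_mean <= 0 or self.loc_precision_sd < 0:
            raise ValueError("localization precision parameters invalid")
        lo, hi = self.sigma_range
        if not (0 < lo <= hi):
            raise ValueError("sigma_range must satisfy 0 < lo <= hi")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be >= 0")


@dataclass
class NoiseSpec:
    """Background model: clustered vesicle labelling plus uniform
    non-specific labels over a rectangular field (nm)."""

    vesicle_density: float = 3.0  # clusters per um^2
    vesicle_locs_mean: float = 8.6  # localizations per cluster (labels x blinks)
    vesicle_sd: float = 25.0  # nm, cluster spread
    uniform_density: float = 35.0  # localizations per um^2
    field_width: float = 95600.0  # nm
    field_height: float = 8000.0  # nm
    n_frames: int = 15000

    def validate(self) -> None:
        if min(self.vesicle_density, self.vesicle_locs_mean, self.uniform_density) < 0:
            raise ValueError("densities must be >= 0")
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("field dimensions must be positive")
        if self.vesicle_sd < 0:
            raise ValueError("vesicle_sd must be >= 0")

    @property
    def area_um2(self) -> float:
        return self.field_width * self.field_height / 1e6


def _truncated_positive_normal(rng, mean, sd, size, floor=0.5):
    """Normal draw truncated below at ``floor`` by redrawing."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = out < floor
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out < floor
    return out


def _photons_from_precision(precision, sigma, pixel=CAMERA_PIXEL_NM, background=DEFAULT_BACKGROUND):
    """Invert the Thompson precision formula for the photon count.

    var = s^2/N + a^2/(12N) + 8 pi s^4 b^2 / (a^2 N^2)  is quadratic in 1/N.
    """
    p2 = np.asarray(precision, dtype=float) ** 2
    A = sigma**2 + pixel**2 / 12.0
    c = 8.0 * np.pi * sigma**4 * background**2 / pixel**2
    N = (A + np.sqrt(A**2 + 4.0 * c * p2)) / (2.0 * p2)
    return np.maximum(1, np.rint(N)).astype(np.int64)


def _metadata(rng, n, precision_mean, precision_sd, sigma_range, n_frames):
    """Draw per-localization fit metadata consistent with the precision."""
    precision = _truncated_positive_normal(rng, precision_mean, precision_sd, n)
    sigma = rng.uniform(sigma_range[0], sigma_range[1], n)
    photons = _photons_from_precision(precision, sigma)
    frame = rng.integers(1, n_frames + 1, n)
    return frame, sigma, photons, precision


def _table(x, y, frame, sigma, photons, precision, label, object_id):
    return pd.DataFrame(
        {
            "frame": np.asarray(frame, dtype=np.int64),
            "x_nm": np.asarray(x, dtype=float),
            "y_nm": np.asarray(y, dtype=float),
            "sigma_nm": np.asarray(sigma, dtype=float),
            "photons": np.asarray(photons, dtype=np.int64),
            "precision_nm": np.asarray(precision, dtype=float),
            "label": pd.array(label, dtype="string"),
            "object_id": pd.array(object_id, dtype="Int64"),
        }
    )


def empty_table() -> pd.DataFrame:
    return _table([], [], [], [], [], [], [], [])


def simulate_double_lines(spec: DoubleLineSpec, rng_seed: int) -> pd.DataFrame:
    """Simulate object localizations for one strand of double-line pairs.

    Each pair consists of two parallel line segments of length ``D``
    (perpendicular to the strand axis) separated by ``d`` along the axis.
    Epitope positions along a line follow the chord-weighted profile of a
    uniformly labelled disc projected onto a diameter (denser mid-line)
    unless ``spec.chord_weighted`` is off.  Epitope -> labels -> blinks ->
    jittered localizations, as in a dSTORM measurement.
    """
    spec.validate()
    rng = np.random.default_rng(rng_seed)

    ux, uy = math.cos(spec.strand_angle), math.sin(spec.strand_angle)
    vx, vy = -uy, ux  # line direction, perpendicular to the strand

    if spec.origin is None:
        origin = (2000.0 + spec.D / 2.0 * abs(vx), spec.D / 2.0 + 2000.0)
    else:
        origin = spec.origin

    disc_area_um2 = math.pi * (spec.D / 2000.0) ** 2  # both faces project together

    xs, ys, oid = [], [], []
    for i in range(spec.n_pairs):
        if spec.epitope_density_range is not None:
            lo, hi = spec.epitope_density_range
            density = rng.uniform(lo, hi)
        else:
            density = spec.epitope_density
        mean_epitopes = 2.0 * density * disc_area_um2  # two disc faces
        cx = origin[0] + i * spec.L * ux
        cy = origin[1] + i * spec.L * uy
        for side in (-0.5, 0.5):
            n_epi = rng.poisson(mean_epitopes)
            if n_epi == 0:
                continue
            if spec.chord_weighted:
                t = (rng.beta(1.5, 1.5, n_epi) - 0.5) * spec.D
            else:
                t = rng.uniform(-spec.D / 2.0, spec.D / 2.0, n_epi)
            ex = cx + side * spec.d * ux + t * vx
            ey = cy + side * spec.d * uy + t * vy
            # labels per epitope: rounded normal with stated mean/variance
            if spec.labels_per_epitope_var > 0:
                n_lab = np.rint(
                    rng.normal(
                        spec.labels_per_epitope_mean,
                        math.sqrt(spec.labels_per_epitope_var),
                        n_epi,
                    )
                ).astype(int)
            else:
                n_lab = np.full(n_epi, int(round(spec.labels_per_epitope_mean)))
            n_lab = np.clip(n_lab, 0, None)
            lx = np.repeat(ex, n_lab)
            ly = np.repeat(ey, n_lab)
            n_labels = lx.size
            if n_labels == 0:
                continue
            phi = rng.uniform(0.0, 2.0 * math.pi, n_labels)
            lx = lx + spec.linker_length * np.cos(phi)
            ly = ly + spec.linker_length * np.sin(phi)
            n_blink = np.maximum(1, rng.poisson(spec.blinks_per_label_mean, n_labels))
            bx = np.repeat(lx, n_blink)
            by = np.repeat(ly, n_blink)
            xs.append(bx)
            ys.append(by)
            oid.append(np.full(bx.size, i, dtype=np.int64))

    if not xs:
        return empty_table()

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    object_id = np.concatenate(oid)
    n = x.size
    frame, sigma, photons, precision = _metadata(
        rng, n, spec.loc_precision_mean, spec.loc_precision_sd, spec.sigma_range, spec.n_frames
    )
    jitter = spec.jitter_scale * rng.normal(0.0, 1.0, (n, 2)) * precision[:, None]
    x = x + jitter[:, 0]
    y = y + jitter[:, 1]
    return _table(x, y, frame, sigma, photons, precision, ["object"] * n, object_id)


def simulate_noise(spec: NoiseSpec, rng_seed: int) -> pd.DataFrame:
    """Simulate background localizations: vesicle clusters + uniform labels."""
    spec.validate()
    rng = np.random.default_rng(rng_seed)
    area = spec.area_um2

    xs, ys = [], []
    n_ves = rng.poisson(spec.vesicle_density * area)
    if n_ves > 0:
        centers = rng.uniform(
            [0.0, 0.0], [spec.field_width, spec.field_height], (n_ves, 2)
        )
        counts = rng.poisson(spec.vesicle_locs_mean, n_ves)
        reps = np.repeat(centers, counts, axis=0)
        if reps.size:
            pts = reps + rng.normal(0.0, spec.vesicle_sd, reps.shape)
            xs.append(pts[:, 0])
            ys.append(pts[:, 1])
    n_uni = rng.poisson(spec.uniform_density * area)
    if n_uni > 0:
        xs.append(rng.uniform(0.0, spec.field_width, n_uni))
        ys.append(rng.uniform(0.0, spec.field_height, n_uni))

    if not xs:
        return empty_table()
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n = x.size
    frame, sigma, photons, precision = _metadata(rng, n, 12.0, 4.0, (105.0, 170.0), spec.n_frames)
    return _table(
        x, y, frame, sigma, photons, precision, ["noise"] * n, [pd.NA] * n
    )


def merge_with_exclusion(
    objects: pd.DataFrame, noise: pd.DataFrame, radius: float = 50.0
) -> pd.DataFrame:
    """Concatenate object and noise tables, dropping noise localizations
    closer than ``radius`` to the nearest object localization.

    Near-structure noise is indistinguishable from specific labelling and
    would corrupt the training labels, hence the exclusion zone (50 nm by
    default).  Object rows and relative order are preserved.
    """
    if radius < 0:
        raise ValueError("exclusion radius must be >= 0")
    if len(objects) == 0 or len(noise) == 0 or radius == 0:
        return pd.concat([objects, noise], ignore_index=True)
    tree = cKDTree(objects[["x_nm", "y_nm"]].to_numpy())
    dist, _ = tree.query(noise[["x_nm", "y_nm"]].to_numpy(), k=1, workers=-1)
    kept = noise[dist >= radius]
    return pd.concat([objects, kept], ignore_index=True)


def split_train_val_test(
    labels,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    rng_seed: int = 0,
):
    """Stratified, disjoint, exhaustive train/val/test index split.

    ``labels`` is any sequence of hashable class labels; returns three
    integer position arrays.  Per-stratum sizes use largest-remainder
    rounding so the class balance of each split tracks the global balance.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("need three non-negative fractions")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(rng_seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for value in pd.unique(labels):
        idx = np.flatnonzero(labels == value)
        idx = rng.permutation(idx)
        n = idx.size
        raw = np.array(fractions) * n
        counts = np.floor(raw).astype(int)
        rem = n - counts.sum()
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:rem]] += 1
        stops = np.cumsum(counts)
        parts[0].append(idx[: stops[0]])
        parts[1].append(idx[stops[0] : stops[1]])
        parts[2].append(idx[stops[1] : stops[2]])
    out = tuple(
        np.sort(np.concatenate(p)) if p else np.array([], dtype=int) for p in parts
    )
    return out


def simulate_field(
    line_spec: DoubleLineSpec | None = None,
    noise_spec: NoiseSpec | None = None,
    rng_seed: int = 0,
    exclusion_radius: float = 50.0,
) -> pd.DataFrame:
    """One labelled training/measurement field: strand + noise, merged with
    the exclusion rule.  Child seeds are spawned deterministically."""
    line_spec = line_spec if line_spec is not None else DoubleLineSpec()
    noise_spec = noise_spec if noise_spec is not None else NoiseSpec()
    ss = np.random.SeedSequence(rng_seed)
    s_obj, s_noise = ss.spawn(2)
    objects = simulate_double_lines(line_spec, s_obj)
    noise = simulate_noise(noise_spec, s_noise)
    return merge_with_exclusion(objects, noise, exclusion_radius)
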