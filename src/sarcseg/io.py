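"""Localization-table I/O and pipeline configuration.

Reads rainSTORM/ThunderSTORM-style CSV tables with tolerant column-name
mapping and writes the package's canonical table
(``frame,x_nm,y_nm,sigma_nm,photons,precision_nm,label,object_id``).
Configuration is one YAML file with per-stage blocks plus a global seed;
all stage randomness is derived from that seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierSpec
from .postfilter import thompson_precision
from .simulate import DoubleLineSpec, NoiseSpec, LOCALIZATION_COLUMNS

__all__ = [
    "read_localizations",
    "write_localizations",
    "PipelineConfig",
    "FeatureConfig",
    "ROIConfig",
    "FilterConfig",
    "load_config",
    "save_config",
    "config_hash",
]

# recognised aliases, lower-cased with spaces/brackets stripped
_ALIASES = {
    "x_nm": ["x_nm", "x[nm]", "x", "xnm", "xposition", "position_x", "x(nm)"],
    "y_nm": ["y_nm", "y[nm]", "y", "ynm", "yposition", "position_y", "y(nm)"],
    "frame": ["frame", "frame_number", "t"],
    "sigma_nm": ["sigma_nm", "sigma[nm]", "sigma", "sd", "sd[nm]", "width"],
    "photons": ["photons", "intensity", "intensity[photon]", "n_photons", "counts"],
    "precision_nm": [
        "precision_nm",
        "precision",
        "precision[nm]",
        "uncertainty",
        "uncertainty[nm]",
        "uncertainty_xy[nm]",
    ],
    "label": ["label"],
    "object_id": ["object_id", "objectid", "id"],
    "roi_id": ["roi_id"],
    "stage_discarded": ["stage_discarded"],
}


def _canon(name: str) -> str:
    return name.strip().lower().replace(" ", "").replace("/", "")


def read_localizations(path, pixel_size: float = 160.0, background: float = 0.0) -> pd.DataFrame:
    """Read a localization CSV, mapping common column dialects.

    x/y are required; a missing precision column is derived from
    sigma/photons via the Thompson formula and flagged in
    ``df.attrs['precision_derived']``.
    """
    raw = pd.read_csv(path)
    lookup = {_canon(c): c for c in raw.columns}
    out = pd.DataFrame()
    for target, aliases in _ALIASES.items():
        for alias in aliases:
            if alias in lookup:
                out[target] = raw[lookup[alias]]
                break
    for required in ("x_nm", "y_nm"):
        if required not in out.columns:
            raise ValueError(
                f"missing required column {required!r}; recognised aliases: "
                f"{_ALIASES[required]}; file has {list(raw.columns)}"
            )
    if len(out) == 0:
        warnings.warn(f"{path}: no localization rows", stacklevel=2)
    out.attrs["precision_derived"] = False
    if "precision_nm" not in out.columns or out["precision_nm"].isna().all():
        if {"sigma_nm", "photons"} <= set(out.columns) and len(out):
            out["precision_nm"] = thompson_precision(
                out["sigma_nm"].to_numpy(float),
                out["photons"].to_numpy(float),
                pixel_size,
                background,
            )
            out.attrs["precision_derived"] = True
    if "object_id" in out.columns:
        out["object_id"] = pd.array(out["object_id"], dtype="Int64")
    return out


def write_localizations(df: pd.DataFrame, path, measurement_mode: bool = False) -> None:
    """Write the canonical table; ``measurement_mode`` omits the
    ground-truth columns, mimicking a real measurement export."""
    cols = [c for c in LOCALIZATION_COLUMNS if c in df.columns]
    if measurement_mode:
        cols = [c for c in cols if c not in ("label", "object_id")]
    df[cols].to_csv(path, index=False)


@dataclass
class FeatureConfig:
    k: int = 350
    n_bins: int = 30
    smooth_width: int = 3
    align_to: float = -np.pi / 6.0
    target_per_object: int = 300
    hist_normalize: bool = True
    standardize_distances: bool = False  # optional z-scoring, off by default

    @property
    def min_subset(self) -> int:
        return self.k + 1

    @property
    def width(self) -> int:
        return self.k + self.n_bins


@dataclass
class ROIConfig:
    pixel_size_nm: float = 100.0
    contrast_grid: tuple = (99.0, 99.5, 99.9)
    expected_diameter_nm: float = 1500.0
    min_aspect: float = 2.0
    margin_nm: float = 1000.0
    increment_nm: float = 500.0
    max_increments: int = 10


@dataclass
class FilterConfig:
    nn_m: int = 10
    nn_multiplier: float = 5.0
    dbscan_eps: float = 50.0
    dbscan_min_pts: int = 5
    sigma_range: tuple = (112.0, 160.0)
    precision_max: float = 20.0
    camera_pixel_nm: float = 160.0
    background: float = 0.0


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: DoubleLineSpec = field(default_factory=DoubleLineSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    exclusion_radius: float = 50.0
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    roi: ROIConfig = field(default_factory=ROIConfig)
    postfilter: FilterConfig = field(default_factory=FilterConfig)

    def substream(self, name: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        digest = hashlib.sha256(f"{self.seed}:{name}".encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)


_BLOCKS = {
    "simulate": DoubleLineSpec,
    "noise": NoiseSpec,
    "features": FeatureConfig,
    "classifier": ClassifierSpec,
    "roi": ROIConfig,
    "postfilter": FilterConfig,
}


def _coerce(cls, value):
    """Rebuild a dataclass from a YAML mapping, restoring tuple fields."""
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in value:
            v = value[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, value in data.items():
        if key in _BLOCKS:
            kwargs[key] = _coerce(_BLOCKS[key], value)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
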