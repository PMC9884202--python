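"""End-to-end segmentation driver.

Measurement mode: render -> detect ROIs at several contrasts -> expand each
ROI -> featurize its subsets -> classify -> OR-merge overlapping-ROI labels
-> per-ROI filter chain (NN outlier, DBSCAN largest cluster, sigma/precision
gates) -> convex-hull summary -> line-separation estimate.  Per-stage
discard counts are tracked for the filter report, and a manifest records
the configuration hash and seed so runs can be reproduced.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import analyze as ana
from . import classify as cls
from . import features as feat
from . import postfilter as pf
from . import roi as roi_mod
from .io import PipelineConfig, config_hash

__all__ = ["SegmentationResult", "train_from_simulation", "segment_measurement"]


@dataclass
class SegmentationResult:
    rois: list
    labels: np.ndarray  # OR-merged object labels, length n
    covered: np.ndarray  # inside at least one analysis box
    objects: list  # ClassifiedObject per accepted ROI
    separations: pd.DataFrame  # roi_id, d_hat_nm, axis_angle_rad, n_locs
    report: dict
    manifest: dict

    def save(self, out_dir) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        roi_json = [
            {
                "roi_id": r.roi_id,
                "detect_box": list(r.detect_box),
                "analysis_box": list(r.analysis_box),
                "est_object_locs": r.est_object_locs,
                "subset_sizes": [len(s) for s in r.subsets],
                "contrast_setting": r.contrast_setting,
            }
            for r in self.rois
        ]
        (out_dir / "rois.json").write_text(json.dumps(roi_json, indent=2))
        self.separations.to_csv(out_dir / "separations.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(self.report, indent=2))
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def train_from_simulation(config: PipelineConfig, n_fields: int = 1) -> cls.TrainedClassifier:
    """Train the classifier on a freshly simulated labelled corpus at the
    configured conditions."""
    from .datasets import training_corpus

    X, y, (tr, va, te) = training_corpus(
        rng_seed=config.substream("train-corpus"),
        n_fields=n_fields,
        k=config.features.k,
        target_per_object=config.features.target_per_object,
    )
    spec = config.classifier
    spec.rng_seed = config.substream("train")
    return cls.train(X[tr], y[tr], spec, X[va], y[va])


def segment_measurement(
    locs: pd.DataFrame,
    model: cls.TrainedClassifier,
    config: PipelineConfig | None = None,
) -> SegmentationResult:
    """Run the full ROI -> classify -> filter -> analyze chain on a
    localization table (measurement mode: ground-truth columns ignored)."""
    config = config or PipelineConfig()
    coords = locs[["x_nm", "y_nm"]].to_numpy(float)
    n = len(locs)
    fc, rc, pc = config.features, config.roi, config.postfilter

    contrast, boxes = roi_mod.select_contrast(
        locs,
        percentile_grid=rc.contrast_grid,
        pixel_size_nm=rc.pixel_size_nm,
        expected_diameter_nm=rc.expected_diameter_nm,
        min_aspect=rc.min_aspect,
    )
    rois = []
    for i, box in enumerate(boxes):
        try:
            rois.append(
                roi_mod.expand_roi(
                    box,
                    coords,
                    margin_nm=rc.margin_nm,
                    increment_nm=rc.increment_nm,
                    target_per_object=fc.target_per_object,
                    min_subset=fc.min_subset,
                    max_increments=rc.max_increments,
                    rng_seed=config.substream(f"roi-{i}"),
                    roi_id=i,
                    contrast_setting=contrast,
                )
            )
        except roi_mod.ROIRejectedError as err:
            warnings.warn(str(err), stacklevel=2)

    per_roi = []
    for r in rois:
        X = feat.compute_features(
            coords,
            r.subsets,
            k=fc.k,
            n_bins=fc.n_bins,
            smooth_width=fc.smooth_width,
            align_to=fc.align_to,
        )
        members = r.member_indices
        _, pred = cls.predict(model, X[members])
        per_roi.append((members, pred))

    labels, covered = roi_mod.merge_roi_labels(per_roi, n)

    # Overlapping ROIs process shared localizations independently, so the
    # Table-1-style accounting is per ROI membership instance; conservation
    # (kept + all discards == total) then holds exactly.
    counters = {
        "classification": 0,
        "nn_outlier": 0,
        "dbscan": 0,
        "sigma_precision": 0,
        "object_rejected": 0,
    }
    total_instances = 0
    kept_final = 0
    objects, sep_rows = [], []
    for r in rois:
        members = r.member_indices
        total_instances += int(members.size)
        pos = members[labels[members]]
        counters["classification"] += int(members.size - pos.size)
        stage_counts = {"input": int(pos.size)}
        if pos.size == 0:
            continue
        keep, drop = pf.nn_outlier_filter(
            coords[pos], m=pc.nn_m, multiplier=pc.nn_multiplier
        )
        counters["nn_outlier"] += int(drop.size)
        stage_counts["nn_outlier"] = int(drop.size)
        pos = pos[keep]
        try:
            keep, drop = pf.dbscan_largest(
                coords[pos], eps=pc.dbscan_eps, min_pts=pc.dbscan_min_pts
            )
        except pf.NoClusterError as err:
            warnings.warn(f"ROI {r.roi_id}: {err}", stacklevel=2)
            counters["object_rejected"] += int(pos.size)
            continue
        counters["dbscan"] += int(drop.size)
        stage_counts["dbscan"] = int(drop.size)
        pos = pos[keep]
        keep, drop = pf.quality_filter(
            locs.iloc[pos],
            sigma_range=pc.sigma_range,
            precision_max=pc.precision_max,
            pixel_size=pc.camera_pixel_nm,
            background=pc.background,
        )
        counters["sigma_precision"] += int(drop.size)
        stage_counts["sigma_precision"] = int(drop.size)
        pos = pos[keep]
        if pos.size < 30:
            warnings.warn(f"ROI {r.roi_id}: too few localizations survive", stacklevel=2)
            counters["object_rejected"] += int(pos.size)
            continue
        kept_final += int(pos.size)
        perim, area = pf.convex_hull_stats(coords[pos])
        objects.append(
            pf.ClassifiedObject(
                roi_id=r.roi_id,
                member_indices=pos,
                hull_perimeter=perim,
                hull_area=area,
                n_discarded_by_stage=stage_counts,
            )
        )
        try:
            est = ana.estimate_separation(coords[pos])
            sep_rows.append(
                {
                    "roi_id": r.roi_id,
                    "d_hat_nm": est.d_hat,
                    "axis_angle_rad": est.axis_angle,
                    "peak_width_nm": est.peak_width,
                    "n_locs": est.n_locs,
                }
            )
        except (ana.ConvergenceError, ValueError) as err:
            warnings.warn(f"ROI {r.roi_id}: separation fit failed ({err})", stacklevel=2)

    report = pf.filter_report(counters, total=total_instances, kept=kept_final)
    manifest = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "n_localizations": n,
        "n_rois": len(rois),
        "n_objects": len(objects),
        "contrast_setting": contrast,
        "stage_discards": counters,
    }
    return SegmentationResult(
        rois=rois,
        labels=labels,
        covered=covered,
        objects=objects,
        separations=pd.DataFrame(
            sep_rows,
            columns=["roi_id", "d_hat_nm", "axis_angle_rad", "peak_width_nm", "n_locs"],
        ),
        report=report,
        manifest=manifest,
    )
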