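# sarcseg

Machine-learning segmentation of **sarcomeric double-line structures** in
single-molecule localization microscopy (SMLM/dSTORM) point clouds.

Many sarcomeric proteins of striated muscle sit in disc pairs that repeat
along the myofibril.  Imaged edge-on by 2D dSTORM they appear as *double
lines*: two parallel lines of length D ≈ 1.5 µm separated by d ≈ 120 nm,
repeating every L ≈ 3.4 µm.  Measuring d across many structures (by
structure averaging) localizes proteins with nanometer accuracy — but
first every double line must be found and its localizations separated from
background, which is tedious by hand.  `sarcseg` automates it, for
researchers analyzing rainSTORM/ThunderSTORM-style localization tables.

## Method

* **Simulation** (`sarcseg.simulate`): labelled training data at the
  localization level — epitopes on projected disc pairs, antibody-linker
  displacement, blinking multiplicity, per-localization precision jitter;
  vesicle-cluster and uniform background noise; noise within 50 nm of the
  structures is excluded from the merge.
* **Features** (`sarcseg.features`): each localization gets a 380-element
  vector computed inside a random subset sized so every structure
  contributes ~300 localizations — its 350 sorted nearest-neighbor
  distances concatenated with a 30-bin (12°) neighbor-direction histogram,
  smoothed over 3 bins and circularly aligned so the global maximum falls
  on the bin at −π/6 (orientation invariance).
* **Classifier** (`sarcseg.classify`): a shallow MLP — one hidden layer of
  32 ReLU units, a single sigmoid output, binary cross-entropy, Adam,
  10 epochs, batch 32 — maps feature vectors to object/noise, with
  distances-only and directions-only ablations.
* **ROI detection** (`sarcseg.roi`): candidate regions are detected on a
  rendered 100-nm-pixel image at several contrast settings (pluggable
  detector backend; classical elongated-component detector by default),
  expanded by 1 µm and grown in 0.5-µm steps until each holds ≥ 351
  localizations.
* **Post-filtering** (`sarcseg.postfilter`): 10-NN/5×median outlier rule →
  DBSCAN (ε = 50 nm, minPts = 5) largest cluster → σ ∈ [112, 160] nm and
  Thompson precision ≤ 20 nm quality gates, with convex-hull summaries and
  per-stage discard accounting.
* **Readout** (`sarcseg.analyze`): per object, the principal axis and a
  symmetric two-Gaussian mixture fit of the perpendicular distance profile
  give the line-separation estimate d̂.

See `docs/methods.md` for the model details and design choices.

## Worked example

Train on one simulated field, then segment an independently simulated
"measurement" field (reduced scale: 4 structures, k = 50, runs in
seconds):

```python
import numpy as np
from sarcseg import classify as cls, features as feat
from sarcseg.io import PipelineConfig
from sarcseg.pipeline import segment_measurement
from sarcseg.simulate import DoubleLineSpec, NoiseSpec, simulate_field

config = PipelineConfig(seed=5)
config.simulate = DoubleLineSpec(n_pairs=4, d=120.0)
config.noise = NoiseSpec(field_width=18000.0, field_height=8000.0)
config.features.k = 50
config.features.target_per_object = 200

train_df = simulate_field(config.simulate, config.noise, rng_seed=101)
coords = train_df[["x_nm", "y_nm"]].to_numpy(float)
y = (train_df["label"] == "object").to_numpy().astype(int)
subsets = feat.partition_subsets(
    np.arange(len(train_df)), int(y.sum() / 4),
    target_per_object=200, min_subset=51, rng_seed=3)
model = cls.train(feat.compute_features(coords, subsets, k=50), y,
                  cls.ClassifierSpec(rng_seed=1))

meas = simulate_field(config.simulate, config.noise, rng_seed=202)
result = segment_measurement(meas, model, config)
print(result.separations.round(2).to_string(index=False))
```

Output:

```
 roi_id  d_hat_nm  axis_angle_rad  peak_width_nm  n_locs
      0    119.75           -1.56          22.10    1593
      1    120.94            1.57          22.11    1510
      2    117.28            1.56          22.69    1704
      3    118.66           -1.56          21.93    1889
```

All four simulated structures are found as ROIs; the recovered line
separations d̂ sit within a few nm of the simulated d = 120 nm (the
~22-nm peak width reflects linker + localization-precision spread, and the
axis angle ±π/2 is the line direction, perpendicular to the strand).
`result.report` carries the per-stage discard counts of the filter chain,
e.g. here classification removed 17.0% of the ROI localizations and the
NN-outlier and DBSCAN stages 0.2% and 0.1%.

The same pipeline is scriptable from the shell:

```bash
sarcseg init-config --out config.yaml
sarcseg simulate --config config.yaml --seed 1 --out field.csv
sarcseg detect --in field.csv --out rois.json
sarcseg featurize --in field.csv --subsets rois.json --out features.npy
sarcseg run --in field.csv --model model --out results/
```

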