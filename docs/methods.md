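# Methods

`sarcseg` segments sarcomeric **double-line structures** in 2D SMLM
(dSTORM) localization tables and classifies, per localization, whether it
belongs to such a structure or to background.  A double line is the 2D
projection of a pair of protein discs in a myofibril: two parallel lines of
length `D` ≈ 1.5 µm separated by `d` ≈ 120 nm along the fiber axis,
repeating every `L` ≈ 3.4 µm along the strand.

## Synthetic data model

Real training labels are unobtainable (no ground truth in measurements), so
the classifier is trained on simulated localizations.  The simulator works
directly at the localization level:

1. **Geometry.** `n_pairs` (default 27) disc pairs are placed along a
   strand at spacing `L`; each pair projects to two segments of length `D`
   separated by `d`.  Epitope positions along a segment follow the
   chord-weighted density of a uniformly labelled disc projected onto a
   diameter (brighter mid-line; a flag restores plain-uniform sampling).
2. **Labelling.** Each epitope carries a rounded-normal number of dye
   labels (mean 5–6, variance 0–2); each label is displaced by the antibody
   linker (25–30 nm, uniform random direction) and blinks
   `max(1, Poisson(1.5))` times.  The blink multiplicity summarizes the
   ON/OFF/bleaching kinetics of the dye — only the resulting localization
   multiplicity matters for the features.
3. **Localization errors.** Every blink is jittered by an isotropic
   Gaussian whose per-localization precision is drawn from N(12, 4²) nm
   (truncated positive).  The fitted PSF width `sigma` is drawn uniformly
   from [105, 170] nm — deliberately bracketing the downstream quality gate
   [112, 160] nm — and the photon count is obtained by inverting the
   Thompson precision formula at the drawn precision (camera pixel 160 nm,
   background 19 photons/pixel, derived from the EMCCD camera model:
   200 counts × 21.5 e⁻/count ÷ (90 EM gain × 2.5 pre-amp)).  This keeps
   `sigma`/`photons`/`precision` mutually consistent to within rounding, so
   the quality-filter stage behaves as it would on fitted data.
4. **Noise.** Two components: vesicle clusters (Poisson-count centers
   uniform in the field, ~7–10 localizations each, Gaussian spread from the
   vesicle linker length), and uniform non-specific labels
   (35 /µm²).  Noise within 50 nm of any object localization is removed
   before merging — closer noise is indistinguishable from specific
   labelling and would poison the labels.
5. **Parameter heterogeneity.** Protein- and simulation-level parameters
   are drawn per field from their stated ranges (`d` ∈ [120, 128] nm,
   per-structure epitope density ∈ [30, 50] /µm², label/linker choices as
   above).  This emulates a corpus assembled from many simulations of
   different proteins rather than one homogeneous field.

One default field (27 pairs, ~95.6 × 8 µm) yields ≈ 50–80k object and
≈ 45–50k noise localizations — about a 1/10-scale version of the full
626k/510k corpus with the same per-field composition.  All randomness
flows from one seed through named substreams; a fixed seed reproduces the
table bit-exactly.

What the simulator does **not** model: PSF rendering and refitting, EMCCD
noise, frame-correlated blinking, drift, 3D/defocus effects, curved or
radially varying structures.  Classification rates measured on this corpus
therefore quantify the method under idealized, well-controlled conditions;
performance on real measurements is bounded by how well these assumptions
hold there.

## Feature vectors

Each localization is described by 380 numbers computed among the members of
its random subset:

* **350 sorted nearest-neighbor distances** (nm, ascending).  The early
  ranks encode local density; because subsets are sized so each structure
  contributes ~300 localizations, rank 350 always reaches past the
  structure into background, anchoring the tail in the noise regime
  regardless of labelling density.
* **30-bin direction histogram**: atan2 angles of the same 350 neighbors
  over the full circle, 12° bins, circularly smoothed with a 3-bin boxcar,
  then circularly shifted so the bin holding the global maximum sits at the
  bin centered on −π/6 (orientation invariance at bin granularity; −π/6
  keeps both characteristic peaks away from the histogram edge).  Ties in
  the maximum resolve to the lowest bin index.  Bins are normalized to
  **unit mean** (sum = 30): like a sum-1 normalization this removes the
  dependence on k, but it keeps the values near 1, which the short
  (10-epoch, batch-32) Adam schedule needs — with sum-1 bins (~0.03) the
  first-layer gradients are so small that the directions-only model
  underfits severely.  `hist_normalize=False` yields raw counts.

Distances are fed raw in nm; optional z-scoring from training-set
statistics is available but off by default.  Subset partitioning:
`n_subsets = max(1, round(est_locs_per_structure / 300))`, random
near-equal parts, reduced until every part has ≥ 351 members (a full k-NN
query needs k+1 points); below 351 total the region must be expanded.

Numerical notes: k-NN ties are broken by localization index (batch path
uses a k-d tree; exact ties are measure-zero for continuous coordinates);
angles use the convention [−π, π) with +π wrapped to −π; the alignment is
applied per localization.  On exact tied maxima the lowest-index rule makes
the aligned histogram weakly orientation-dependent; this degeneracy has
measure zero for real data.

## Classifier

A single-hidden-layer perceptron: 32 ReLU units, one sigmoid output,
binary cross-entropy loss, Adam (lr 10⁻³), 10 epochs, batch size 32,
decision threshold 0.5.  Training runs as an explicit per-epoch loop so
train/validation losses are recorded; the validation split (10%) is used
for monitoring only — no early stopping.  No class weighting (the corpus
is roughly balanced).  Rates are reported on the held-out 10% test split
of a stratified 80/10/10 split.  Feature-set ablations (distances-only
columns 0–349, directions-only 350–379, combined) train on column slices
of the same matrix with identical splits and seeds.

## ROI detection and expansion

Measurement files are large and mostly background, so feature vectors are
computed only inside candidate regions.  The point cloud is rendered as a
100-nm-pixel count histogram, contrast-clipped at an upper percentile of
the occupied pixels.  The default detector is classical: Gaussian blur
(σ = 1 px) → Otsu threshold → morphological closing → connected
components, keeping components with major axis within [0.5, 2] × D and
aspect ratio ≥ 2 (double lines are elongated; vesicles are compact).  Any
callable `backend(image) -> boxes` — e.g. a trained Mask-RCNN — can be
plugged in behind the same contract; the classical default keeps the
pipeline self-contained and desk-scale.  For a deep backend, training data
can be augmented by taking random subsets of simulated localizations and
rotating the structure in small angular steps.

Detection runs at several contrast settings ({99.0, 99.5, 99.9} upper
percentiles); the setting with the most boxes (total box area breaks ties,
lower percentile wins exact ties) is kept.  Each box is expanded by 1 µm on
all sides, then grown in 0.5-µm increments (at most 10) until its
localizations can be partitioned into subsets of ≥ 351; otherwise the ROI
is rejected.  A localization in several overlapping ROIs is labelled
object if **any** ROI classifies it as object — the enclosing ROI sees the
whole structure and is the more reliable vote; the largest-cluster filter
removes spurious positives this introduces.

## Post-filtering

Applied in order on classifier positives, per ROI (measurement mode only —
never on the simulated corpus used to score the classifier):

1. **NN-outlier rule**: discard localizations whose mean distance to their
   first 10 neighbors exceeds 5× the median of that statistic.
2. **DBSCAN** (ε = 50 nm, minPts = 5): keep the most populous cluster
   (ties → lowest cluster label); no cluster ⇒ reject the object.
3. **Quality gates**: `sigma` ∈ [112, 160] nm (closed interval) and
   Thompson precision ≤ 20 nm (inclusive; boundary inclusion is the
   package's choice).  Missing precision is derived from sigma/photons.

Convex-hull perimeter and area of the surviving cluster are reported (via
Qhull; collinear sets get area 0 and perimeter 2× the span).  Stage counts
are conserved exactly and reported as discard ratios in two conventions:
against the total entering classification, and against each stage's own
input — published per-stage tables are ambiguous between the two, so both
are emitted and neither is asserted against external numbers.

## Line-separation readout

For each accepted object the principal (largest-variance) axis through the
centroid is taken as the symmetry axis — a straight-axis simplification of
density-based curved-axis fits used by full structure-averaging tools.
Signed perpendicular distances from the axis are fitted with a symmetric
two-Gaussian mixture (means ±d/2, shared width, equal weights) by EM;
`d_hat` is the distance between the component means.  EM is initialized
from moments (μ₀ = mean |t|, σ₀² = var(t) − μ₀²), converges monotonically,
and handles the degenerate zero-width case (two delta lines) exactly.  No
correction for antibody size or localization precision is applied, so
`d_hat` estimates the separation of the *label* distributions, not the
epitopes; on synthetic data with known `d` the residual bias from
in-between background is well inside ±10 nm.

## Problem sizes and defaults

The standard benchmark corpus is one 27-pair field per seed
(~110–130k localizations, ≈ 55% object), three seeds for reported rates,
five for the ablation-ordering robustness check; the end-to-end recovery
check uses four measurement-mode fields (108 objects) at `d` = 120 nm.
These sizes are the package's reference conditions: one field reproduces
the per-field composition of the full corpus at about a tenth of its bulk,
which keeps all benchmarks runnable on a single CPU core.  Reduced-scale
smoke configurations (k = 50, 4-pair fields) exercise the identical code
paths for fast iteration.

## Known limitations

* Classical detector recall depends on rendering contrast; very dense
  fields with touching structures may merge into one component (partially
  mitigated by multi-contrast selection).
* The straight principal axis under-fits bent myofibrils; `d_hat` is then
  biased upward by axis misalignment.
* Thompson-formula inversion assumes the background level is known; real
  tables should supply a measured background.
* The OR-merge across overlapping ROIs can duplicate an object in two ROIs;
  consumers should deduplicate by detection box when counting objects.
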