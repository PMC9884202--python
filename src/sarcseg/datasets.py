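"""Standard synthetic corpora used for training and benchmarking.

The default training corpus is one simulated field: a strand of 27
double-line pairs (L = 3.4 um, D = 1.5 um, d drawn from 120-128 nm)
yielding ~60k object localizations, plus vesicle and uniform background
yielding ~50k noise localizations after the 50-nm exclusion merge —
roughly a 1/10-scale version of the full 626k/510k training corpus, with
the same per-field composition.
"""

from __future__ import annotations

import numpy as np

from . import features as feat
from .simulate import DoubleLineSpec, NoiseSpec, simulate_field, split_train_val_test

__all__ = ["standard_field", "training_corpus"]


def standard_field(rng_seed: int = 0, d: float | None = None):
    """One labelled field at the study's default conditions.

    Protein- and simulation-level parameters are drawn from their stated
    ranges: line separation ``d`` from 120-128 nm, per-structure epitope
    density from 30-50 per um^2 of disc face, labels per epitope with mean
    5 or 6 and variance 0-2, antibody linker 25 or 30 nm; noise vesicles
    carry 4 or 6 labels each with linker 10-30 nm.
    """
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0xD1]))
    if d is None:
        d = float(rng.uniform(120.0, 128.0))
    blinks_mean = 1.5
    mean_blinks_per_label = blinks_mean + np.exp(-blinks_mean)  # E[max(1, Pois)]
    line_spec = DoubleLineSpec(
        d=d,
        epitope_density_range=(30.0, 50.0),
        labels_per_epitope_mean=float(rng.choice([5.0, 6.0])),
        labels_per_epitope_var=float(rng.choice([0.0, 1.0, 2.0])),
        linker_length=float(rng.choice([25.0, 30.0])),
        blinks_per_label_mean=blinks_mean,
    )
    vesicle_labels = float(rng.choice([4.0, 6.0]))
    vesicle_linker = float(rng.choice([10.0, 15.0, 30.0]))
    noise_spec = NoiseSpec(
        vesicle_locs_mean=vesicle_labels * mean_blinks_per_label,
        vesicle_sd=float(np.sqrt(vesicle_linker**2 / 2.0 + 12.0**2)),
    )
    return simulate_field(line_spec, noise_spec, rng_seed=rng_seed)


def training_corpus(
    rng_seed: int = 0,
    n_fields: int = 1,
    k: int = feat.DEFAULT_K,
    target_per_object: int = 300,
    return_locs: bool = False,
):
    """Simulate, featurize and split the standard labelled corpus.

    Features are computed per field within random subsets sized so each
    double-line structure contributes ~``target_per_object`` localizations.
    Returns ``(X, y, (train_idx, val_idx, test_idx))`` with y = 1 for
    object localizations; with ``return_locs`` the localization table is
    appended as a fourth element.
    """
    blocks_X, blocks_y, blocks_df = [], [], []
    for i in range(n_fields):
        df = standard_field(rng_seed=(rng_seed * 1000 + i) % 2**31)
        coords = df[["x_nm", "y_nm"]].to_numpy(float)
        y = (df["label"] == "object").to_numpy()
        n_objects = df["object_id"].nunique()
        per_structure = int(y.sum() / max(n_objects, 1))
        subsets = feat.partition_subsets(
            np.arange(len(df)),
            per_structure,
            target_per_object=target_per_object,
            min_subset=k + 1,
            rng_seed=(rng_seed * 1000 + 500 + i) % 2**31,
        )
        blocks_X.append(feat.compute_features(coords, subsets, k=k))
        blocks_y.append(y.astype(int))
        blocks_df.append(df)
    X = np.concatenate(blocks_X)
    y = np.concatenate(blocks_y)
    splits = split_train_val_test(y, (0.8, 0.1, 0.1), rng_seed=rng_seed)
    if return_locs:
        import pandas as pd

        return X, y, splits, pd.concat(blocks_df, ignore_index=True)
    return X, y, splits
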