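import numpy as np
import pandas as pd
import pytest

from sarcseg.simulate import (
    DoubleLineSpec,
    NoiseSpec,
    merge_with_exclusion,
    simulate_double_lines,
    simulate_field,
    simulate_noise,
    split_train_val_test,
)


def perpendicular_offsets(df, spec):
    """Brute-force signed offsets of each localization from its pair center
    along the strand axis (the line-separation coordinate)."""
    u = np.array([np.cos(spec.strand_angle), np.sin(spec.strand_angle)])
    xy = df[["x_nm", "y_nm"]].to_numpy(float)
    out = np.empty(len(df))
    for pair in df["object_id"].unique():
        mask = (df["object_id"] == pair).to_numpy()
        center = xy[mask].mean(axis=0)
        out[mask] = (xy[mask] - center) @ u
    return out


class TestSimulateDoubleLines:
    def test_labels_and_object_ids(self, small_line_spec):
        df = simulate_double_lines(small_line_spec, rng_seed=0)
        assert (df["label"] == "object").all()
        assert set(df["object_id"].unique()) == set(range(small_line_spec.n_pairs))
        assert (df["sigma_nm"] > 0).all()
        assert (df["photons"] > 0).all()
        assert (df["precision_nm"] > 0).all()

    def test_zero_density_gives_empty_table(self):
        spec = DoubleLineSpec(epitope_density=0.0)
        assert len(simulate_double_lines(spec, rng_seed=0)) == 0

    def test_zero_jitter_points_lie_exactly_on_two_lines(self):
        """With no linker and no jitter, every localization sits exactly on
        one of the two segments at +/- d/2 from the pair center."""
        spec = DoubleLineSpec(
            n_pairs=4,
            d=200.0,
            linker_length=0.0,
            jitter_scale=0.0,
            blinks_per_label_mean=0.0,
            strand_angle=0.3,
        )
        df = simulate_double_lines(spec, rng_seed=1)
        offsets = perpendicular_offsets(df, spec)
        for pair in df["object_id"].unique():
            t = offsets[(df["object_id"] == pair).to_numpy()]
            values = np.unique(np.round(t, 9))
            assert len(values) == 2
            assert values[1] - values[0] == pytest.approx(200.0, abs=1e-9)

    def test_line_separation_matches_d_within_jitter(self):
        """Per-object separation of the two line centroids ~ d = 120 nm."""
        spec = DoubleLineSpec(n_pairs=27)
        df = simulate_double_lines(spec, rng_seed=3)
        assert df["object_id"].nunique() == 27
        u = np.array([1.0, 0.0])
        xy = df[["x_nm", "y_nm"]].to_numpy(float)
        for pair in range(27):
            t = (xy[(df["object_id"] == pair).to_numpy()] - 0) @ u
            t = t - t.mean()
            sep = t[t > 0].mean() - t[t <= 0].mean()
            # transverse spread ~ sqrt(prec^2 + linker^2/2) ~ 22 nm
            assert sep == pytest.approx(120.0, abs=25.0)

    def test_thompson_consistency_of_metadata(self, small_line_spec):
        from sarcseg.postfilter import thompson_precision
        from sarcseg.simulate import CAMERA_PIXEL_NM, DEFAULT_BACKGROUND

        df = simulate_double_lines(small_line_spec, rng_seed=2)
        recomputed = thompson_precision(
            df["sigma_nm"], df["photons"], CAMERA_PIXEL_NM, DEFAULT_BACKGROUND
        )
        ratio = recomputed / df["precision_nm"].to_numpy()
        assert np.all(np.abs(ratio - 1.0) < 0.2)

    def test_invalid_spec_raises(self):
        with pytest.raises(ValueError):
            simulate_double_lines(DoubleLineSpec(d=-1.0), rng_seed=0)
        with pytest.raises(ValueError):
            simulate_double_lines(DoubleLineSpec(L=100.0, d=200.0), rng_seed=0)
        with pytest.raises(ValueError):
            simulate_double_lines(DoubleLineSpec(n_pairs=0), rng_seed=0)

    def test_fixed_seed_is_bit_identical(self, small_line_spec):
        a = simulate_double_lines(small_line_spec, rng_seed=9)
        b = simulate_double_lines(small_line_spec, rng_seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateNoise:
    def test_zero_densities_empty(self):
        spec = NoiseSpec(vesicle_density=0.0, uniform_density=0.0)
        assert len(simulate_noise(spec, rng_seed=0)) == 0

    def test_uniform_count_matches_poisson_mean(self):
        """3 /um^2 over 10x10 um -> mean 300 localizations (Poisson oracle),
        mean over 1000 seeds within 3 standard errors."""
        spec = NoiseSpec(
            vesicle_density=0.0,
            uniform_density=3.0,
            field_width=10000.0,
            field_height=10000.0,
        )
        counts = [len(simulate_noise(spec, rng_seed=s)) for s in range(1000)]
        se = np.sqrt(300.0 / 1000.0)
        assert abs(np.mean(counts) - 300.0) < 3.0 * se

    def test_count_scales_linearly_with_density(self):
        """Mean localization count vs density is linear (slope test)."""
        densities = [2.0, 4.0, 8.0]
        means = []
        for d in densities:
            spec = NoiseSpec(
                vesicle_density=0.0, uniform_density=d,
                field_width=20000.0, field_height=20000.0,
            )
            means.append(
                np.mean([len(simulate_noise(spec, rng_seed=s)) for s in range(30)])
            )
        expected = [d * 400.0 for d in densities]
        for m, e in zip(means, expected):
            assert m == pytest.approx(e, rel=0.05)

    def test_vesicle_clusters_recovered_by_dbscan(self):
        """On a sparse field the DBSCAN cluster count equals the simulated
        vesicle count (brute-force check via scikit-learn on ground truth)."""
        from sklearn.cluster import DBSCAN

        spec = NoiseSpec(
            vesicle_density=0.1,
            vesicle_locs_mean=30.0,
            vesicle_sd=10.0,
            uniform_density=0.0,
            field_width=30000.0,
            field_height=30000.0,
        )
        df = simulate_noise(spec, rng_seed=8)
        labels = DBSCAN(eps=50.0, min_samples=5).fit_predict(
            df[["x_nm", "y_nm"]].to_numpy()
        )
        n_clusters = len(set(labels[labels >= 0]))
        # ~90 clusters expected; allow rare overlaps/small clusters
        assert n_clusters == pytest.approx(spec.vesicle_density * 900, rel=0.1)


class TestMergeWithExclusion:
    def test_zero_radius_is_plain_concatenation(self, small_field):
        obj = small_field[small_field["label"] == "object"]
        noi = small_field[small_field["label"] == "noise"]
        merged = merge_with_exclusion(obj, noi, radius=0.0)
        assert len(merged) == len(obj) + len(noi)

    def test_printed_example_30_removed_80_kept(self):
        obj = pd.DataFrame({"x_nm": [0.0], "y_nm": [0.0], "label": ["object"]})
        noi = pd.DataFrame(
            {"x_nm": [30.0, 80.0], "y_nm": [0.0, 0.0], "label": ["noise", "noise"]}
        )
        merged = merge_with_exclusion(obj, noi, radius=50.0)
        kept_noise = merged[merged["label"] == "noise"]["x_nm"].tolist()
        assert kept_noise == [80.0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_no_kept_noise_within_radius_all_pairs(self, seed):
        """Post-condition verified by an O(n^2) all-pairs scan."""
        rng = np.random.default_rng(seed)
        obj = pd.DataFrame(
            {"x_nm": rng.uniform(0, 2000, 80), "y_nm": rng.uniform(0, 2000, 80)}
        )
        obj["label"] = "object"
        noi = pd.DataFrame(
            {"x_nm": rng.uniform(0, 2000, 300), "y_nm": rng.uniform(0, 2000, 300)}
        )
        noi["label"] = "noise"
        merged = merge_with_exclusion(obj, noi, radius=50.0)
        kept = merged[merged["label"] == "noise"][["x_nm", "y_nm"]].to_numpy()
        oxy = obj[["x_nm", "y_nm"]].to_numpy()
        dists = np.sqrt(((kept[:, None, :] - oxy[None, :, :]) ** 2).sum(-1))
        assert np.all(dists.min(axis=1) >= 50.0)
        # and that only offending noise was removed
        nxy = noi[["x_nm", "y_nm"]].to_numpy()
        all_d = np.sqrt(((nxy[:, None, :] - oxy[None, :, :]) ** 2).sum(-1))
        expected_kept = int((all_d.min(axis=1) >= 50.0).sum())
        assert len(kept) == expected_kept

    def test_negative_radius_raises(self, small_field):
        with pytest.raises(ValueError):
            merge_with_exclusion(small_field, small_field, radius=-1.0)


class TestSplit:
    def test_sizes_8_1_1(self):
        tr, va, te = split_train_val_test(["a"] * 10, (0.8, 0.1, 0.1), rng_seed=0)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_property(self, seed):
        labels = np.array(["object"] * 37 + ["noise"] * 23)
        tr, va, te = split_train_val_test(labels, rng_seed=seed)
        allidx = np.concatenate([tr, va, te])
        assert sorted(allidx) == list(range(60))
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    @pytest.mark.parametrize("seed", range(5))
    def test_stratification_tracks_global_ratio(self, seed):
        labels = np.array([1] * 40 + [0] * 20)
        splits = split_train_val_test(labels, (0.8, 0.1, 0.1), rng_seed=seed)
        for idx, frac in zip(splits, (0.8, 0.1, 0.1)):
            n_obj = int(np.sum(labels[idx] == 1))
            assert abs(n_obj - 40 * frac) <= 1

    def test_invalid_fractions_raise(self):
        with pytest.raises(ValueError):
            split_train_val_test([1, 0], (0.5, 0.4, 0.2))


def test_field_fixed_seed_bit_identical(small_line_spec, small_noise_spec):
    a = simulate_field(small_line_spec, small_noise_spec, rng_seed=4)
    b = simulate_field(small_line_spec, small_noise_spec, rng_seed=4)
    pd.testing.assert_frame_equal(a, b)
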