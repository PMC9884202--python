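import numpy as np
import pandas as pd
import pytest

from sarcseg.postfilter import (
    NoClusterError,
    convex_hull_stats,
    dbscan_largest,
    filter_report,
    nn_outlier_filter,
    quality_filter,
    thompson_precision,
)


def brute_force_dbscan(coords, eps, min_pts):
    """O(n^2) region-query DBSCAN oracle; returns labels, -1 = noise."""
    n = len(coords)
    d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for q in neighbors[j]:
                if labels[q] == -1:
                    labels[q] = cluster
                    stack.append(q)
        cluster += 1
    return labels


class TestNNOutlierFilter:
    def test_regular_grid_keeps_everything(self):
        g = np.arange(10)
        coords = np.array([(x, y) for x in g for y in g], dtype=float)
        kept, discarded = nn_outlier_filter(coords, m=4)
        assert discarded.size == 0 and kept.size == 100

    def test_single_far_outlier_discarded(self):
        """Dense 100-point cluster + 1 point 10x the pitch away: brute-force
        means/median oracle says exactly that point goes."""
        rng = np.random.default_rng(1)
        cluster = rng.uniform(0, 100, (100, 2))
        coords = np.vstack([cluster, [1000.0, 1000.0]])
        m = 10
        d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        d_sorted = np.sort(d, axis=1)[:, 1 : m + 1]
        means = d_sorted.mean(axis=1)
        oracle_out = np.flatnonzero(means > 5 * np.median(means))
        kept, discarded = nn_outlier_filter(coords, m=m, multiplier=5)
        np.testing.assert_array_equal(discarded, oracle_out)
        assert discarded.tolist() == [100]

    def test_infinite_multiplier_keeps_everything(self, rng):
        coords = rng.uniform(0, 100, (50, 2))
        kept, discarded = nn_outlier_filter(coords, m=5, multiplier=np.inf)
        assert discarded.size == 0

    def test_too_few_points_skips_with_warning(self):
        coords = np.zeros((5, 2))
        with pytest.warns(UserWarning, match="skipped"):
            kept, discarded = nn_outlier_filter(coords, m=10)
        assert kept.size == 5 and discarded.size == 0


class TestDBSCANLargest:
    def test_larger_blob_wins(self, rng):
        big = rng.normal(0, 10, (60, 2))
        small = rng.normal(0, 10, (40, 2)) + np.array([1000.0, 0.0])
        coords = np.vstack([big, small])
        kept, discarded = dbscan_largest(coords, eps=50, min_pts=5)
        assert set(kept) == set(range(60))
        assert set(discarded) == set(range(60, 100))

    def test_all_isolated_points_rejected(self):
        coords = np.arange(40, dtype=float).reshape(20, 2) * 100.0
        with pytest.raises(NoClusterError):
            dbscan_largest(coords, eps=50, min_pts=5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        """Largest-cluster membership equals an O(n^2) DBSCAN oracle on
        mixed clustered+uniform instances (<= 500 points)."""
        rng = np.random.default_rng(seed)
        blobs = [
            rng.normal(0, 15, (rng.integers(10, 60), 2)) + rng.uniform(0, 2000, 2)
            for _ in range(4)
        ]
        coords = np.vstack(blobs + [rng.uniform(0, 2000, (100, 2))])
        labels = brute_force_dbscan(coords, eps=50, min_pts=5)
        if labels.max() < 0:
            return
        sizes = np.bincount(labels[labels >= 0])
        oracle_best = np.argmax(sizes)
        oracle_kept = set(np.flatnonzero(labels == oracle_best))
        kept, _ = dbscan_largest(coords, eps=50, min_pts=5)
        assert set(kept) == oracle_kept


class TestConvexHull:
    def test_unit_square(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        perimeter, area = convex_hull_stats(pts)
        assert perimeter == pytest.approx(4.0)
        assert area == pytest.approx(1.0)

    def test_collinear_points(self):
        pts = np.array([[0, 0], [5, 0], [10, 0]], dtype=float)
        perimeter, area = convex_hull_stats(pts)
        assert perimeter == pytest.approx(20.0)
        assert area == 0.0

    def test_hull_contains_all_points(self, rng):
        from scipy.spatial import ConvexHull, Delaunay

        pts = rng.normal(0, 50, (100, 2))
        perimeter, area = convex_hull_stats(pts)
        hull = ConvexHull(pts)
        assert Delaunay(pts[hull.vertices]).find_simplex(pts).min() >= 0
        assert perimeter > 0 and area > 0

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            convex_hull_stats(np.zeros((1, 2)))


class TestThompsonPrecision:
    def test_closed_form_spot_check(self):
        """sigma=130, N=1000, a=160, b=0 against independent arithmetic."""
        expected = np.sqrt(130.0**2 / 1000.0 + 160.0**2 / 12000.0)
        assert thompson_precision(130.0, 1000.0, 160.0, 0.0) == pytest.approx(expected)

    def test_monotone_decreasing_in_photons(self):
        values = [thompson_precision(130.0, n, 160.0, 5.0) for n in (100, 500, 2500)]
        assert values[0] > values[1] > values[2]

    def test_small_pixel_limit_is_sigma_over_sqrt_n(self):
        p = thompson_precision(130.0, 400.0, 1e-3, 0.0)
        assert p == pytest.approx(130.0 / 20.0, rel=1e-6)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            thompson_precision(-1.0, 100.0)
        with pytest.raises(ValueError):
            thompson_precision(130.0, 0.0)


class TestQualityFilter:
    def toy(self):
        return pd.DataFrame(
            {
                "sigma_nm": [130.0, 111.0, 161.0, 140.0, 150.0, 120.0],
                "precision_nm": [15.0, 10.0, 12.0, 25.0, 19.9, 20.0],
                "photons": [1000] * 6,
            }
        )

    def test_six_row_toy_keeps_three(self):
        """2 sigma violations + 1 precision violation (disjoint) -> 3 kept;
        boundary values sigma 120/150 and precision 20 are kept."""
        kept, discarded = quality_filter(self.toy())
        assert kept.tolist() == [0, 4, 5]
        assert discarded.tolist() == [1, 2, 3]

    def test_boundaries_inclusive(self):
        df = pd.DataFrame(
            {"sigma_nm": [112.0, 160.0], "precision_nm": [20.0, 20.0]}
        )
        kept, _ = quality_filter(df)
        assert kept.tolist() == [0, 1]

    def test_precision_derived_from_photons_when_missing(self):
        df = pd.DataFrame({"sigma_nm": [130.0, 130.0], "photons": [10000, 10]})
        kept, discarded = quality_filter(df)
        assert kept.tolist() == [0] and discarded.tolist() == [1]

    def test_missing_columns_named(self):
        with pytest.raises(ValueError, match="sigma_nm"):
            quality_filter(pd.DataFrame({"x_nm": [1.0]}))
        with pytest.raises(ValueError, match="precision_nm.*photons"):
            quality_filter(pd.DataFrame({"sigma_nm": [130.0]}))


class TestFilterReport:
    def test_ratios_against_total(self):
        report = filter_report(
            {"classification": 571, "nn": 8, "dbscan": 195}, total=1000, kept=226
        )
        st = report["stages"]
        assert st["classification"]["ratio_of_total"] == pytest.approx(0.571)
        assert st["nn"]["ratio_of_total"] == pytest.approx(0.008)
        assert st["dbscan"]["ratio_of_total"] == pytest.approx(0.195)
        # per-stage-input convention uses the shrinking denominator
        assert st["dbscan"]["ratio_of_stage_input"] == pytest.approx(195 / 421)
        total_ratio = sum(s["ratio_of_total"] for s in st.values())
        assert total_ratio + report["kept_fraction"] == pytest.approx(1.0)

    def test_no_discards(self):
        report = filter_report({"a": 0, "b": 0}, total=50, kept=50)
        assert all(s["discarded"] == 0 for s in report["stages"].values())

    def test_conservation_enforced(self):
        with pytest.raises(ValueError, match="conservation"):
            filter_report({"a": 10}, total=100, kept=80)
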