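import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swarmbalance import (
    BalancerParams,
    DegenerateInputError,
    LabeledDataset,
    minority_neighbors,
    param_bounds,
    smote_augment,
    synthesis_count,
)
from conftest import counts_dataset


class TestMinorityNeighbors:
    def test_nearest_on_a_line(self):
        pts = np.array([[0.0], [1.0], [10.0]])
        assert minority_neighbors(pts, 0, 1).tolist() == [1]
        assert minority_neighbors(pts, 0, 2).tolist() == [1, 2]
        assert minority_neighbors(pts, 2, 1).tolist() == [1]

    def test_matches_exhaustive_distance_sort(self, rng):
        X = rng.normal(size=(20, 4))
        for idx in (0, 7, 19):
            got = minority_neighbors(X, idx, 5)
            d = np.linalg.norm(X - X[idx], axis=1)
            # oracle: all-pairs sort, seed excluded, ties toward lower id
            oracle = sorted(
                (i for i in range(20) if i != idx), key=lambda i: (d[i], i)
            )[:5]
            assert got.tolist() == oracle

    def test_ties_break_toward_lower_row_id(self):
        pts = np.array([[0.0], [1.0], [-1.0], [2.0]])
        assert minority_neighbors(pts, 0, 2).tolist() == [1, 2]

    def test_seed_point_excluded_and_k_clamped(self):
        pts = np.array([[0.0], [3.0]])
        got = minority_neighbors(pts, 0, 10)
        assert got.tolist() == [1]

    def test_single_point_cannot_synthesize(self):
        with pytest.raises(DegenerateInputError):
            minority_neighbors(np.array([[0.0]]), 0, 1)


class TestSynthesisCount:
    @pytest.mark.parametrize(
        "M,S,total",
        [
            (48, 6969, 3393),   # published whole-dataset run
            (22, 26247, 5796),  # published whole-dataset run
            (16, 9700, 1568),   # published window-2 run
            (10, 100, 20),      # S=100 doubles the class
            (48, 0, 48),        # no synthesis
        ],
    )
    def test_total_minority_after_oversampling(self, M, S, total):
        assert M + synthesis_count(M, S) == total

    @given(M=st.integers(1, 5000), S=st.integers(0, 100_000))
    @settings(derandomize=True, max_examples=200)
    def test_floor_convention(self, M, S):
        assert synthesis_count(M, S) == (M * S) // 100


class TestSmoteAugment:
    def make_ds(self, rng, n_maj=30, n_min=8, d=3):
        feats = rng.normal(size=(n_maj + n_min, d))
        labels = np.array([0] * n_maj + [1] * n_min)
        return LabeledDataset(feats, labels)

    def test_originals_preserved_first_and_unchanged(self, rng):
        ds = self.make_ds(rng)
        aug = smote_augment(ds, BalancerParams(250, 3), rng=1)
        np.testing.assert_array_equal(aug.features[: ds.n_rows], ds.features)
        assert aug.labels[: ds.n_rows].tolist() == ds.labels.tolist()
        assert aug.labels[ds.n_rows:].tolist() == [1] * (aug.n_rows - ds.n_rows)

    def test_synthetics_are_convex_combinations(self, rng):
        ds = self.make_ds(rng)
        aug = smote_augment(ds, BalancerParams(400, 3), rng=2)
        minority = ds.features[ds.labels == 1]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        syn = aug.features[ds.n_rows:]
        # every synthetic point lies on a segment between two minority rows,
        # hence inside the minority bounding box, coordinate-wise
        assert (syn >= lo - 1e-12).all() and (syn <= hi + 1e-12).all()
        for row in syn[:10]:
            on_segment = False
            for i in range(len(minority)):
                for j in range(len(minority)):
                    if i == j:
                        continue
                    v = minority[j] - minority[i]
                    w = row - minority[i]
                    t = np.dot(w, v) / np.dot(v, v)
                    if 0 <= t <= 1 and np.allclose(row, minority[i] + t * v,
                                                   atol=1e-9):
                        on_segment = True
                        break
                if on_segment:
                    break
            assert on_segment

    def test_zero_percent_is_identity(self, rng):
        ds = self.make_ds(rng)
        aug = smote_augment(ds, BalancerParams(0, 5), rng=3)
        np.testing.assert_array_equal(aug.features, ds.features)
        assert aug.labels.tolist() == ds.labels.tolist()

    def test_same_seed_same_output(self, rng):
        ds = self.make_ds(rng)
        a = smote_augment(ds, BalancerParams(333, 4), rng=7)
        b = smote_augment(ds, BalancerParams(333, 4), rng=7)
        np.testing.assert_array_equal(a.features, b.features)

    def test_published_minority_total(self):
        ds = counts_dataset(3375, 48)
        ds.features = np.random.default_rng(0).normal(size=ds.features.shape)
        aug = smote_augment(ds, BalancerParams(6969, 36), rng=0)
        assert aug.class_counts().positive == 3393

    def test_oversized_k_clamps_with_warning(self, rng):
        ds = self.make_ds(rng, n_min=4)
        with pytest.warns(UserWarning, match="clamping"):
            aug = smote_augment(ds, BalancerParams(100, 610), rng=0)
        assert aug.class_counts().positive == 8

    def test_single_minority_row_errors(self, rng):
        ds = self.make_ds(rng, n_min=1)
        # n_min=1 → only one positive: cannot interpolate
        ds2 = LabeledDataset(ds.features, ds.labels)
        with pytest.raises(DegenerateInputError):
            smote_augment(ds2, BalancerParams(100, 2), rng=0)


class TestParamBounds:
    def test_9801_s_values_and_k_range(self):
        # 1980 majority / 20 minority → S spans 100..9900: the 9801-value,
        # K 2..20 search space whose exhaustive sweep is 186,219 points
        ds = counts_dataset(1980, 20)
        (s_lo, s_hi), (k_lo, k_hi) = param_bounds(ds, "experiment2")
        assert s_hi - s_lo + 1 == 9801
        assert (s_lo, s_hi) == (100, 9900)
        assert (k_lo, k_hi) == (2, 20)

    def test_bioassay_362_upper_bound(self):
        ds = counts_dataset(3375, 48)
        (s_lo, s_hi), _ = param_bounds(ds, "experiment1")
        assert s_lo == 10
        assert s_hi == 7031  # floor(100 * 3375 / 48)

    def test_balanced_dataset_upper_is_100(self):
        ds = counts_dataset(10, 10)
        (_, s_hi), _ = param_bounds(ds, "experiment1")
        assert s_hi == 100
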