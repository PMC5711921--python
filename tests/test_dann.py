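import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from osteomir.cohort import MODEL_FEATURES
from osteomir.dann import (
    DANNModel,
    derivative_features,
    derivative_grid,
    division_sizes,
    euclidean,
    make_divisions,
    train_dann,
)


class TestEuclidean:
    def test_identical_rows_zero(self):
        assert euclidean([0.1, 0.2], [0.1, 0.2]) == 0.0

    def test_unit_difference(self):
        assert euclidean([0, 0], [0, 1]) == 1.0

    def test_six_dim_max_distance(self):
        assert euclidean(np.zeros(6), np.ones(6)) == pytest.approx(np.sqrt(6))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            euclidean([1, 2], [1, 2, 3])


class TestDivisions:
    @pytest.mark.parametrize("n, m, sizes", [
        (229, 4, [58, 57, 57, 57]),
        (10, 2, [5, 5]),
        (229, 10, [23, 23, 23, 23, 23, 23, 23, 23, 23, 22]),
    ])
    def test_nearly_equal_sizes(self, n, m, sizes):
        assert division_sizes(n, m) == sizes

    def test_m_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            division_sizes(100, 1)
        with pytest.raises(ValueError):
            division_sizes(100, 11)

    def test_m_exceeding_reference_rejected(self):
        with pytest.raises(ValueError):
            division_sizes(5, 8)

    @given(st.integers(11, 300), st.integers(2, 10))
    @settings(max_examples=150, deadline=None)
    def test_partition_contract(self, n, m):
        """Divisions are disjoint, exhaustive and size-balanced for all (n, m)."""
        rng = np.random.default_rng(n * 13 + m)
        dists = rng.random(n)
        blocks = make_divisions(dists, m)
        sizes = [len(b) for b in blocks]
        assert max(sizes) - min(sizes) <= 1
        combined = np.concatenate(blocks)
        assert sorted(combined) == list(range(n))
        # ordered by distance: nearest block's max <= farthest block's min
        assert dists[blocks[0]].max() <= dists[blocks[-1]].min() + 1e-12

    def test_tie_break_by_id_order(self):
        dists = np.array([0.5, 0.2, 0.5, 0.1])
        blocks = make_divisions(dists, 2)
        assert list(blocks[0]) == [3, 1] and list(blocks[1]) == [0, 2]


class TestDerivativeFeatures:
    # 5-member reference fixture in 2-D, hand-computed:
    #   focal at origin; members A..E at the coordinates below
    #   distances: A=0.1, B=0.5, C=0.2, D=1.0, E=1.0 (D before E by id order)
    #   m=2 -> division 1 = {A, C, B}, division 2 = {D, E}
    REF_X = np.array([[0.1, 0.0], [0.3, 0.4], [0.0, 0.2], [1.0, 0.0], [0.6, 0.8]])
    REF_OUT = np.array([0.2, 0.4, 0.6, 0.8, 1.0])
    REF_RISK = np.array([0.0, 1.0, 0.0, 1.0, 1.0])

    def test_hand_computed_nearest_division(self):
        f = derivative_features(np.zeros(2), 0.5, self.REF_X, self.REF_OUT,
                                self.REF_RISK, m=2, d_index=1)
        assert f.ann1_self == 0.5
        assert f.div_mean_output == pytest.approx((0.2 + 0.6 + 0.4) / 3)
        assert f.div_mean_dist == pytest.approx((0.1 + 0.2 + 0.5) / 3)
        assert f.div_op_prop == pytest.approx(1 / 3)

    def test_hand_computed_far_division(self):
        f = derivative_features(np.zeros(2), 0.5, self.REF_X, self.REF_OUT,
                                self.REF_RISK, m=2, d_index=2)
        assert f.div_mean_output == pytest.approx(0.9)
        assert f.div_mean_dist == pytest.approx(1.0)
        assert f.div_op_prop == 1.0

    def test_all_osteoporosis_division(self):
        f = derivative_features(np.zeros(2), 0.1, self.REF_X, self.REF_OUT,
                                np.ones(5), m=2, d_index=1)
        assert f.div_op_prop == 1.0

    def test_degenerate_geometry(self):
        # focal identical to every reference member: zero distance everywhere
        # and division outputs collapse to the shared network output
        ref = np.tile([[0.5, 0.5]], (6, 1))
        out = np.full(6, 0.7)
        f = derivative_features(np.array([0.5, 0.5]), 0.7, ref, out,
                                np.zeros(6), m=3, d_index=1)
        assert f.div_mean_dist == 0.0
        assert f.div_mean_output == f.ann1_self == 0.7

    def test_invalid_d_index(self):
        with pytest.raises(ValueError):
            derivative_features(np.zeros(2), 0.5, self.REF_X, self.REF_OUT,
                                self.REF_RISK, m=2, d_index=3)

    def test_grid_matches_per_row_computation(self):
        """The vectorized all-(m,d) builder agrees with the single-row path."""
        rng = np.random.default_rng(3)
        X = rng.random((12, 3))
        out = rng.random(12)
        risk = (rng.random(12) < 0.3).astype(float)
        tables = derivative_grid(X, out, risk, m_range=(2, 3))
        for (m, d), table in tables.items():
            for i in range(12):
                keep = np.arange(12) != i
                f = derivative_features(X[i], out[i], X[keep], out[keep],
                                        risk[keep], m=m, d_index=d)
                assert np.allclose(table[i], f.as_array())

    def test_grid_size_is_sum_of_m(self):
        rng = np.random.default_rng(0)
        X = rng.random((30, 2))
        tables = derivative_grid(X, rng.random(30), np.zeros(30),
                                 m_range=range(2, 11))
        assert len(tables) == sum(range(2, 11))  # 54 candidates

    def test_focal_label_never_used(self):
        """No label leakage: flipping a focal row's risk label leaves her own
        derivative features unchanged (only neighbours' labels enter)."""
        rng = np.random.default_rng(4)
        X = rng.random((15, 3))
        out = rng.random(15)
        risk = np.zeros(15)
        t1 = derivative_grid(X, out, risk, m_range=(3,))[(3, 1)]
        risk2 = risk.copy()
        risk2[0] = 1.0
        t2 = derivative_grid(X, out, risk2, m_range=(3,))[(3, 1)]
        assert np.allclose(t1[0], t2[0])
        assert not np.allclose(t1, t2)  # but her neighbours do see the flip


class TestTrainedModel:
    def test_selected_hyperparameters_within_range(self, trained_dann):
        model, diag = trained_dann
        assert 2 <= model.m <= 10
        assert 1 <= model.d_index <= model.m
        assert len(diag.grid) == sum(range(2, 11))

    def test_internal_scoring_idempotent(self, trained_dann):
        model, _ = trained_dann
        s1, s2 = model.score_internal(), model.score_internal()
        assert np.array_equal(s1, s2)

    def test_scores_in_unit_interval(self, trained_dann):
        model, _ = trained_dann
        s = model.score_internal()
        assert s.min() >= 0.0 and s.max() <= 1.0

    def test_training_is_deterministic(self, harbin_like, trained_dann):
        model, diag = trained_dann
        model2, diag2 = train_dann(harbin_like, MODEL_FEATURES, seed=1)
        assert (model2.m, model2.d_index) == (model.m, model.d_index)
        assert np.allclose(model2.score_internal(), model.score_internal())
        assert diag2.rho_full == diag.rho_full

    def test_dann_output_tracks_bmd_better_than_marker(self, harbin_like,
                                                       trained_dann):
        model, diag = trained_dann
        rho_marker = abs(stats.spearmanr(harbin_like.df["mir194"],
                                         harbin_like.bmd).statistic)
        assert diag.rho_full > rho_marker

    def test_external_scoring(self, trained_dann, external_like):
        model, _ = trained_dann
        scores = model.score_external(external_like)
        assert len(scores) == len(external_like)
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_serialization_round_trip(self, trained_dann, external_like):
        model, _ = trained_dann
        again = DANNModel.from_dict(model.to_dict())
        assert np.allclose(again.score_external(external_like),
                           model.score_external(external_like))
        assert np.allclose(again.score_internal(), model.score_internal())

    def test_classify_orientation(self, trained_dann):
        model, _ = trained_dann
        calls = model.classify(np.array([0.1, 0.9]))
        assert list(calls) == [1, 0]  # low score (low BMD) = osteoporosis call
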