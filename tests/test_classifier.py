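"""Normalization, sigmoid-network forward pass and LM training."""

import numpy as np
import pytest

from hybridbci import classifier as clf
from hybridbci.classifier import (ANNModel, LabelledDataset, NormalizationParams,
                                  TrainingConfig)


def sigmoid(a):
    return 1.0 / (1.0 + np.exp(-a))


def separable_dataset(rng, n_features=54, n_per_class=50, spread=0.05):
    """Two well-separated Gaussian clusters: linearly separable by design."""
    centers = np.zeros((2, n_features))
    centers[0, :10] = 1.0
    centers[1, 10:20] = 1.0
    X = np.vstack([c + spread * rng.standard_normal((n_per_class, n_features))
                   for c in centers])
    y = np.array(["A"] * n_per_class + ["B"] * n_per_class)
    return LabelledDataset(X, y)


class TestNormalization:
    def test_min_max_fitted_per_feature(self):
        params = clf.fit_normalization(np.array([[2.0], [4.0], [6.0]]))
        assert params.x_min[0] == 2 and params.x_max[0] == 6

    def test_endpoints_map_to_zero_and_one(self):
        params = NormalizationParams(np.array([2.0]), np.array([6.0]))
        assert clf.apply_normalization(np.array([[2.0]]), params)[0, 0] == 0
        assert clf.apply_normalization(np.array([[6.0]]), params)[0, 0] == 1

    def test_interior_value_scales_linearly(self):
        params = NormalizationParams(np.array([2.0]), np.array([6.0]))
        assert clf.apply_normalization(np.array([[5.0]]), params)[0, 0] \
            == pytest.approx(0.75)

    def test_out_of_range_values_clip(self):
        params = NormalizationParams(np.array([2.0]), np.array([6.0]))
        out = clf.apply_normalization(np.array([[0.0], [9.0]]), params)
        assert out[0, 0] == 0 and out[1, 0] == 1

    def test_constant_feature_maps_to_half(self):
        params = NormalizationParams(np.array([3.0]), np.array([3.0]))
        assert clf.apply_normalization(np.array([[3.0]]), params)[0, 0] == 0.5

    def test_training_rows_land_in_unit_interval(self, rng):
        X = rng.random((20, 5)) * 100 - 50
        params = clf.fit_normalization(X)
        out = clf.apply_normalization(X, params)
        assert out.min() >= 0 and out.max() <= 1

    def test_dimension_mismatch_rejected(self):
        params = NormalizationParams(np.zeros(3), np.ones(3))
        with pytest.raises(ValueError, match="dimension"):
            clf.apply_normalization(np.zeros((2, 4)), params)


class TestForward:
    @staticmethod
    def zero_model(n=3, m=2, k=2):
        return ANNModel(np.zeros((m, n)), np.zeros(m), np.zeros((k, m)),
                        np.zeros(k), NormalizationParams(np.zeros(n), np.ones(n)),
                        [f"c{i}" for i in range(k)])

    def test_all_zero_weights_output_half(self):
        z = clf.forward(self.zero_model(), np.array([0.3, 0.4, 0.5]))
        assert np.allclose(z, 0.5)

    def test_large_output_bias_saturates_toward_one(self):
        model = self.zero_model()
        model.b_out = np.array([50.0, -50.0])
        z = clf.forward(model, np.zeros(3))
        assert z[0] > 1 - 1e-12 and z[1] < 1e-12

    def test_matches_hand_computed_nested_sigmoid(self):
        # n=2, m=2, k=1 scalar evaluation
        W1 = np.array([[0.3, -0.2], [0.1, 0.4]])
        b1 = np.array([0.05, -0.1])
        W2 = np.array([[0.7, -0.5]])
        b2 = np.array([0.2])
        x = np.array([0.6, 0.9])
        model = ANNModel(W1, b1, W2, b2,
                         NormalizationParams(np.zeros(2), np.ones(2)), ["c"])
        y0 = sigmoid(0.3 * 0.6 + (-0.2) * 0.9 + 0.05)
        y1 = sigmoid(0.1 * 0.6 + 0.4 * 0.9 - 0.1)
        expected = sigmoid(0.7 * y0 - 0.5 * y1 + 0.2)
        assert clf.forward(model, x)[0] == pytest.approx(expected, abs=1e-12)

    def test_outputs_bounded_in_open_unit_interval(self, rng):
        model = ANNModel(rng.standard_normal((4, 6)), rng.standard_normal(4),
                         rng.standard_normal((3, 4)), rng.standard_normal(3),
                         NormalizationParams(np.zeros(6), np.ones(6)),
                         ["a", "b", "c"])
        for _ in range(20):
            z = clf.forward(model, rng.standard_normal(6) * 100)
            assert np.all(z > 0) and np.all(z < 1)

    def test_non_finite_weights_rejected(self):
        model = self.zero_model()
        model.W_out = model.W_out + np.nan
        with pytest.raises(ValueError, match="non-finite"):
            clf.forward(model, np.zeros(3))


class TestPredict:
    def test_argmax_class_returned(self):
        model = TestForward.zero_model(n=2, m=2, k=3)
        model.b_out = np.array([0.0, 2.0, -1.0])
        assert clf.predict_class(model, np.array([0.5, 0.5])) == "c1"

    def test_ties_break_to_lowest_index(self):
        model = TestForward.zero_model(n=2, m=2, k=3)
        # all-zero weights: every output is exactly 0.5
        assert clf.predict_class(model, np.array([0.1, 0.2])) == "c0"


class TestEarlyStopRule:
    def test_three_consecutive_rises_stop_at_epoch_six(self):
        stop, best = clf.early_stop_epoch([.5, .4, .3, .31, .32, .33, .2],
                                          patience=3)
        assert (stop, best) == (6, 3)

    def test_no_rise_runs_to_completion(self):
        stop, best = clf.early_stop_epoch([.5, .4, .3], patience=3)
        assert (stop, best) == (3, 3)

    def test_interrupted_rise_resets_the_counter(self):
        stop, best = clf.early_stop_epoch([.5, .51, .52, .4, .41, .42, .43],
                                          patience=3)
        assert (stop, best) == (7, 4)


class TestTrainLM:
    def test_separable_two_class_data_reaches_full_accuracy(self, rng):
        ds = separable_dataset(rng)
        tr, va, te = clf.split_dataset(ds, seed=0)
        model, hist = clf.train_lm(tr, va, TrainingConfig(seed=0, max_epochs=30),
                                   m=4)
        assert clf.evaluate_accuracy(model, te) == 1.0
        # independent oracle: a plain linear classifier confirms the set is
        # linearly separable, so 100% is the right target, not luck
        from sklearn.linear_model import LogisticRegression
        lin = LogisticRegression(max_iter=1000).fit(tr.features, tr.labels)
        assert lin.score(te.features, te.labels) == 1.0

    def test_training_mse_non_increasing_over_accepted_steps(self, rng):
        ds = separable_dataset(rng, spread=0.3)
        tr, va, _ = clf.split_dataset(ds, seed=1)
        _, hist = clf.train_lm(tr, va, TrainingConfig(seed=1, max_epochs=20), m=4)
        assert all(b <= a + 1e-12 for a, b in zip(hist.train_mse,
                                                  hist.train_mse[1:]))

    def test_returned_weights_are_best_validation_epoch(self, rng):
        ds = separable_dataset(rng, spread=0.4)
        tr, va, _ = clf.split_dataset(ds, seed=2)
        model, hist = clf.train_lm(tr, va, TrainingConfig(seed=2, max_epochs=25),
                                   m=4)
        norm = model.norm
        Xva = clf.apply_normalization(va.features, norm)
        mse = float(np.mean((clf.forward(model, Xva) - va.one_hot) ** 2))
        assert mse == pytest.approx(min(hist.val_mse), rel=1e-9)

    def test_trained_model_recovers_its_own_training_labels(self, rng):
        ds = separable_dataset(rng)
        tr, va, _ = clf.split_dataset(ds, seed=3)
        model, _ = clf.train_lm(tr, va, TrainingConfig(seed=3, max_epochs=30), m=4)
        pred = clf.predict_class(model, tr.features)
        assert np.mean(np.asarray(pred) == tr.labels) == 1.0

    def test_lm_step_approaches_gradient_direction_at_large_damping(self, rng):
        # (J'J + lam I)^-1 J'e -> J'e / lam as lam -> inf
        ds = separable_dataset(rng, n_per_class=10)
        norm = clf.fit_normalization(ds.features)
        X = clf.apply_normalization(ds.features, norm)
        T = ds.one_hot
        m, k = 3, 2
        rng2 = np.random.default_rng(0)
        n = X.shape[1]
        w = rng2.standard_normal(m * n + m + k * m + k) * 0.1
        lam = 1e8
        step = w - clf.lm_step(w, X, T, m, k, lam)
        Z, J = clf._forward_jacobian(w, X, m, k)
        grad = J.T @ (Z - T).ravel()
        cos = np.dot(step, grad) / (np.linalg.norm(step) * np.linalg.norm(grad))
        assert cos > 0.9999
        assert np.allclose(step, grad / lam, rtol=1e-3)

    def test_affine_rescaling_of_a_feature_column_is_absorbed(self, rng):
        # min-max scaling makes the pipeline invariant to x -> a*x + b per
        # training feature column (a > 0)
        ds = separable_dataset(rng, n_per_class=20)
        tr, va, te = clf.split_dataset(ds, seed=4)
        cfg = TrainingConfig(seed=4, max_epochs=15)
        model_a, _ = clf.train_lm(tr, va, cfg, m=3)
        scale, shift = 37.0, -11.0
        rescale = lambda d: LabelledDataset(  # noqa: E731
            d.features * scale + shift, d.labels, d.class_names)
        model_b, _ = clf.train_lm(rescale(tr), rescale(va), cfg, m=3)
        za = clf.forward(model_a, clf.apply_normalization(te.features, model_a.norm))
        zb = clf.forward(model_b, clf.apply_normalization(
            te.features * scale + shift, model_b.norm))
        assert np.allclose(za, zb, atol=1e-10)


class TestSelectArchitecture:
    def test_sweep_trains_requested_range_and_returns_min_val_mse(self, rng):
        ds = separable_dataset(rng)
        tr, va, _ = clf.split_dataset(ds, seed=5)
        cfg = TrainingConfig(seed=5, max_epochs=8, hidden_sweep=(4, 7))
        model, sweep = clf.select_architecture(tr, va, cfg)
        assert list(sweep["hidden"]) == [4, 5, 6, 7]
        assert model.meta["best_val_mse"] == sweep["validation_mse"].min()

    def test_identical_classes_give_chance_accuracy(self, rng):
        X = rng.random((80, 10))
        y = np.array(["A", "B"] * 40)   # labels carry no information
        ds = LabelledDataset(X, y)
        tr, va, te = clf.split_dataset(ds, seed=6)
        cfg = TrainingConfig(seed=6, max_epochs=6, hidden_sweep=(4, 5))
        model, _ = clf.select_architecture(tr, va, cfg)
        assert abs(clf.evaluate_accuracy(model, te) - 0.5) < 0.25


class TestSessionBlockedSplit:
    def test_splits_are_74_units_per_task(self, mental_frame):
        ds = LabelledDataset.from_frame(mental_frame)
        sessions = mental_frame["session"].to_numpy()
        tr, va, te = clf.split_dataset(ds, seed=0, sessions=sessions)
        for part in (tr, va, te):
            assert len(part.features) == 222    # 3 tasks x 74 windows
            for cls in ds.class_names:
                assert int(np.sum(part.labels == cls)) == 74

    def test_sessions_never_straddle_splits(self, mental_frame):
        # a whole session's windows overlap heavily; they must land in one
        # split only, otherwise test accuracy is inflated by leakage
        ds = LabelledDataset.from_frame(mental_frame)
        sessions = mental_frame["session"].to_numpy()
        splits = clf.split_dataset(ds, seed=0, sessions=sessions)
        row_of = {np.asarray(r).tobytes(): g
                  for g, part in enumerate(splits) for r in part.features}
        for (label, sess), grp in (
                mental_frame.groupby(["label", "session"]).groups.items()):
            assigned = {row_of[ds.features[i].tobytes()] for i in grp}
            assert len(assigned) == 1, f"{label}/{sess} spans splits {assigned}"


class TestSerialization:
    def test_model_round_trips_through_text_file(self, tmp_path, rng):
        ds = separable_dataset(rng, n_per_class=15)
        tr, va, _ = clf.split_dataset(ds, seed=7)
        model, _ = clf.train_lm(tr, va, TrainingConfig(seed=7, max_epochs=5), m=3)
        path = tmp_path / "model.json"
        clf.save_model(model, path)
        loaded = clf.load_model(path)
        x = rng.random(ds.features.shape[1])
        assert clf.predict_class(loaded, x) == clf.predict_class(model, x)
        assert np.array_equal(loaded.W_hidden, model.W_hidden)

    def test_foreign_file_rejected(self, tmp_path):
        path = tmp_path / "bogus.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="not a hybridbci"):
            clf.load_model(path)
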