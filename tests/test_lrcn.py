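"""Network shapes, two-stage training, the freeze invariant, estimators."""

import hashlib

import numpy as np
import pytest

from myonet import (LrcnConfig, MyoNetAngleRegressor,
                    MyoNetMovementClassifier, build_lrcn,
                    segments_to_arrays)


def _weights_hash(net, block="feature_extractor"):
    h = hashlib.sha256()
    for name in sorted(net.named_blocks()[block]):
        h.update(net.named_blocks()[block][name].tobytes())
    return h.hexdigest()


class TestArchitecture:
    def test_output_shapes_default(self, rng):
        net = build_lrcn(LrcnConfig(seed=0))
        X = rng.normal(size=(5, 256, 4)).astype(np.float32)
        feats = net.features(X)
        assert feats.shape == (5, 16, 20)  # stage-2 maps: 256/4/4 x 20
        net.training_stage = "angle_trained"
        angle = net.predict_angle(X)
        assert angle.shape == (5, 256)
        net.training_stage = "transfer_complete"
        proba = net.predict_proba(X)
        assert proba.shape == (5, 3)

    def test_stage_lengths_and_flatten(self):
        net = build_lrcn(LrcnConfig())
        assert net.map_lengths == (64, 16)
        assert net.flat_dim == 320  # 16 x 20

    @pytest.mark.parametrize("W", [128, 256, 512])
    def test_shape_contract_any_w_divisible_by_16(self, W, rng):
        """Under 'same' padding the pooling chain stays integral for any
        window divisible by 16."""
        net = build_lrcn(LrcnConfig(angle_out=W))
        X = rng.normal(size=(3, W, 4)).astype(np.float32)
        assert net.features(X).shape == (3, W // 16, 20)

    def test_valid_padding_incompatible_window(self):
        # 256 - 10 = 246 is not divisible by 4
        with pytest.raises(ValueError, match="pooling chain"):
            build_lrcn(LrcnConfig(padding="valid"))

    def test_same_seed_identical_init(self):
        a = build_lrcn(LrcnConfig(seed=3))
        b = build_lrcn(LrcnConfig(seed=3))
        assert _weights_hash(a) == _weights_hash(b)
        assert _weights_hash(a, "angle_head") == _weights_hash(b, "angle_head")

    def test_different_seed_different_init(self):
        a = build_lrcn(LrcnConfig(seed=3))
        b = build_lrcn(LrcnConfig(seed=4))
        assert _weights_hash(a) != _weights_hash(b)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            LrcnConfig(dropout=1.5)
        with pytest.raises(ValueError):
            LrcnConfig(stride=2)
        with pytest.raises(ValueError):
            LrcnConfig(n_filters=0)


class TestTraining:
    def test_loss_decreases(self, trained_network):
        losses = trained_network._test_angle_losses
        assert losses[-1] < losses[0]

    def test_zero_epochs_leaves_weights_unchanged(self, small_segments):
        from myonet import apply_normalizer, fit_normalizer

        segs = apply_normalizer(fit_normalizer(small_segments),
                                small_segments[:30])
        X, Y, _ = segments_to_arrays(segs)
        net = build_lrcn(LrcnConfig(epochs=0, seed=1))
        before = _weights_hash(net)
        before_angle = _weights_hash(net, "angle_head")
        net.fit_angle(X, Y)
        assert _weights_hash(net) == before
        assert _weights_hash(net, "angle_head") == before_angle
        assert net.training_stage == "angle_trained"

    def test_reproducible_training(self, small_segments):
        from myonet import apply_normalizer, fit_normalizer

        segs = apply_normalizer(fit_normalizer(small_segments),
                                small_segments[:40])
        X, Y, _ = segments_to_arrays(segs)
        runs = []
        for _ in range(2):
            net = build_lrcn(LrcnConfig(epochs=2, seed=5))
            losses = net.fit_angle(X, Y)
            runs.append((losses, _weights_hash(net)))
        assert runs[0][0] == runs[1][0]
        assert runs[0][1] == runs[1][1]

    def test_feature_extractor_frozen_through_transfer(self, small_segments):
        """The transfer step must leave extractor weights bit-identical."""
        from myonet import apply_normalizer, fit_normalizer

        segs = apply_normalizer(fit_normalizer(small_segments),
                                small_segments)
        X, Y, y = segments_to_arrays(segs)
        net = build_lrcn(LrcnConfig(epochs=2, seed=2))
        net.fit_angle(X, Y)
        before = _weights_hash(net)
        before_angle = _weights_hash(net, "angle_head")
        net.fit_classifier(X, y)
        assert _weights_hash(net) == before
        assert _weights_hash(net, "angle_head") == before_angle

    def test_transfer_requires_angle_training(self, rng):
        net = build_lrcn(LrcnConfig(epochs=1))
        X = rng.normal(size=(10, 256, 4)).astype(np.float32)
        with pytest.raises(RuntimeError, match="angle-trained"):
            net.fit_classifier(X, np.zeros(10, dtype=int))

    def test_classification_before_transfer_is_state_error(self, rng):
        net = build_lrcn(LrcnConfig(epochs=0))
        net.training_stage = "angle_trained"
        X = rng.normal(size=(4, 256, 4)).astype(np.float32)
        with pytest.raises(RuntimeError, match="transfer"):
            net.predict_proba(X)

    def test_prediction_before_training_is_state_error(self, rng):
        net = build_lrcn(LrcnConfig())
        X = rng.normal(size=(4, 256, 4)).astype(np.float32)
        with pytest.raises(RuntimeError):
            net.predict_angle(X)

    def test_empty_training_set_rejected(self):
        net = build_lrcn(LrcnConfig(epochs=1))
        with pytest.raises(ValueError):
            net.fit_angle(np.empty((0, 256, 4)), np.empty((0, 256)))

    def test_overfit_capacity_check(self, small_segments):
        """25 segments: loss falls below 10% of its initial value within
        200 epochs — the network has the capacity to fit its input.
        Capacity is measured with the regularizer (dropout) off, as usual
        for an overfit sanity check."""
        from myonet import apply_normalizer, fit_normalizer

        segs = apply_normalizer(fit_normalizer(small_segments),
                                small_segments[:25])
        X, Y, _ = segments_to_arrays(segs)
        net = build_lrcn(LrcnConfig(epochs=200, dropout=0.0, seed=0))
        losses = net.fit_angle(X, Y)
        assert min(losses) < 0.1 * losses[0]


class TestPrediction:
    def test_probability_rows_sum_to_one(self, trained_network):
        X, _, _ = trained_network._test_arrays
        proba = trained_network.predict_proba(X[:20])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(proba >= 0)

    def test_argmax_tie_break_lowest_index(self):
        assert int(np.argmax([0.1, 0.7, 0.2])) == 1
        assert int(np.argmax([0.4, 0.4, 0.2])) == 0

    def test_batch_order_preserved(self, trained_network):
        X, _, _ = trained_network._test_arrays
        full = trained_network.predict_angle(X[:16])
        flipped = trained_network.predict_angle(X[:16][::-1])
        np.testing.assert_allclose(full, flipped[::-1], rtol=1e-5, atol=1e-5)

    def test_permutation_equivariance_of_proba(self, trained_network):
        X, _, _ = trained_network._test_arrays
        perm = np.random.default_rng(0).permutation(16)
        p1 = trained_network.predict_proba(X[:16])[perm]
        p2 = trained_network.predict_proba(X[:16][perm])
        np.testing.assert_allclose(p1, p2, rtol=1e-6, atol=1e-7)

    def test_better_than_chance_classification(self, trained_network):
        X, _, y = trained_network._test_arrays
        acc = (trained_network.predict_proba(X).argmax(axis=1) == y).mean()
        assert acc > 1.0 / 3.0

    def test_finite_angle_predictions(self, trained_network):
        X, _, _ = trained_network._test_arrays
        pred = trained_network.predict_angle(X[:10])
        assert np.all(np.isfinite(pred))


class TestEstimators:
    def test_sklearn_params_roundtrip(self):
        reg = MyoNetAngleRegressor(epochs=5, seed=3)
        params = reg.get_params()
        assert params["epochs"] == 5
        reg.set_params(epochs=7)
        assert reg.epochs == 7

    def test_regressor_then_transfer_classifier(self, small_segments):
        from myonet import apply_normalizer, fit_normalizer
        from sklearn.base import clone

        segs = apply_normalizer(fit_normalizer(small_segments),
                                small_segments)
        X, Y, y = segments_to_arrays(segs)
        reg = MyoNetAngleRegressor(epochs=3, seed=0)
        assert clone(reg).get_params() == reg.get_params()
        reg.fit(X, Y)
        assert reg.network_.training_stage == "angle_trained"
        assert reg.predict(X[:4]).shape == (4, 256)
        clf = MyoNetMovementClassifier(source=reg, epochs=3, seed=0)
        clf.fit(X, y)
        assert clf.network_.training_stage == "transfer_complete"
        proba = clf.predict_proba(X[:6])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        assert clf.predict(X[:6]).shape == (6,)


class TestFunctionalSurface:
    def test_segment_list_training_and_prediction(self, small_segments):
        """The functional wrappers mirror the estimator path on Segment
        lists: angle-first training, transfer, then both prediction modes."""
        from myonet import (apply_normalizer, fit_normalizer, build_lrcn,
                            predict_angle, predict_movement,
                            train_angle_predictor, transfer_to_classifier)

        segs = apply_normalizer(fit_normalizer(small_segments),
                                small_segments)
        net = build_lrcn(LrcnConfig(epochs=2, seed=4))
        net = train_angle_predictor(net, segs)
        assert net.training_stage == "angle_trained"
        angles = predict_angle(net, segs[:5])
        assert angles.shape == (5, 256)
        assert np.all(np.isfinite(angles))
        net = transfer_to_classifier(net, segs)
        assert net.training_stage == "transfer_complete"
        labels, proba = predict_movement(net, segs[:5])
        assert labels.shape == (5,)
        assert proba.shape == (5, 3)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(labels, proba.argmax(axis=1))
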