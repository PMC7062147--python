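"""Windowing, SNR-targeted augmentation, folds, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myonet import (AugmentConfig, MovementClass, Recording, Segment,
                    SegmentNormalizer, augment_wgn, apply_normalizer,
                    empirical_snr, fit_normalizer, kfold_split,
                    segment_windows, solve_noise_power)


def _recording(n_samples, fs=1000.0, seed=0):
    rng = np.random.default_rng(seed)
    return Recording(emg=rng.normal(size=(n_samples, 4)),
                     angle=rng.uniform(0, 120, size=n_samples),
                     fs=fs, cls=MovementClass.WALKING, subject_id="t",
                     cohort="synthetic")


class TestSegmentation:
    def test_default_geometry_1000_samples(self):
        segs = segment_windows(_recording(1000))
        assert [s.origin[1] for s in segs] == [0, 192, 384, 576]
        assert all(s.x.shape == (256, 4) for s in segs)
        assert all(s.y_angle.shape == (256,) for s in segs)

    def test_too_short_recording_gives_empty_list(self):
        assert segment_windows(_recording(255)) == []

    def test_window_within_realtime_bound(self):
        # the default window must stay within the 300 ms real-time budget
        assert 256.0 <= 300.0
        segs = segment_windows(_recording(1000), window_ms=256.0)
        assert segs[0].x.shape[0] == 256

    def test_angle_alignment(self):
        rec = _recording(600)
        segs = segment_windows(rec)
        np.testing.assert_array_equal(segs[1].y_angle,
                                      rec.angle[192:192 + 256])

    def test_stride_override(self):
        segs = segment_windows(_recording(1000), stride_ms=64.0)
        assert [s.origin[1] for s in segs[:3]] == [0, 64, 128]

    @given(n=st.integers(min_value=0, max_value=5000))
    @settings(max_examples=60, deadline=None)
    def test_count_matches_enumeration_oracle(self, n):
        """Window count equals floor((n - W) / stride) + 1 for n >= W."""
        if n < 4:
            return
        rec = _recording(n, seed=1)
        segs = segment_windows(rec)
        W, stride = 256, 192
        expected = max(0, (n - W) // stride + 1) if n >= W else 0
        assert len(segs) == expected
        starts = [s.origin[1] for s in segs]
        assert starts == [i * stride for i in range(expected)]


class TestNoisePower:
    def test_linear_convention_direct(self):
        seg = Segment(x=np.full((256, 4), 5.0), y_angle=np.zeros(256),
                      y_class=0, origin=("t", 0))
        # signal power 25, linear SNR target 25 -> noise power 1
        p = solve_noise_power(seg, AugmentConfig(snr_target=25.0,
                                                 snr_convention="linear"))
        assert p == pytest.approx(1.0)

    def test_db_convention(self):
        seg = Segment(x=np.full((256, 4), 5.0), y_angle=np.zeros(256),
                      y_class=0, origin=("t", 0))
        p = solve_noise_power(seg, AugmentConfig(snr_target=25.0,
                                                 snr_convention="dB"))
        assert p == pytest.approx(25.0 / 10 ** 2.5)

    def test_noiseless_limit(self):
        seg = Segment(x=np.ones((16, 2)), y_angle=np.zeros(16),
                      y_class=0, origin=("t", 0))
        p = solve_noise_power(seg, AugmentConfig(snr_target=1e12,
                                                 snr_convention="linear"))
        assert p == pytest.approx(0.0, abs=1e-11)

    def test_all_zero_segment_rejected(self):
        seg = Segment(x=np.zeros((16, 2)), y_angle=np.zeros(16),
                      y_class=0, origin=("t", 0))
        with pytest.raises(ValueError):
            solve_noise_power(seg, AugmentConfig())


class TestAugmentation:
    def _segments(self, n=12):
        rng = np.random.default_rng(3)
        return [Segment(x=rng.normal(size=(256, 4)),
                        y_angle=rng.uniform(0, 120, 256),
                        y_class=MovementClass(i % 3), origin=("t", i))
                for i in range(n)]

    def test_factor_10_size(self):
        out = augment_wgn(self._segments(12), AugmentConfig())
        assert len(out) == 120

    def test_factor_1_identity(self):
        segs = self._segments(5)
        out = augment_wgn(segs, AugmentConfig(factor=1))
        assert len(out) == 5
        for a, b in zip(segs, out):
            assert np.array_equal(a.x, b.x)
            assert not b.is_virtual

    def test_labels_and_targets_inherited(self):
        segs = self._segments(6)
        out = augment_wgn(segs, AugmentConfig(factor=3, seed=1))
        originals = [s for s in out if not s.is_virtual]
        virtuals = [s for s in out if s.is_virtual]
        assert len(originals) == 6 and len(virtuals) == 12
        for v in virtuals:
            src = next(s for s in originals if s.origin == v.origin)
            np.testing.assert_array_equal(v.y_angle, src.y_angle)
            assert v.y_class == src.y_class
            assert not np.array_equal(v.x, src.x)

    def test_seeded_determinism(self):
        segs = self._segments(4)
        a = augment_wgn(segs, AugmentConfig(seed=9))
        b = augment_wgn(segs, AugmentConfig(seed=9))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.x, sb.x)

    def test_empirical_snr_hits_target(self):
        """Mean empirical SNR over >=100 virtual copies matches the 25 dB
        target within +/-5%."""
        segs = self._segments(15)
        cfg = AugmentConfig(seed=2)  # dB convention, factor 10
        out = augment_wgn(segs, cfg)
        virtuals = out[len(segs):]
        snrs = []
        for i, v in enumerate(virtuals):
            src = segs[i // (cfg.factor - 1)]
            snrs.append(empirical_snr(src.x, v.x, "dB"))
        assert len(snrs) >= 100
        assert np.mean(snrs) == pytest.approx(25.0, rel=0.05)

    def test_empirical_snr_linear_convention(self):
        segs = self._segments(15)
        cfg = AugmentConfig(snr_convention="linear", seed=2)
        out = augment_wgn(segs, cfg)
        snrs = [empirical_snr(segs[i // 9].x, v.x, "linear")
                for i, v in enumerate(out[len(segs):])]
        assert np.mean(snrs) == pytest.approx(25.0, rel=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            augment_wgn([], AugmentConfig())


class TestKFold:
    def test_nine_into_three(self):
        split = kfold_split(9, k=3, seed=0)
        folds = [set(split.test_indices(f)) for f in range(3)]
        assert all(len(f) == 3 for f in folds)
        assert set().union(*folds) == set(range(9))
        assert sum(len(f) for f in folds) == 9

    def test_partition_property(self):
        split = kfold_split(100, k=3, seed=4)
        seen = np.zeros(100, dtype=int)
        for f in range(3):
            te = split.test_indices(f)
            tr = split.train_indices(f)
            assert len(np.intersect1d(te, tr)) == 0
            assert len(te) + len(tr) == 100
            seen[te] += 1
        assert np.all(seen == 1)
        sizes = [len(split.test_indices(f)) for f in range(3)]
        assert max(sizes) - min(sizes) <= 1

    def test_too_few_segments(self):
        with pytest.raises(ValueError):
            kfold_split(2, k=3)


class TestNormalizer:
    def test_train_moments(self, rng):
        X = rng.normal(loc=3.0, scale=2.5, size=(40, 256, 4))
        norm = SegmentNormalizer().fit(X)
        Z = norm.transform(X)
        np.testing.assert_allclose(Z.mean(axis=(0, 1)), 0.0, atol=1e-6)
        np.testing.assert_allclose(Z.var(axis=(0, 1)), 1.0, atol=1e-3)

    def test_constant_channel_guarded(self, rng):
        X = rng.normal(size=(10, 64, 2))
        X[:, :, 1] = 5.0
        with pytest.warns(RuntimeWarning):
            norm = SegmentNormalizer().fit(X)
        Z = norm.transform(X)
        np.testing.assert_allclose(Z[:, :, 1], 0.0, atol=1e-9)
        assert np.all(np.isfinite(Z))

    def test_test_set_uses_train_statistics(self, rng):
        """Held-out data is transformed with training stats only (no leakage)."""
        Xtr = rng.normal(loc=0.0, size=(30, 64, 3))
        Xte = rng.normal(loc=4.0, size=(10, 64, 3))
        norm = SegmentNormalizer().fit(Xtr)
        Zte = norm.transform(Xte)
        # its own z-score would be ~0-mean; train-stat transform is not
        assert np.abs(Zte.mean()) > 1.0

    def test_segment_wrappers(self, small_segments):
        norm = fit_normalizer(small_segments)
        out = apply_normalizer(norm, small_segments)
        X = np.stack([s.x for s in out])
        np.testing.assert_allclose(X.mean(axis=(0, 1)), 0.0, atol=1e-9)
        np.testing.assert_allclose(X.std(axis=(0, 1)), 1.0, atol=1e-6)
        # labels and angles untouched
        for a, b in zip(small_segments, out):
            np.testing.assert_array_equal(a.y_angle, b.y_angle)
            assert a.y_class == b.y_class
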