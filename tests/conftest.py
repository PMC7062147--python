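import numpy as np
import pytest

from myonet import (MovementClass, SimConfig, gen_dataset, gen_recording,
                    segment_windows)


@pytest.fixture(scope="session")
def walking_recording():
    return gen_recording(MovementClass.WALKING, SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """One 10 s trial per class: 153 segments total."""
    return gen_dataset(1, SimConfig(duration_s=10.0, seed=11))


@pytest.fixture(scope="session")
def small_segments(small_dataset):
    segs = []
    for rec in small_dataset:
        segs.extend(segment_windows(rec))
    return segs


@pytest.fixture(scope="session")
def trained_network(small_segments):
    """A small but genuinely trained network shared across tests.

    10 epochs on one 10 s trial per class is enough for loss decrease,
    better-than-chance classification and state-machine checks without
    dominating the suite's runtime.
    """
    from myonet import (LrcnConfig, apply_normalizer, build_lrcn,
                        fit_normalizer, segments_to_arrays)

    norm = fit_normalizer(small_segments)
    segs = apply_normalizer(norm, small_segments)
    net = build_lrcn(LrcnConfig(epochs=10, seed=0))
    X, Y, y = segments_to_arrays(segs)
    angle_losses = net.fit_angle(X, Y)
    net._test_angle_losses = angle_losses
    net.fit_classifier(X, y)
    net._test_arrays = (X, Y, y)
    net._test_normalizer = norm
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
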