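"""Turn recordings into model-ready folds.

Windowing (256 ms windows with 64 ms overlap, i.e. a 192 ms stride at
1000 Hz), white-Gaussian-noise augmentation at a fixed signal-to-noise
ratio (``D_v = D_o + wgn(m, n, p)`` with the noise power ``p`` solved per
segment from the SNR target), z-score normalization estimated on the
training set only, and k-fold partitioning (default k = 3).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .dataio import Recording
from .movements import MovementClass

_STD_EPS = 1e-8


@dataclasses.dataclass
class Segment:
    """One fixed-length window: model input plus both targets.

    ``x`` is ``[W, n_channels]`` raw (or normalized) sEMG, ``y_angle`` the
    aligned angle trace in degrees, ``y_class`` the trial's movement label.
    ``origin`` records (subject_id, start_sample) in the source recording;
    windows are half-open ``[start, start + W)``.  ``is_virtual`` marks
    augmentation copies.
    """

    x: np.ndarray
    y_angle: np.ndarray
    y_class: MovementClass
    origin: tuple[str, int]
    is_virtual: bool = False

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y_angle = np.asarray(self.y_angle, dtype=float)
        if self.x.shape[0] != self.y_angle.shape[0]:
            raise ValueError("x and y_angle must share the window length")


@dataclasses.dataclass
class AugmentConfig:
    """Gaussian-noise augmentation settings.

    ``snr_target`` is 25 by default; since its unit is a convention,
    ``snr_convention`` selects dB (default) or a linear power ratio.
    ``factor`` is the total size multiple (10 means originals plus nine
    virtual copies each).
    """

    snr_target: float = 25.0
    snr_convention: str = "dB"
    factor: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.snr_target <= 0:
            raise ValueError("snr_target must be positive")
        if self.snr_convention not in ("linear", "dB"):
            raise ValueError("snr_convention must be 'linear' or 'dB'")
        if self.factor < 1:
            raise ValueError("factor must be >= 1")


@dataclasses.dataclass
class FoldSplit:
    """Uniform random k-fold partition of segment indices."""

    k: int
    assignments: np.ndarray  # fold index per segment
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def segment_windows(rec: Recording, window_ms: float = 256.0,
                    overlap_ms: float = 64.0,
                    stride_ms: float | None = None) -> list[Segment]:
    """Slice a recording into overlapping windows.

    Default geometry: 256 ms windows overlapping by 64 ms, so the stride is
    ``window_ms - overlap_ms`` = 192 ms (``stride_ms`` overrides it).  A
    recording shorter than one window yields an empty list.
    """
    if window_ms <= 0 or overlap_ms <= 0:
        raise ValueError("window_ms and overlap_ms must be positive")
    if stride_ms is None:
        if overlap_ms >= window_ms:
            raise ValueError("overlap_ms must be smaller than window_ms")
        stride_ms = window_ms - overlap_ms
    if stride_ms <= 0:
        raise ValueError("stride must be positive")
    W = int(round(window_ms * rec.fs / 1000.0))
    stride = int(round(stride_ms * rec.fs / 1000.0))
    out = []
    s = 0
    while s + W <= rec.n_samples:
        out.append(Segment(
            x=rec.emg[s:s + W].copy(),
            y_angle=rec.angle[s:s + W].copy(),
            y_class=rec.cls,
            origin=(rec.subject_id, s),
        ))
        s += stride
    return out


def solve_noise_power(seg: Segment | np.ndarray,
                      cfg: AugmentConfig | None = None) -> float:
    """Noise power ``p`` that makes the augmented segment hit the SNR target.

    With signal power ``P_s`` (mean square of the window):
    linear convention ``p = P_s / snr_target``; dB convention
    ``p = P_s / 10**(snr_target / 10)``.
    """
    cfg = cfg or AugmentConfig()
    x = seg.x if isinstance(seg, Segment) else np.asarray(seg, dtype=float)
    p_s = float(np.mean(x * x))
    if p_s == 0.0:
        raise ValueError("all-zero segment: signal power is zero")
    if cfg.snr_convention == "linear":
        return p_s / cfg.snr_target
    return p_s / 10.0 ** (cfg.snr_target / 10.0)


def empirical_snr(original: np.ndarray, virtual: np.ndarray,
                  convention: str = "dB") -> float:
    """Estimate the SNR of a virtual copy: power(D_o) / power(D_v - D_o)."""
    noise = np.asarray(virtual, dtype=float) - np.asarray(original, dtype=float)
    ratio = float(np.mean(original ** 2) / np.mean(noise ** 2))
    if convention == "dB":
        return 10.0 * np.log10(ratio)
    return ratio


def augment_wgn(segments: list[Segment],
                cfg: AugmentConfig | None = None) -> list[Segment]:
    """White-Gaussian-noise augmentation: ``factor`` × more segments.

    Output comprises the originals followed by ``factor - 1`` virtual copies
    per original, each the original plus fresh i.i.d. Gaussian noise whose
    power is solved per segment from the SNR target.  Labels and angle
    targets are inherited unchanged; virtual copies carry ``is_virtual``.
    """
    if not segments:
        raise ValueError("augment_wgn needs a non-empty segment list")
    cfg = cfg or AugmentConfig()
    rng = np.random.default_rng(cfg.seed)
    out = list(segments)
    for seg in segments:
        p = solve_noise_power(seg, cfg)
        sigma = np.sqrt(p)
        for _ in range(cfg.factor - 1):
            noise = rng.normal(0.0, sigma, size=seg.x.shape)
            out.append(Segment(
                x=seg.x + noise,
                y_angle=seg.y_angle.copy(),
                y_class=seg.y_class,
                origin=seg.origin,
                is_virtual=True,
            ))
    return out


def kfold_split(n_segments: int, k: int = 3, seed: int = 0) -> FoldSplit:
    """Uniform random partition into k folds with sizes differing by <= 1."""
    if n_segments < k:
        raise ValueError(f"cannot split {n_segments} segments into {k} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_segments)
    assignments = np.empty(n_segments, dtype=int)
    assignments[perm] = np.arange(n_segments) % k
    return FoldSplit(k=k, assignments=assignments, seed=seed)


class SegmentNormalizer(BaseEstimator, TransformerMixin):
    """Per-channel z-score normalizer fitted on training segments only.

    Holding the training-set statistics fixed when transforming held-out
    data is what prevents test-set leakage.  A zero-variance channel is
    guarded with a small epsilon and a warning.
    """

    def __init__(self, eps: float = _STD_EPS):
        self.eps = eps

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)          # [n, W, C]
        if X.ndim != 3 or X.shape[0] == 0:
            raise ValueError("expected a non-empty [n, W, C] array")
        self.mean_ = X.mean(axis=(0, 1))
        std = X.std(axis=(0, 1))
        if np.any(std < self.eps):
            warnings.warn("zero-variance channel guarded with eps",
                          RuntimeWarning, stacklevel=2)
        self.scale_ = np.maximum(std, self.eps)
        self.n_features_in_ = X.shape[2]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) / self.scale_


# -- Segment-list convenience wrappers ------------------------------------

def segments_to_arrays(segments: list[Segment]):
    """Stack segments into ``(X [n,W,C], Y_angle [n,W], y_class [n])``."""
    X = np.stack([s.x for s in segments]).astype(np.float32)
    Y = np.stack([s.y_angle for s in segments]).astype(np.float32)
    y = np.array([int(s.y_class) for s in segments], dtype=int)
    return X, Y, y


def fit_normalizer(train_segments: list[Segment]) -> SegmentNormalizer:
    if not train_segments:
        raise ValueError("cannot fit a normalizer on an empty training set")
    X = np.stack([s.x for s in train_segments])
    return SegmentNormalizer().fit(X)


def apply_normalizer(norm: SegmentNormalizer,
                     segments: list[Segment]) -> list[Segment]:
    out = []
    for s in segments:
        out.append(Segment(
            x=norm.transform(s.x[None])[0],
            y_angle=s.y_angle.copy(),
            y_class=s.y_class,
            origin=s.origin,
            is_virtual=s.is_virtual,
        ))
    return out
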