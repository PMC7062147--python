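"""Empirical Iterative Algorithm: extrema-midpoint spline smoothing.

A data-driven iterative low-pass filter in the spirit of empirical mode
decomposition's envelope step: per iteration, locate all interior local
maxima and minima, take the midpoint of every consecutive pair of extrema
(in time and in value), anchor the signal's first and last samples, and
replace the signal by the natural cubic spline through those knots
evaluated on the original sample grid.  Two iterations are the default.
A pass needs at least two maxima and two minima to define an oscillatory
component worth stripping (the same degeneracy rule envelope-based sifting
uses); constants, monotone ramps and already-smooth trends therefore pass
through unchanged, which makes the algorithm safe on short windows and
idempotent once converged.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator, TransformerMixin


@dataclasses.dataclass
class EiaConfig:
    iterations: int = 2

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


@dataclasses.dataclass
class EiaResult:
    """Smoothed signal plus per-iteration intermediates for inspection."""

    smoothed: np.ndarray
    intermediates: list[np.ndarray]
    extrema_counts: list[tuple[int, int]]  # (n_maxima, n_minima) per iteration


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    A plateau (run of equal values) higher than both neighbours counts as a
    single maximum at its central index (ties broken to the left); likewise
    for minima.  Endpoints are never extrema.  Signals shorter than 3
    samples have none.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 3:
        return np.array([], dtype=int), np.array([], dtype=int)
    # run-length compress equal neighbours, then compare run values
    change = np.flatnonzero(np.diff(x) != 0.0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [n - 1]])
    vals = x[starts]
    maxima, minima = [], []
    for j in range(1, len(starts) - 1):
        center = (starts[j] + ends[j]) // 2
        if vals[j] > vals[j - 1] and vals[j] > vals[j + 1]:
            maxima.append(center)
        elif vals[j] < vals[j - 1] and vals[j] < vals[j + 1]:
            minima.append(center)
    return np.asarray(maxima, dtype=int), np.asarray(minima, dtype=int)


def _one_pass(x: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    maxima, minima = find_extrema(x)
    counts = (len(maxima), len(minima))
    # an oscillatory component to strip requires at least two extrema of
    # each kind (as in envelope-based sifting); otherwise the signal is
    # already a trend and the pass is an identity
    if len(maxima) < 2 or len(minima) < 2:
        return x.copy(), counts
    t_ext = np.sort(np.concatenate([maxima, minima]))
    v_ext = x[t_ext]
    # the pass removes a ripple riding on a trend; when a substantial share
    # of consecutive-extrema swings spans the signal's excursion, the
    # surviving extrema constitute the trend itself and flattening them
    # would destroy it -> identity
    span = float(x.max() - x.min())
    if span > 0:
        swings = np.abs(np.diff(v_ext))
        if np.mean(swings >= 0.5 * span) >= 0.25:
            return x.copy(), counts
    t_mid = (t_ext[:-1] + t_ext[1:]) / 2.0
    v_mid = (v_ext[:-1] + v_ext[1:]) / 2.0
    # anchor the boundary samples so the spline cannot blow up at the edges
    t_knots = np.concatenate([[0.0], t_mid, [float(x.shape[0] - 1)]])
    v_knots = np.concatenate([[x[0]], v_mid, [x[-1]]])
    spline = CubicSpline(t_knots, v_knots, bc_type="natural")
    return spline(np.arange(x.shape[0], dtype=float)), counts


def eia_smooth(x: np.ndarray, cfg: EiaConfig | None = None) -> EiaResult:
    """Run the configured number of smoothing iterations on one signal."""
    cfg = cfg or EiaConfig()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("eia_smooth expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains NaN or Inf")
    current = x.copy()
    intermediates: list[np.ndarray] = []
    counts: list[tuple[int, int]] = []
    for _ in range(cfg.iterations):
        current, c = _one_pass(current)
        intermediates.append(current.copy())
        counts.append(c)
    return EiaResult(smoothed=current, intermediates=intermediates,
                     extrema_counts=counts)


class EiaSmoother(BaseEstimator, TransformerMixin):
    """Stateless transformer wrapper around :func:`eia_smooth`.

    ``transform`` accepts a 1-D signal or a 2-D ``[n_signals, length]``
    stack and smooths each row independently.
    """

    def __init__(self, iterations: int = 2):
        self.iterations = iterations

    def fit(self, X, y=None):
        EiaConfig(iterations=self.iterations)  # validate
        return self

    def transform(self, X):
        cfg = EiaConfig(iterations=self.iterations)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            return eia_smooth(X, cfg).smoothed
        if X.ndim == 2:
            return np.stack([eia_smooth(row, cfg).smoothed for row in X])
        raise ValueError("expected a 1-D signal or [n_signals, length] stack")
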