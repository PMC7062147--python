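"""The three-block LRCN: feature extractor, angle head, classification head.

Architecture (window W = 256 samples, 4 channels):

* **feature_extractor** — four parallel per-channel stages, each a 1-D
  convolution (20 filters, kernel 11, stride 1, 'same' padding), ReLU,
  4-to-1 max-pooling and 0.5 dropout; the four 20-map outputs are
  concatenated along the feature axis (80 maps, length W/4) and passed
  through one more conv/ReLU/pool/dropout stage, giving ``[W/16, 20]``
  feature maps (16 x 20 for W = 256).
* **angle_head** — two stacked LSTMs (32 then 64 units) run over the
  feature-map sequence; the second LSTM's full output sequence feeds a
  dense layer with linear activation producing one angle value per input
  sample (256 outputs for W = 256).
* **classification_head** — flatten (320 features for W = 256) and a dense
  softmax layer over the three movement classes.

Training is two-stage: the extractor and angle head are first optimized
end-to-end for angle regression (Adam, lr 0.001, batch 25); the extractor's
knowledge is then transferred — its weights frozen bit-exactly — and only
the softmax head is trained for movement classification.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import nn
from .movements import N_CLASSES
from .preprocess import Segment, segments_to_arrays

TRAINING_STAGES = ("untrained", "angle_trained", "transfer_complete")


@dataclasses.dataclass
class LrcnConfig:
    """Architecture and training hyperparameters.

    Defaults follow the reference operating point: 20 filters of size 11x1,
    stride 1, 4x1 max-pooling, dropout 0.5, LSTMs of 32 and 64 units, batch
    size 25, 70 epochs, Adam with learning rate 0.001.  ``angle_out`` must
    equal the window length W.
    """

    n_filters: int = 20
    kernel: int = 11
    stride: int = 1
    pool: int = 4
    dropout: float = 0.5
    lstm_units: tuple[int, int] = (32, 64)
    angle_out: int = 256
    n_classes: int = N_CLASSES
    n_channels: int = 4
    batch_size: int = 25
    epochs: int = 70
    optimizer: str = "adam"
    learning_rate: float = 0.001
    padding: str = "same"
    loss: str = "mse"
    seed: int = 0

    def __post_init__(self):
        if min(self.n_filters, self.kernel, self.pool, self.angle_out,
               self.n_classes, self.n_channels, self.batch_size) < 1:
            raise ValueError("all architecture counts must be positive")
        if self.stride != 1:
            raise ValueError("only stride 1 is supported")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        self.lstm_units = tuple(self.lstm_units)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lstm_units"] = list(self.lstm_units)
        return d


def _chain_lengths(W: int, cfg: LrcnConfig) -> tuple[int, int]:
    """Feature-map lengths after stage 1 and stage 2 (validates the chain)."""
    L = W
    for stage in (1, 2):
        if cfg.padding == "valid":
            L = L - cfg.kernel + 1
        if L <= 0 or L % cfg.pool:
            raise ValueError(
                f"window {W} incompatible with the pooling chain under "
                f"'{cfg.padding}' padding (stage {stage} length {L} not "
                f"divisible by {cfg.pool})"
            )
        L //= cfg.pool
        if stage == 1:
            L1 = L
    return L1, L


class _FeatureExtractor:
    def __init__(self, cfg: LrcnConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.branches = []
        for _ in range(cfg.n_channels):
            self.branches.append([
                nn.Conv1D(1, cfg.n_filters, cfg.kernel, cfg.padding, rng,
                          input_layer=True),
                nn.ReLU(),
                nn.MaxPool1D(cfg.pool),
                nn.Dropout(cfg.dropout, rng),
            ])
        self.stage2 = [
            nn.Conv1D(cfg.n_channels * cfg.n_filters, cfg.n_filters,
                      cfg.kernel, cfg.padding, rng),
            nn.ReLU(),
            nn.MaxPool1D(cfg.pool),
            nn.Dropout(cfg.dropout, rng),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        outs = []
        for c, branch in enumerate(self.branches):
            h = np.ascontiguousarray(x[:, :, c:c + 1])
            for layer in branch:
                h = layer.forward(h, train)
            outs.append(h)
        h = np.concatenate(outs, axis=2)
        for layer in self.stage2:
            h = layer.forward(h, train)
        return h

    def backward(self, dout: np.ndarray) -> None:
        for layer in reversed(self.stage2):
            dout = layer.backward(dout)
        F = self.cfg.n_filters
        for c, branch in enumerate(self.branches):
            d = dout[:, :, c * F:(c + 1) * F]
            for layer in reversed(branch):
                d = layer.backward(d)
                if d is None:
                    break

    def params(self) -> list[nn.Param]:
        ps = []
        for branch in self.branches:
            for layer in branch:
                ps.extend(layer.params())
        for layer in self.stage2:
            ps.extend(layer.params())
        return ps

    def named_params(self) -> dict[str, nn.Param]:
        out = {}
        for c, branch in enumerate(self.branches):
            for pname, p in branch[0].named_params().items():
                out[f"branch{c}_conv_{pname}"] = p
        for pname, p in self.stage2[0].named_params().items():
            out[f"stage2_conv_{pname}"] = p
        return out


class _AngleHead:
    """Two stacked LSTMs; the second's full output sequence feeds the dense
    angle layer (linear activation), so the temporal readout is not squeezed
    through a single final state."""

    def __init__(self, cfg: LrcnConfig, rng: np.random.Generator):
        u1, u2 = cfg.lstm_units
        _, L2 = _chain_lengths(cfg.angle_out, cfg)
        self.lstm1 = nn.LSTM(cfg.n_filters, u1, rng, return_sequences=True)
        self.lstm2 = nn.LSTM(u1, u2, rng, return_sequences=True)
        self.dense = nn.Dense(L2 * u2, cfg.angle_out, rng)

    def forward(self, feats: np.ndarray, train: bool) -> np.ndarray:
        h = self.lstm1.forward(feats, train)
        h = self.lstm2.forward(h, train)
        self._shape = h.shape
        return self.dense.forward(h.reshape(h.shape[0], -1), train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.dense.backward(dout)
        d = self.lstm2.backward(d.reshape(self._shape))
        return self.lstm1.backward(d)

    def params(self):
        return self.lstm1.params() + self.lstm2.params() + self.dense.params()

    def named_params(self):
        out = {}
        for tag, layer in (("lstm1", self.lstm1), ("lstm2", self.lstm2),
                           ("dense", self.dense)):
            for pname, p in layer.named_params().items():
                out[f"{tag}_{pname}"] = p
        return out


class _ClassificationHead:
    def __init__(self, cfg: LrcnConfig, flat_dim: int, rng: np.random.Generator):
        self.flat_dim = flat_dim
        self.dense = nn.Dense(flat_dim, cfg.n_classes, rng)

    def forward(self, feats: np.ndarray, train: bool) -> np.ndarray:
        self._shape = feats.shape
        flat = feats.reshape(feats.shape[0], -1)
        return self.dense.forward(flat, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.dense.backward(dout).reshape(self._shape)

    def params(self):
        return self.dense.params()

    def named_params(self):
        return {f"dense_{k}": p for k, p in self.dense.named_params().items()}


class LrcnNetwork:
    """The assembled network with its three named weight blocks."""

    def __init__(self, cfg: LrcnConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        L1, L2 = _chain_lengths(cfg.angle_out, cfg)
        self.map_lengths = (L1, L2)
        self.flat_dim = L2 * cfg.n_filters
        self.feature_extractor = _FeatureExtractor(cfg, rng)
        self.angle_head = _AngleHead(cfg, rng)
        self.classification_head = _ClassificationHead(cfg, self.flat_dim, rng)
        self.training_stage = "untrained"
        # angle-target standardization learned during angle training
        self.y_center = 0.0
        self.y_scale = 1.0

    # -- inference ---------------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=nn.DTYPE)
        if X.ndim != 3 or X.shape[1] != self.cfg.angle_out \
                or X.shape[2] != self.cfg.n_channels:
            raise ValueError(
                f"expected input [batch, {self.cfg.angle_out}, "
                f"{self.cfg.n_channels}], got {X.shape}"
            )
        return X

    def features(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """Inference-mode feature maps ``[n, W/16, n_filters]``."""
        X = self._check_input(X)
        outs = [self.feature_extractor.forward(X[i:i + batch], train=False)
                for i in range(0, X.shape[0], batch)]
        return np.concatenate(outs, axis=0)

    def predict_angle(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """Per-window angle sequences in degrees, ``[n, W]``."""
        if self.training_stage == "untrained":
            raise RuntimeError("angle prediction requires an angle-trained model")
        X = self._check_input(X)
        outs = []
        for i in range(0, X.shape[0], batch):
            f = self.feature_extractor.forward(X[i:i + batch], train=False)
            outs.append(self.angle_head.forward(f, train=False))
        pred = np.concatenate(outs, axis=0)
        return pred.astype(float) * self.y_scale + self.y_center

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """Softmax class probabilities, rows summing to one."""
        if self.training_stage != "transfer_complete":
            raise RuntimeError(
                "movement classification requires the transfer-learning step "
                f"(training_stage is '{self.training_stage}')"
            )
        feats = self.features(X, batch=batch)
        logits = self.classification_head.forward(feats, train=False)
        return nn.softmax(logits.astype(np.float64))

    # -- training ----------------------------------------------------------

    def fit_angle(self, X: np.ndarray, Y: np.ndarray,
                  log: list | None = None) -> list[float]:
        """End-to-end angle-regression training of extractor + angle head.

        Targets are z-scored internally (the scaling is stored on the model
        and inverted at prediction time).  Returns per-epoch mean losses on
        the standardized scale.
        """
        cfg = self.cfg
        X = self._check_input(X)
        Y = np.asarray(Y, dtype=nn.DTYPE)
        if Y.shape != (X.shape[0], cfg.angle_out):
            raise ValueError(f"angle targets must be [n, {cfg.angle_out}]")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if self.training_stage == "transfer_complete":
            raise RuntimeError("model already transfer-complete")
        self.y_center = float(Y.mean())
        self.y_scale = float(max(Y.std(), 1e-8))
        Yn = (Y - self.y_center) / self.y_scale
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        params = self.feature_extractor.params() + self.angle_head.params()
        opt = nn.Adam(params, lr=cfg.learning_rate)
        losses = []
        n = X.shape[0]
        for epoch in range(cfg.epochs):
            perm = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for i in range(0, n, cfg.batch_size):
                idx = perm[i:i + cfg.batch_size]
                opt.zero_grad()
                f = self.feature_extractor.forward(X[idx], train=True)
                pred = self.angle_head.forward(f, train=True)
                loss, grad = nn.regression_loss(pred, Yn[idx], cfg.loss)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite angle loss at epoch {epoch}: {loss}"
                    )
                dfeat = self.angle_head.backward(grad.astype(nn.DTYPE))
                self.feature_extractor.backward(dfeat)
                opt.step()
                epoch_loss += loss
                n_batches += 1
            losses.append(epoch_loss / max(n_batches, 1))
            if log is not None:
                log.append(f"epoch {epoch + 1}/{cfg.epochs} "
                           f"angle_loss {losses[-1]:.6f}")
        self.training_stage = "angle_trained"
        return losses

    def fit_classifier(self, X: np.ndarray, y: np.ndarray,
                       log: list | None = None) -> list[float]:
        """Transfer step: train only the softmax head on frozen features.

        The feature extractor is not touched (its weights stay bit-identical);
        features are computed once in inference mode and cached, which is the
        computational payoff of sharing the extractor between tasks.
        """
        if self.training_stage != "angle_trained":
            raise RuntimeError(
                "transfer learning requires an angle-trained model "
                f"(training_stage is '{self.training_stage}')"
            )
        cfg = self.cfg
        y = np.asarray(y, dtype=int)
        feats = self.features(X)
        if y.shape[0] != feats.shape[0] or y.shape[0] == 0:
            raise ValueError("labels must match a non-empty training set")
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        opt = nn.Adam(self.classification_head.params(), lr=cfg.learning_rate)
        losses = []
        n = feats.shape[0]
        for epoch in range(cfg.epochs):
            perm = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for i in range(0, n, cfg.batch_size):
                idx = perm[i:i + cfg.batch_size]
                opt.zero_grad()
                logits = self.classification_head.forward(feats[idx], train=True)
                loss, grad = nn.softmax_cross_entropy(logits, y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite classification loss at epoch {epoch}"
                    )
                self.classification_head.backward(grad.astype(nn.DTYPE))
                opt.step()
                epoch_loss += loss
                n_batches += 1
            losses.append(epoch_loss / max(n_batches, 1))
            if log is not None:
                log.append(f"epoch {epoch + 1} class_loss {losses[-1]:.6f}")
        self.training_stage = "transfer_complete"
        return losses

    # -- serialization helpers ---------------------------------------------

    def named_blocks(self) -> dict[str, dict[str, np.ndarray]]:
        return {
            "feature_extractor": {k: p.value for k, p in
                                  self.feature_extractor.named_params().items()},
            "angle_head": {k: p.value for k, p in
                           self.angle_head.named_params().items()},
            "classification_head": {k: p.value for k, p in
                                    self.classification_head.named_params().items()},
        }

    def set_block_weights(self, blocks: dict[str, dict[str, np.ndarray]]) -> None:
        owners = {
            "feature_extractor": self.feature_extractor,
            "angle_head": self.angle_head,
            "classification_head": self.classification_head,
        }
        for bname, params in blocks.items():
            if bname not in owners:
                raise ValueError(f"unknown weight block {bname!r}")
            named = owners[bname].named_params()
            for pname, arr in params.items():
                if pname not in named:
                    raise ValueError(f"unknown parameter {bname}/{pname}")
                if named[pname].value.shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for {bname}/{pname}: "
                        f"{named[pname].value.shape} vs {arr.shape}"
                    )
                named[pname].value[...] = arr

    def config_dict(self) -> dict:
        d = self.cfg.to_dict()
        d["_y_center"] = self.y_center
        d["_y_scale"] = self.y_scale
        return d


def build_lrcn(cfg: LrcnConfig | None = None) -> LrcnNetwork:
    """Build an untrained network (same config + seed => identical weights)."""
    return LrcnNetwork(cfg or LrcnConfig())


# -- scikit-learn estimator surface ----------------------------------------


class MyoNetAngleRegressor(BaseEstimator, RegressorMixin):
    """Angle-sequence regressor: sEMG windows in, angle sequences out.

    ``fit(X, Y)`` takes ``X [n, W, channels]`` and ``Y [n, W]`` (degrees) and
    trains the feature extractor and angle head end-to-end.  The fitted
    network is exposed as ``network_`` so a classifier can reuse (transfer)
    its feature extractor.
    """

    def __init__(self, n_filters=20, kernel=11, pool=4, dropout=0.5,
                 lstm_units=(32, 64), batch_size=25, epochs=70,
                 learning_rate=0.001, padding="same", loss="mse", seed=0):
        self.n_filters = n_filters
        self.kernel = kernel
        self.pool = pool
        self.dropout = dropout
        self.lstm_units = lstm_units
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.padding = padding
        self.loss = loss
        self.seed = seed

    def _config(self, W: int, C: int) -> LrcnConfig:
        return LrcnConfig(
            n_filters=self.n_filters, kernel=self.kernel, pool=self.pool,
            dropout=self.dropout, lstm_units=tuple(self.lstm_units),
            angle_out=W, n_channels=C, batch_size=self.batch_size,
            epochs=self.epochs, learning_rate=self.learning_rate,
            padding=self.padding, loss=self.loss, seed=self.seed,
        )

    def fit(self, X, Y):
        X = np.asarray(X)
        Y = np.asarray(Y)
        if X.ndim != 3:
            raise ValueError("X must be [n_segments, window, channels]")
        self.network_ = LrcnNetwork(self._config(X.shape[1], X.shape[2]))
        self.loss_history_ = self.network_.fit_angle(X, Y)
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def predict(self, X):
        return self.network_.predict_angle(np.asarray(X))

    def score(self, X, Y):
        """Mean per-window Pearson correlation with the true angle."""
        pred = self.predict(X)
        Y = np.asarray(Y, dtype=float)
        a = pred - pred.mean(axis=1, keepdims=True)
        b = Y - Y.mean(axis=1, keepdims=True)
        denom = np.sqrt((a * a).sum(axis=1) * (b * b).sum(axis=1))
        ok = denom > 0
        return float(((a * b).sum(axis=1)[ok] / denom[ok]).mean())


class MyoNetMovementClassifier(BaseEstimator, ClassifierMixin):
    """Movement classifier built by transfer from an angle-trained network.

    ``fit`` freezes the source network's feature extractor and trains only
    the softmax classification head.  Pass a fitted
    :class:`MyoNetAngleRegressor` (or a raw angle-trained network) as
    ``source``; alternatively leave ``source=None`` and the regressor is
    trained first on the angle targets supplied via ``fit``'s ``Y_angle``.
    """

    def __init__(self, source=None, epochs=70, batch_size=25,
                 learning_rate=0.001, seed=0):
        self.source = source
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def _resolve_network(self, X, Y_angle) -> LrcnNetwork:
        src = self.source
        if src is None:
            if Y_angle is None:
                raise ValueError(
                    "source=None requires Y_angle to train the angle stage"
                )
            reg = MyoNetAngleRegressor(
                epochs=self.epochs, batch_size=self.batch_size,
                learning_rate=self.learning_rate, seed=self.seed,
            ).fit(X, Y_angle)
            return reg.network_
        if isinstance(src, MyoNetAngleRegressor):
            return src.network_
        if isinstance(src, LrcnNetwork):
            return src
        raise TypeError("source must be a MyoNetAngleRegressor or LrcnNetwork")

    def fit(self, X, y, Y_angle=None):
        X = np.asarray(X)
        y = np.asarray(y, dtype=int)
        net = self._resolve_network(X, Y_angle)
        cfg = dataclasses.replace(
            net.cfg, epochs=self.epochs, batch_size=self.batch_size,
            learning_rate=self.learning_rate,
        )
        net.cfg = cfg
        self.loss_history_ = net.fit_classifier(X, y)
        self.network_ = net
        self.classes_ = np.arange(net.cfg.n_classes)
        return self

    def predict_proba(self, X):
        return self.network_.predict_proba(np.asarray(X))

    def predict(self, X):
        # np.argmax breaks ties toward the lowest index
        return self.predict_proba(X).argmax(axis=1)


# -- segment-list functional surface ---------------------------------------


def train_angle_predictor(model: LrcnNetwork, train_segments: list[Segment],
                          cfg: LrcnConfig | None = None) -> LrcnNetwork:
    """End-to-end angle training on a list of (normalized) segments."""
    if cfg is not None:
        model.cfg = cfg
    X, Y, _ = segments_to_arrays(train_segments)
    model.fit_angle(X, Y)
    return model


def transfer_to_classifier(model: LrcnNetwork, train_segments: list[Segment],
                           cfg: LrcnConfig | None = None) -> LrcnNetwork:
    """Freeze the extractor and train the classification head."""
    if cfg is not None:
        model.cfg = cfg
    X, _, y = segments_to_arrays(train_segments)
    model.fit_classifier(X, y)
    return model


def predict_angle(model: LrcnNetwork, segments: list[Segment]) -> np.ndarray:
    X, _, _ = segments_to_arrays(segments)
    return model.predict_angle(X)


def predict_movement(model: LrcnNetwork, segments: list[Segment]):
    """Return (labels, probability rows) for a list of segments."""
    X, _, _ = segments_to_arrays(segments)
    proba = model.predict_proba(X)
    return proba.argmax(axis=1), proba
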