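"""CNN + Bi-LSTM spectrogram classifier.

Architecture: repeated conv blocks (strided valid convolution -> batch norm
-> ReLU -> max pool -> dropout), reshaping the final feature maps into a
time sequence (image width = time, channels x height = per-step features),
a bidirectional LSTM whose directional outputs are combined by learned
per-unit weights, additive attention pooling over time, a fully connected
layer and a softmax head.  Training uses Adam and an imbalance-aware
focal-style cross-entropy (one-vs-rest over the softmax outputs).

Default hyperparameters: learning rate 1e-5, kernel 4, 128 filters, stride
2, 30 epochs, dropout 0.3, batch 64, 2x2 max pooling, 40 fully connected
nodes, 3 softmax nodes, 224x224 input.

Everything runs on NumPy; training is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from glucospec import nn
from glucospec.signals import ClassLabel

__all__ = ["ModelConfig", "TrainingHistory", "Network", "build_model", "SpectrogramClassifier"]


@dataclass
class ModelConfig:
    """Hyperparameters of the CNN + Bi-LSTM model."""

    learning_rate: float = 1e-5
    kernel: int = 4
    n_filters: int = 128
    stride: int = 2
    n_epochs: int = 30
    dropout: float = 0.3
    batch_size: int = 64
    optimizer: str = "adam"
    pool: int = 2
    fc_nodes: int = 40
    lstm_hidden: int = 64
    n_classes: int = 3
    n_conv_blocks: int = 2
    image_size: int = 224
    in_channels: int = 3
    use_attention: bool = True
    loss: str = "modified"  # "modified" (focal-style) or "cross_entropy"
    loss_t: float = 0.75
    loss_eta: float = 2.0
    bn_eps: float = 1e-5
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError(f"dropout must lie in [0, 1), got {self.dropout}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.n_classes < 2:
            raise ValueError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"only the Adam optimizer is supported, got {self.optimizer!r}")

    @property
    def out_nodes(self) -> int:
        return self.n_classes


@dataclass
class TrainingHistory:
    """Per-epoch training curves."""

    train_loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, len(self) + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        )


class Network:
    """The assembled layer stack with forward/backward passes."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.rng = rng
        c = config.in_channels
        h = w = config.image_size
        self.conv_stack: list[nn.Layer] = []
        for i in range(config.n_conv_blocks):
            conv = nn.Conv2D(c, config.n_filters, config.kernel, config.stride, rng=rng)
            ho, wo = conv.out_shape(h, w)
            if ho < 1 or wo < 1:
                raise ValueError(
                    f"conv block {i + 1}: kernel {config.kernel} / stride "
                    f"{config.stride} does not fit a {h}x{w} input"
                )
            self.conv_stack += [
                conv,
                nn.BatchNorm2D(config.n_filters, eps=config.bn_eps),
                nn.ReLULayer(),
                nn.MaxPool2D(config.pool),
                nn.Dropout(config.dropout, rng),
            ]
            h = -(-ho // config.pool)
            w = -(-wo // config.pool)
            c = config.n_filters
        self.seq_len = w
        self.seq_features = c * h
        self.bilstm = nn.BiLSTMLayer(self.seq_features, config.lstm_hidden, rng)
        self.pool_time = (
            nn.Attention(config.lstm_hidden, rng) if config.use_attention else nn.MeanPoolTime()
        )
        self.head_drop = nn.Dropout(config.dropout, rng)
        self.fc1 = nn.Dense(config.lstm_hidden, config.fc_nodes, rng)
        self.fc1_relu = nn.ReLULayer()
        self.fc2 = nn.Dense(config.fc_nodes, config.n_classes, rng)
        self._all_layers = self.conv_stack + [
            self.bilstm,
            self.pool_time,
            self.head_drop,
            self.fc1,
            self.fc1_relu,
            self.fc2,
        ]

    # -- forward ----------------------------------------------------------
    def _to_sequence(self, x: np.ndarray) -> np.ndarray:
        # [N, C, H, W] -> [T=W, N, C*H]: spectrogram width is time
        n, c, h, w = x.shape
        self._seq_shape = (n, c, h, w)
        return x.transpose(3, 0, 1, 2).reshape(w, n, c * h)

    def _from_sequence_grad(self, dseq: np.ndarray) -> np.ndarray:
        n, c, h, w = self._seq_shape
        return dseq.reshape(w, n, c, h).transpose(1, 2, 3, 0)

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Penultimate feature vector: the attention context, [N, lstm_hidden]."""
        for layer in self.conv_stack:
            x = layer.forward(x, train)
        seq = self._to_sequence(x)
        seq = self.bilstm.forward(seq, train)
        return self.pool_time.forward(seq, train)

    def head(self, ctx: np.ndarray, train: bool = False, feature_weights=None) -> np.ndarray:
        """Softmax head over (optionally re-weighted) penultimate features."""
        if feature_weights is not None:
            ctx = ctx * np.asarray(feature_weights)
        z = self.head_drop.forward(ctx, train)
        z = self.fc1_relu.forward(self.fc1.forward(z, train), train)
        return nn.softmax(self.fc2.forward(z, train), axis=1)

    def forward_probs(self, x: np.ndarray, train: bool = False, feature_weights=None) -> np.ndarray:
        return self.head(self.features(x, train), train, feature_weights)

    # -- backward ---------------------------------------------------------
    def train_step(self, x: np.ndarray, y_onehot: np.ndarray) -> float:
        probs = self.forward_probs(x, train=True)
        n = x.shape[0]
        cfg = self.config
        if cfg.loss == "modified":
            loss = nn.modified_ce_loss(probs, y_onehot, cfg.loss_t, cfg.loss_eta, reduce="none")
            loss = float(loss.sum(axis=1).mean())
            g = nn.modified_ce_loss_grad(probs, y_onehot, cfg.loss_t, cfg.loss_eta) / n
            dz = probs * (g - (g * probs).sum(axis=1, keepdims=True))
        elif cfg.loss == "cross_entropy":
            p = np.clip(probs, 1e-12, 1.0)
            loss = float(-(y_onehot * np.log(p)).sum(axis=1).mean())
            dz = (probs - y_onehot) / n
        else:
            raise ValueError(f"unknown loss {cfg.loss!r}")
        d = self.fc2.backward(dz)
        d = self.fc1.backward(self.fc1_relu.backward(d))
        d = self.head_drop.backward(d)
        d = self.pool_time.backward(d)
        d = self.bilstm.backward(d)
        d = self._from_sequence_grad(d)
        for layer in reversed(self.conv_stack):
            d = layer.backward(d)
        return loss

    def eval_loss(self, probs: np.ndarray, y_onehot: np.ndarray) -> float:
        cfg = self.config
        if cfg.loss == "modified":
            per = nn.modified_ce_loss(probs, y_onehot, cfg.loss_t, cfg.loss_eta, reduce="none")
            return float(per.sum(axis=1).mean())
        p = np.clip(probs, 1e-12, 1.0)
        return float(-(y_onehot * np.log(p)).sum(axis=1).mean())


def build_model(config: ModelConfig) -> Network:
    """Build a seeded, untrained network from a configuration."""
    return Network(config)


def _prepare_images(X) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim == 3:
        X = X[..., None]
    if X.ndim != 4:
        raise ValueError(f"expected images [N, H, W(, C)], got shape {X.shape}")
    x = X.astype(np.float64)
    if X.dtype == np.uint8 or x.max() > 1.5:
        x = x / 255.0
    return x.transpose(0, 3, 1, 2)  # channels first


class SpectrogramClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style estimator around the NumPy CNN + Bi-LSTM network.

    ``fit(X, y)`` takes image batches ``[N, H, W, C]`` (uint8 or floats) and
    labels (strings, ints or :class:`ClassLabel`).  An internal stratified
    validation split tracks per-epoch accuracy; the best-validation
    parameters are restored at the end of training.

    Examples
    --------
    >>> clf = SpectrogramClassifier(image_size=32, n_filters=8, n_epochs=2,
    ...                             lstm_hidden=8, learning_rate=1e-3, seed=0)
    >>> clf.fit(X_train, y_train).score(X_test, y_test)  # doctest: +SKIP
    """

    def __init__(
        self,
        learning_rate: float = 1e-5,
        kernel: int = 4,
        n_filters: int = 128,
        stride: int = 2,
        n_epochs: int = 30,
        dropout: float = 0.3,
        batch_size: int = 64,
        optimizer: str = "adam",
        pool: int = 2,
        fc_nodes: int = 40,
        lstm_hidden: int = 64,
        n_classes: int = 3,
        n_conv_blocks: int = 2,
        image_size: int = 224,
        in_channels: int = 3,
        use_attention: bool = True,
        loss: str = "modified",
        loss_t: float = 0.75,
        loss_eta: float = 2.0,
        bn_eps: float = 1e-5,
        val_fraction: float = 0.15,
        seed: int = 0,
    ):
        self.learning_rate = learning_rate
        self.kernel = kernel
        self.n_filters = n_filters
        self.stride = stride
        self.n_epochs = n_epochs
        self.dropout = dropout
        self.batch_size = batch_size
        self.optimizer = optimizer
        self.pool = pool
        self.fc_nodes = fc_nodes
        self.lstm_hidden = lstm_hidden
        self.n_classes = n_classes
        self.n_conv_blocks = n_conv_blocks
        self.image_size = image_size
        self.in_channels = in_channels
        self.use_attention = use_attention
        self.loss = loss
        self.loss_t = loss_t
        self.loss_eta = loss_eta
        self.bn_eps = bn_eps
        self.val_fraction = val_fraction
        self.seed = seed

    # ------------------------------------------------------------------
    def _make_config(self) -> ModelConfig:
        return ModelConfig(
            learning_rate=self.learning_rate,
            kernel=self.kernel,
            n_filters=self.n_filters,
            stride=self.stride,
            n_epochs=self.n_epochs,
            dropout=self.dropout,
            batch_size=self.batch_size,
            optimizer=self.optimizer,
            pool=self.pool,
            fc_nodes=self.fc_nodes,
            lstm_hidden=self.lstm_hidden,
            n_classes=self.n_classes,
            n_conv_blocks=self.n_conv_blocks,
            image_size=self.image_size,
            in_channels=self.in_channels,
            use_attention=self.use_attention,
            loss=self.loss,
            loss_t=self.loss_t,
            loss_eta=self.loss_eta,
            bn_eps=self.bn_eps,
            val_fraction=self.val_fraction,
            seed=self.seed,
        )

    def _encode_labels(self, y) -> np.ndarray:
        canonical = [ClassLabel.LOW, ClassLabel.NORMAL, ClassLabel.HIGH]
        try:
            labels = [ClassLabel.coerce(v) for v in y]
            present = [c for c in canonical if c in labels]
            self.classes_ = np.array([c.value for c in present], dtype=object)
            index = {c.value: i for i, c in enumerate(present)}
            return np.array([index[v.value] for v in labels])
        except (ValueError, KeyError):
            self.classes_ = np.unique(np.asarray(y))
            index = {v: i for i, v in enumerate(self.classes_)}
            return np.array([index[v] for v in np.asarray(y)])

    def fit(self, X, y):
        x = _prepare_images(X)
        cfg = self._make_config()
        if x.shape[2] != cfg.image_size or x.shape[3] != cfg.image_size:
            raise ValueError(
                f"images are {x.shape[2]}x{x.shape[3]} but image_size={cfg.image_size}"
            )
        if x.shape[1] != cfg.in_channels:
            cfg.in_channels = x.shape[1]
        yi = self._encode_labels(y)
        n_classes = len(self.classes_)
        if n_classes != cfg.n_classes:
            cfg.n_classes = n_classes
        if np.min(np.bincount(yi)) < 1:
            raise ValueError("every class needs at least one training sample")

        rng = np.random.default_rng(cfg.seed)
        net = Network(cfg)
        opt = nn.Adam(net._all_layers, lr=cfg.learning_rate)

        # stratified validation split
        n = len(yi)
        val_idx: list[int] = []
        if cfg.val_fraction > 0 and n >= 10:
            for c in range(n_classes):
                members = np.flatnonzero(yi == c)
                k = max(1, int(round(cfg.val_fraction * len(members))))
                if k < len(members):
                    val_idx.extend(rng.permutation(members)[:k])
        val_idx = np.array(sorted(val_idx), dtype=int)
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        if len(val_idx) == 0:
            val_idx = train_idx

        onehot = np.eye(n_classes)[yi]
        history = TrainingHistory()
        best = (-1.0, None)
        for _ in range(cfg.n_epochs):
            order = rng.permutation(train_idx)
            losses = []
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                if len(batch) < 2:
                    continue  # train-mode batch norm needs >= 2 samples
                losses.append(net.train_step(x[batch], onehot[batch]))
                opt.step()
            p_tr = self._batched_probs(net, x[train_idx])
            p_va = self._batched_probs(net, x[val_idx])
            tr_acc = float(np.mean(p_tr.argmax(axis=1) == yi[train_idx]))
            va_acc = float(np.mean(p_va.argmax(axis=1) == yi[val_idx]))
            history.train_loss.append(float(np.mean(losses)) if losses else float("nan"))
            history.train_acc.append(tr_acc)
            history.val_loss.append(net.eval_loss(p_va, onehot[val_idx]))
            history.val_acc.append(va_acc)
            if va_acc > best[0]:
                best = (va_acc, nn.snapshot_params(net._all_layers))
        if best[1] is not None:
            nn.restore_params(net._all_layers, best[1])
        self.network_ = net
        self.config_ = cfg
        self.history_ = history
        self.n_features_in_ = int(np.prod(x.shape[1:]))
        return self

    @staticmethod
    def _batched_probs(net: Network, x: np.ndarray, feature_weights=None, chunk: int = 128):
        parts = [
            net.forward_probs(x[i : i + chunk], train=False, feature_weights=feature_weights)
            for i in range(0, len(x), chunk)
        ]
        return np.vstack(parts)

    def _validated(self, X) -> np.ndarray:
        x = _prepare_images(X)
        size = self.config_.image_size
        if x.shape[2] != size or x.shape[3] != size:
            raise ValueError(
                f"images are {x.shape[2]}x{x.shape[3]} but the model's "
                f"image_size is {size}"
            )
        return x

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self._batched_probs(self.network_, self._validated(X))

    def predict(self, X):
        probs = self.predict_proba(X)
        return self.classes_[probs.argmax(axis=1)]

    def transform(self, X) -> np.ndarray:
        """Penultimate (attention-context) features, [N, lstm_hidden]."""
        self._check_fitted()
        x = self._validated(X)
        parts = [self.network_.features(x[i : i + 128]) for i in range(0, len(x), 128)]
        return np.vstack(parts)

    def predict_proba_weighted(self, X, feature_weights) -> np.ndarray:
        """Class probabilities with per-feature weights applied to the
        penultimate layer (the transparency hook of the feature-weighting
        scheme); weights of 1 reproduce :meth:`predict_proba` exactly."""
        self._check_fitted()
        return self._batched_probs(self.network_, self._validated(X), feature_weights)

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted; call fit first")

    # -- checkpointing --------------------------------------------------
    def save_checkpoint(self, directory) -> None:
        """Write a config snapshot (JSON), parameters (one .npy per named
        array) and the training history (CSV) to ``directory``."""
        self._check_fitted()
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config_)
        cfg["classes"] = list(self.classes_)
        (d / "config.json").write_text(json.dumps(cfg, indent=2))
        arrays = {}
        for i, layer in enumerate(nn._flatten_layers(self.network_._all_layers)):
            for name, arr in layer.params.items():
                arrays[f"layer{i:02d}_{name}"] = arr
            if isinstance(layer, nn.BatchNorm2D):
                arrays[f"layer{i:02d}_running_mean"] = layer.running_mean
                arrays[f"layer{i:02d}_running_var"] = layer.running_var
        np.savez(d / "parameters.npz", **arrays)
        self.history_.to_frame().to_csv(d / "history.csv", index=False)

    @classmethod
    def load_checkpoint(cls, directory) -> "SpectrogramClassifier":
        d = Path(directory)
        cfg = json.loads((d / "config.json").read_text())
        classes = cfg.pop("classes")
        config = ModelConfig(**cfg)
        est = cls(**{k: getattr(config, k) for k in cfg})
        net = Network(config)
        data = np.load(d / "parameters.npz")
        for i, layer in enumerate(nn._flatten_layers(net._all_layers)):
            for name in layer.params:
                layer.params[name] = data[f"layer{i:02d}_{name}"]
            if isinstance(layer, nn.BatchNorm2D):
                layer.running_mean = data[f"layer{i:02d}_running_mean"]
                layer.running_var = data[f"layer{i:02d}_running_var"]
        est.network_ = net
        est.config_ = config
        est.classes_ = np.array(classes, dtype=object)
        hist = pd.read_csv(d / "history.csv")
        est.history_ = TrainingHistory(
            train_loss=hist["train_loss"].tolist(),
            train_acc=hist["train_acc"].tolist(),
            val_loss=hist["val_loss"].tolist(),
            val_acc=hist["val_acc"].tolist(),
        )
        est.n_features_in_ = config.in_channels * config.image_size**2
        return est
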