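"""Convolutional residue-pair classifier (scikit-learn estimator API).

The network consumes 2 x 217 x 1 residue-pair blocks through three
convolution + max-pool stages (3x3/32, 3x3/64, 1x3/128 filters, stride 2), a
1024-unit softplus fully-connected layer with dropout, and a 2-way softmax.
A 3 x 3 kernel cannot traverse a height-2 input under a strict valid
convolution, so the default padding policy pads only an axis shorter than
the kernel up to the kernel size ("short-axis same"); pooling windows clip to
the available extent. The realised shape chain is recorded in
``layer_shapes_`` at fit time.

Training is plain Adam on softmax cross-entropy with an exponentially
decaying learning rate and dropout on the fully-connected layer, fully
seeded and reproducible.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .features import FEATURE_LENGTH

DEFAULT_CONV_SPECS = ((3, 3, 32), (3, 3, 64), (1, 3, 128))


class PairCNNClassifier(BaseEstimator, ClassifierMixin):
    """Small CNN over residue-pair feature blocks.

    Parameters
    ----------
    conv_specs : tuple of (kh, kw, depth)
        Kernel geometry and depth of each convolutional stage.
    conv_stride, pool_size, pool_stride : int
        Strides and pooling window (pooling clips on short axes).
    fc_units : int
        Width of the fully-connected softplus layer.
    dropout_rate : float
        Dropout on the fully-connected activations during training.
    learning_rate, lr_decay : float
        Adam base rate and per-epoch exponential decay factor.
    weight_decay : float
        Decoupled L2 weight decay on convolution/dense weights (not biases).
    batch_size, epochs : int
    random_state : int
        Seeds weight init, shuffling and dropout; identical inputs and seed
        give identical training logs.
    padding_policy : "short_axis_same" | "valid"
        How kernels larger than an input axis are accommodated.
    """

    def __init__(self, conv_specs=DEFAULT_CONV_SPECS, conv_stride=2, pool_size=2,
                 pool_stride=2, fc_units=1024, dropout_rate=0.5, learning_rate=1e-3,
                 lr_decay=0.96, batch_size=128, epochs=50, weight_decay=0.0,
                 random_state=0, padding_policy="short_axis_same"):
        self.conv_specs = conv_specs
        self.conv_stride = conv_stride
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.fc_units = fc_units
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.lr_decay = lr_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.weight_decay = weight_decay
        self.random_state = random_state
        self.padding_policy = padding_policy

    # ------------------------------------------------------------------
    def _coerce_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2 and X.shape[1] % FEATURE_LENGTH == 0:
            X = X.reshape(len(X), X.shape[1] // FEATURE_LENGTH, FEATURE_LENGTH, 1)
        elif X.ndim == 3:
            X = X[:, :, :, None]
        if X.ndim != 4:
            raise ValueError(f"expected pair blocks of shape (n, 2, {FEATURE_LENGTH}, 1), got {X.shape}")
        return X

    def _build(self, input_shape: tuple[int, int, int], rng: np.random.Generator) -> nn.Sequential:
        h, w, c = input_shape
        layers: list[nn.Layer] = []
        shapes = [("input", (h, w, c))]
        for k, (kh, kw, depth) in enumerate(self.conv_specs, start=1):
            conv = nn.Conv2D((kh, kw), c, depth, self.conv_stride, rng, self.padding_policy)
            try:
                h, w = conv.out_shape(h, w)
            except ValueError:
                h = w = 0
            if h < 1 or w < 1:
                raise ValueError(f"conv{k} ({kh}x{kw}) collapses the spatial extent "
                                 f"under padding policy {self.padding_policy!r}")
            c = depth
            layers += [conv, nn.Softplus()]
            shapes.append((f"conv{k}", (h, w, c)))
            pool = nn.MaxPool2D(self.pool_size, self.pool_stride)
            oh, ow = pool.out_shape(h, w)
            if (oh, ow) != (h, w):
                layers.append(pool)
                h, w = oh, ow
            shapes.append((f"pool{k}", (h, w, c)))
        layers.append(nn.Flatten())
        flat = h * w * c
        layers += [nn.Dense(flat, self.fc_units, rng), nn.Softplus(),
                   nn.Dropout(self.dropout_rate, rng),
                   nn.Dense(self.fc_units, 2, rng)]
        shapes += [("flatten", (flat,)), ("fc", (self.fc_units,)), ("logits", (2,))]
        self.layer_shapes_ = shapes
        return nn.Sequential(layers)

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = self._coerce_X(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("PairCNNClassifier is a binary classifier; need exactly 2 classes")
        yi = np.searchsorted(self.classes_, y)
        self.n_features_in_ = int(np.prod(X.shape[1:]))

        rng = np.random.default_rng(self.random_state)
        self.net_ = self._build(X.shape[1:], rng)
        opt = nn.Adam(self.net_.params, lr=self.learning_rate, weight_decay=self.weight_decay)
        n = len(X)
        bs = min(self.batch_size, n)
        self.training_log_ = []
        for epoch in range(self.epochs):
            lr = self.learning_rate * self.lr_decay ** epoch
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                logits = self.net_.forward(X[idx], train=True)
                loss, dz = nn.softmax_cross_entropy(logits, yi[idx])
                dz = dz.astype(np.float32)
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite training loss at epoch {epoch}: {loss}")
                self.net_.backward(dz)
                opt.step(self.net_.grads, lr=lr)
                losses.append(loss)
            self.training_log_.append(float(np.mean(losses)))
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = self._coerce_X(X)
        out = []
        for start in range(0, len(X), 1024):
            logits = self.net_.forward(X[start:start + 1024], train=False)
            out.append(np.exp(nn.log_softmax(logits)))
        return np.concatenate(out) if out else np.empty((0, 2))

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[proba.argmax(axis=1)]

    def decision_function(self, X) -> np.ndarray:
        """Probability of the positive (second) class."""
        return self.predict_proba(X)[:, 1]
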