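"""A compact NumPy convolutional network for small grayscale images.

Architecture (fixed apart from the tuned hyperparameters)::

    Conv(F, 3x3, same) -> ReLU -> MaxPool(2x2)
    Conv(2F, 3x3, same) -> ReLU -> MaxPool(2x2)
    Flatten -> Dense(128) -> ReLU -> Dropout(p) -> Dense(C) -> Softmax

with ``F`` the tuned base filter count (the second block doubles it), ``p``
the tuned dropout rate and ``C`` the number of classes.  Training minimizes
the multi-class cross-entropy with mini-batch Adam or SGD at the tuned
learning rate and batch size.  Everything is float32; convolutions are
computed as nine shifted matrix products (one per kernel tap), which maps the
work onto BLAS without materializing an im2col buffer.

:class:`CNNClassifier` wraps the network as a scikit-learn estimator
(``fit`` / ``predict`` / ``predict_proba``, ``get_params``/``set_params``,
fitted attributes with trailing underscores), so it composes with sklearn
model selection and pipelines.
"""

from __future__ import annotations

import math
from typing import Callable, Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["CNNClassifier", "build_cnn", "architecture_summary", "parameter_count"]


# --------------------------------------------------------------------------
# layers (NHWC, float32)
# --------------------------------------------------------------------------

class _Conv3x3:
    """3x3 convolution, stride 1, zero 'same' padding.

    Forward and backward are each a single large GEMM over an im2col matrix
    of shape ``(n*h*w, 9*c_in)``, which keeps the single-thread BLAS close to
    peak; the column matrix is cached during training for the weight-gradient
    product and folded back with nine strided adds for the input gradient.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 needs_input_grad: bool = True):
        scale = math.sqrt(2.0 / (9 * c_in))  # He initialization
        self.w = (rng.standard_normal((3, 3, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.needs_input_grad = needs_input_grad
        self._cols = None
        self._in_shape = None

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def params(self):
        return [self.w, self.b]

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xpad = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = np.empty((n, h, w, 9 * c), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                k = 3 * i + j
                cols[..., k * c:(k + 1) * c] = xpad[:, i:i + h, j:j + w, :]
        return cols.reshape(n * h * w, 9 * c)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        cols = self._im2col(x)
        out = cols @ self.w.reshape(9 * c, -1)
        out += self.b
        if train:
            self._cols, self._in_shape = cols, x.shape
        return out.reshape(n, h, w, -1)

    def backward(self, d: np.ndarray):
        n, h, w, c_out = d.shape
        c = self._in_shape[3]
        dmat = d.reshape(n * h * w, c_out)
        dw = (self._cols.T @ dmat).reshape(3, 3, c, c_out)
        db = dmat.sum(axis=0)
        self._cols = None
        if not self.needs_input_grad:
            return None, [dw, db]
        dcols = (dmat @ self.w.reshape(9 * c, c_out).T).reshape(n, h, w, 9 * c)
        dxpad = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
        for i in range(3):
            for j in range(3):
                k = 3 * i + j
                dxpad[:, i:i + h, j:j + w, :] += dcols[..., k * c:(k + 1) * c]
        return dxpad[:, 1:-1, 1:-1, :], [dw, db]


class _ReLU:
    def forward(self, x, train):
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, d):
        return d * self._mask


class _MaxPool2:
    """2x2 max pooling; the gradient is routed to the first maximal entry of
    each window (raster order), so tied maxima receive it exactly once."""

    @staticmethod
    def _quadrants(x):
        return (x[:, ::2, ::2, :], x[:, ::2, 1::2, :],
                x[:, 1::2, ::2, :], x[:, 1::2, 1::2, :])

    def forward(self, x, train):
        quads = self._quadrants(x)
        out = np.maximum(np.maximum(quads[0], quads[1]), np.maximum(quads[2], quads[3]))
        if train:
            self._x_shape = x.shape
            self._quads = quads
            self._out = out
        return out

    def backward(self, d):
        dx = np.zeros(self._x_shape, dtype=d.dtype)
        dquads = self._quadrants(dx)
        taken = np.zeros(self._out.shape, dtype=bool)
        for q, dq in zip(self._quads, dquads):
            hit = (q == self._out) & ~taken
            dq += d * hit
            taken |= hit
        self._quads = self._out = None
        return dx


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 scale: float | None = None):
        scale = math.sqrt(2.0 / n_in) if scale is None else scale
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    @property
    def n_params(self) -> int:
        return self.w.size + self.b.size

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, d):
        dw = self._x.T @ d
        db = d.sum(axis=0)
        dx = d @ self.w.T
        self._x = None
        return dx, [dw, db]


class _Dropout:
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, d):
        return d if self._mask is None else d * self._mask


def _clip_gradients(grads, max_norm: float):
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = 0.0
    for gs in grads:
        for g in gs:
            total += float(np.sum(np.square(g, dtype=np.float64)))
    norm = math.sqrt(total)
    if norm > max_norm:
        scale = np.float32(max_norm / (norm + 1e-12))
        for gs in grads:
            for g in gs:
                g *= scale
    return grads


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Network:
    """The two-conv-block network with explicit forward/backward."""

    def __init__(self, image_shape: tuple[int, int], base_filters: int,
                 dropout_rate: float, n_classes: int, rng: np.random.Generator,
                 dense_units: int = 128):
        h, w = image_shape
        if h % 4 or w % 4 or h < 8 or w < 8:
            raise ValueError("image sides must be multiples of 4 and >= 8")
        if base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        self.conv1 = _Conv3x3(1, base_filters, rng, needs_input_grad=False)
        self.relu1 = _ReLU()
        self.pool1 = _MaxPool2()
        self.conv2 = _Conv3x3(base_filters, 2 * base_filters, rng)
        self.relu2 = _ReLU()
        self.pool2 = _MaxPool2()
        self.flat_dim = (h // 4) * (w // 4) * 2 * base_filters
        self.dense1 = _Dense(self.flat_dim, dense_units, rng)
        self.relu3 = _ReLU()
        self.dropout = _Dropout(dropout_rate, rng)
        # small output-layer init keeps initial logits near zero (loss ~ ln C)
        self.dense2 = _Dense(dense_units, n_classes, rng, scale=0.01)
        self.image_shape = (h, w)

    def param_layers(self):
        return [self.conv1, self.conv2, self.dense1, self.dense2]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.param_layers())

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        """x: (n, h, w) in [0, 1]; returns class probabilities (n, C)."""
        a = x[..., None].astype(np.float32, copy=False)
        a = self.pool1.forward(self.relu1.forward(self.conv1.forward(a, train), train), train)
        a = self.pool2.forward(self.relu2.forward(self.conv2.forward(a, train), train), train)
        self._pooled_shape = a.shape
        a = a.reshape(a.shape[0], -1)
        a = self.relu3.forward(self.dense1.forward(a, train), train)
        a = self.dropout.forward(a, train)
        logits = self.dense2.forward(a, train)
        return _softmax(logits)

    def backward(self, probs: np.ndarray, onehot: np.ndarray):
        """Gradients of mean cross-entropy w.r.t. all parameters."""
        d = (probs - onehot).astype(np.float32) / probs.shape[0]
        d, g4 = self.dense2.backward(d)
        d = self.dropout.backward(d)
        d = self.relu3.backward(d)
        d, g3 = self.dense1.backward(d)
        d = d.reshape(self._pooled_shape)
        d = self.pool2.backward(d)
        d = self.relu2.backward(d)
        d, g2 = self.conv2.backward(d)
        d = self.pool1.backward(d)
        d = self.relu1.backward(d)
        _, g1 = self.conv1.backward(d)
        return [g1, g2, g3, g4]


class _SGD:
    def __init__(self, layers, lr: float):
        self.layers, self.lr = layers, lr

    def step(self, grads):
        for layer, gs in zip(self.layers, grads):
            for p, g in zip(layer.params(), gs):
                p -= self.lr * g


class _Adam:
    def __init__(self, layers, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers, self.lr = layers, lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for p in layer.params()] for layer in layers]
        self.v = [[np.zeros_like(p) for p in layer.params()] for layer in layers]

    def step(self, grads):
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for li, (layer, gs) in enumerate(zip(self.layers, grads)):
            for pi, (p, g) in enumerate(zip(layer.params(), gs)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= self.beta1
                m += (1.0 - self.beta1) * g
                v *= self.beta2
                v += (1.0 - self.beta2) * g * g
                p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


# --------------------------------------------------------------------------
# sklearn estimator
# --------------------------------------------------------------------------

class CNNClassifier(ClassifierMixin, BaseEstimator):
    """Two-conv-block CNN classifier with tunable training hyperparameters.

    Parameters
    ----------
    learning_rate, batch_size, base_filters, dropout, optimizer
        The tuned hyperparameters: step size, mini-batch size, filter count of
        the first conv block (the second uses twice as many), dropout rate on
        the hidden dense layer, and ``"adam"`` or ``"sgd"``.
    epochs
        Number of passes over the training set.
    augmenter
        Optional callable ``(image_2d, rng) -> image_2d`` applied to each
        training image on the fly (never at prediction time).
    random_state
        Seeds weight initialization, shuffling, dropout and augmentation.

    ``X`` may be ``(n, h, w)`` image stacks or flattened ``(n, h*w)`` rows of
    square images, intensities in [0, 1].
    """

    def __init__(self, learning_rate: float = 1e-3, batch_size: int = 32,
                 base_filters: int = 32, dropout: float = 0.5,
                 optimizer: str = "adam", epochs: int = 5,
                 dense_units: int = 128,
                 max_grad_norm: float = 5.0,
                 augmenter: Optional[Callable] = None,
                 random_state: Optional[int] = None):
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.base_filters = base_filters
        self.dropout = dropout
        self.optimizer = optimizer
        self.epochs = epochs
        self.dense_units = dense_units
        self.max_grad_norm = max_grad_norm
        self.augmenter = augmenter
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_images(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            side = int(round(math.sqrt(X.shape[1])))
            if side * side != X.shape[1]:
                raise ValueError("flattened inputs must be square images")
            X = X.reshape(X.shape[0], side, side)
        if X.ndim != 3:
            raise ValueError("X must be (n, h, w) images or (n, h*w) flattened rows")
        return X

    def _make_optimizer(self, layers):
        kind = str(self.optimizer).lower()
        if kind == "adam":
            return _Adam(layers, self.learning_rate)
        if kind == "sgd":
            return _SGD(layers, self.learning_rate)
        raise ValueError(f"unknown optimizer {self.optimizer!r}; expected 'adam' or 'sgd'")

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        X = self._as_images(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = self.classes_.size
        if n_classes < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.random_state)
        net = _Network(X.shape[1:], self.base_filters, self.dropout, n_classes,
                       rng, dense_units=self.dense_units)
        opt = self._make_optimizer(net.param_layers())
        eye = np.eye(n_classes, dtype=np.float32)
        n = X.shape[0]
        history = []
        for _ in range(int(self.epochs)):
            order = rng.permutation(n)
            epoch_loss, seen = 0.0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = X[idx]
                if self.augmenter is not None:
                    xb = np.stack([self.augmenter(im, rng) for im in xb]).astype(np.float32)
                yb = eye[y_idx[idx]]
                probs = net.forward(xb, train=True)
                p = np.clip(probs[np.arange(idx.size), y_idx[idx]], 1e-12, None)
                epoch_loss += float(-np.log(p).sum())
                seen += idx.size
                grads = net.backward(probs, yb)
                if self.max_grad_norm is not None:
                    _clip_gradients(grads, self.max_grad_norm)
                opt.step(grads)
            history.append(epoch_loss / max(seen, 1))
        self.network_ = net
        self.loss_history_ = history
        self.n_iter_ = int(self.epochs)
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        self.image_shape_ = X.shape[1:]
        return self

    def predict_proba(self, X, batch_size: int = 256) -> np.ndarray:
        check_is_fitted(self, "network_")
        X = self._as_images(X)
        if X.shape[1:] != self.image_shape_:
            raise ValueError(f"expected images of shape {self.image_shape_}, got {X.shape[1:]}")
        out = np.empty((X.shape[0], self.classes_.size), dtype=np.float32)
        for start in range(0, X.shape[0], batch_size):
            out[start:start + batch_size] = self.network_.forward(
                X[start:start + batch_size], train=False)
        return out

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    @property
    def n_parameters_(self) -> int:
        check_is_fitted(self, "network_")
        return self.network_.n_params


# --------------------------------------------------------------------------
# architecture inspection
# --------------------------------------------------------------------------

def build_cnn(config, image_size: int = 64, n_classes: int = 4,
              random_state: Optional[int] = None) -> CNNClassifier:
    """Instantiate a :class:`CNNClassifier` from a decoded configuration."""
    return CNNClassifier(
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        base_filters=config.base_filters,
        dropout=config.dropout_rate,
        optimizer=config.optimizer_kind,
        random_state=random_state,
    )


def architecture_summary(base_filters: int, dropout_rate: float,
                         image_size: int = 64, n_classes: int = 4,
                         dense_units: int = 128) -> list[dict]:
    """Layer list of the architecture for a given base filter count."""
    f1, f2 = base_filters, 2 * base_filters
    side = image_size // 4
    return [
        {"layer": "conv1", "filters": f1, "kernel": (3, 3), "activation": "relu"},
        {"layer": "maxpool1", "pool": (2, 2)},
        {"layer": "conv2", "filters": f2, "kernel": (3, 3), "activation": "relu"},
        {"layer": "maxpool2", "pool": (2, 2)},
        {"layer": "flatten", "units": side * side * f2},
        {"layer": "dense1", "units": dense_units, "activation": "relu"},
        {"layer": "dropout", "rate": dropout_rate},
        {"layer": "dense2", "units": n_classes, "activation": "softmax"},
    ]


def parameter_count(base_filters: int, image_size: int = 64, n_classes: int = 4,
                    dense_units: int = 128) -> int:
    """Trainable-parameter count of the architecture (weights + biases)."""
    f1, f2 = base_filters, 2 * base_filters
    flat = (image_size // 4) * (image_size // 4) * f2
    conv1 = 9 * 1 * f1 + f1
    conv2 = 9 * f1 * f2 + f2
    dense1 = flat * dense_units + dense_units
    dense2 = dense_units * n_classes + n_classes
    return conv1 + conv2 + dense1 + dense2
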