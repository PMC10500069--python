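"""Shallow and deep ConvNet EEG classifiers, implemented on NumPy.

Both architectures operate directly on epoched multichannel EEG
(trials x channels x samples):

* **Shallow ConvNet** -- 40 temporal filters (kernel 25 samples) play the
  role of a learned filter bank, 40 spatial filters collapse the channel
  axis (the CSP analogue), then squaring, mean pooling (length 75, stride
  15) and a log give band-power-like features feeding a dense softmax.
* **Deep ConvNet** -- 25 temporal filters (kernel 10) plus a spatial
  collapse form the first of four convolution/max-pooling blocks
  (25/50/100/200 filters, pool length 3, stride 3), with ELU activations
  and optional batch normalisation, ending in a dense softmax.

Training: Adam (lr 1e-3), batch size 32, up to 100 epochs, dropout 0.5
before the dense head, early stopping on validation accuracy with patience
10 and best-epoch weight restore.  Everything is driven by a single seeded
NumPy generator, so runs are reproducible bit-for-bit on a fixed thread
count.  The penultimate activation (the flattened features entering the
dense layer) can be extracted for canonical-correlation analysis.
"""

from __future__ import annotations

import copy

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "ShallowConvNet",
    "DeepConvNet",
    "build_shallow",
    "build_deep",
    "train_net",
    "extract_penultimate",
]


# ---------------------------------------------------------------------------
# layers

class _Layer:
    params: list = []
    grads: list = []

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, d):  # pragma: no cover - interface
        raise NotImplementedError


class _TemporalConv(_Layer):
    """(N, C, T) -> (N, F, C, T-K+1): 1-D convolution along time, per channel."""

    def __init__(self, n_filters: int, kernel: int, rng):
        self.kernel = kernel
        self.W = (rng.standard_normal((n_filters, kernel)) *
                  np.sqrt(2.0 / kernel)).astype(np.float32)
        self.b = np.zeros(n_filters, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        n, c, t = x.shape
        k = self.kernel
        t1 = t - k + 1
        win = np.ascontiguousarray(sliding_window_view(x, k, axis=2)).reshape(-1, k)
        self._win = win if train else None
        self._shape = (n, c, t)
        out = (win @ self.W.T).reshape(n, c, t1, -1).transpose(0, 3, 1, 2)
        return np.ascontiguousarray(out) + self.b[None, :, None, None]

    def backward(self, d):
        n, c, t = self._shape
        k = self.kernel
        t1 = t - k + 1
        d2 = np.ascontiguousarray(d.transpose(0, 2, 3, 1)).reshape(-1, d.shape[1])
        self.grads[0][...] = d2.T @ self._win
        self.grads[1][...] = d.sum(axis=(0, 2, 3))
        # dx[n,c,t+k] accumulates d[n,f,c,t] W[f,k]
        contrib = (d2 @ self.W).reshape(n, c, t1, k)
        dx = np.zeros((n, c, t), dtype=np.float32)
        for j in range(k):
            dx[:, :, j:j + t1] += contrib[:, :, :, j]
        self._win = None
        return dx


class _SpatialCollapse(_Layer):
    """(N, F, C, T) -> (N, G, T): spatial filters spanning all channels."""

    def __init__(self, n_out: int, n_in: int, n_channels: int, rng):
        fan_in = n_in * n_channels
        self.W = (rng.standard_normal((n_out, n_in, n_channels)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        n, f, c, t = x.shape
        x2 = np.ascontiguousarray(x.transpose(0, 3, 1, 2)).reshape(n * t, f * c)
        self._x2 = x2 if train else None
        self._shape = (n, f, c, t)
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = (x2 @ wmat.T).reshape(n, t, -1).transpose(0, 2, 1)
        return np.ascontiguousarray(out) + self.b[None, :, None]

    def backward(self, d):
        n, f, c, t = self._shape
        g = d.shape[1]
        d2 = np.ascontiguousarray(d.transpose(0, 2, 1)).reshape(n * t, g)
        wmat = self.W.reshape(g, -1)
        self.grads[0][...] = (d2.T @ self._x2).reshape(self.W.shape)
        self.grads[1][...] = d.sum(axis=(0, 2))
        dx = (d2 @ wmat).reshape(n, t, f, c).transpose(0, 2, 3, 1)
        self._x2 = None
        return np.ascontiguousarray(dx)


class _Conv1d(_Layer):
    """(N, F, T) -> (N, G, T-K+1): convolution over time across feature maps."""

    def __init__(self, n_out: int, n_in: int, kernel: int, rng):
        self.kernel = kernel
        fan_in = n_in * kernel
        self.W = (rng.standard_normal((n_out, n_in, kernel)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        n, f, t = x.shape
        k = self.kernel
        t1 = t - k + 1
        win = sliding_window_view(x, k, axis=2)  # (N, F, T1, K)
        win = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(n * t1, f * k)
        self._win = win if train else None
        self._shape = (n, f, t)
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = (win @ wmat.T).reshape(n, t1, -1).transpose(0, 2, 1)
        return np.ascontiguousarray(out) + self.b[None, :, None]

    def backward(self, d):
        n, f, t = self._shape
        k = self.kernel
        t1 = t - k + 1
        g = d.shape[1]
        d2 = np.ascontiguousarray(d.transpose(0, 2, 1)).reshape(n * t1, g)
        wmat = self.W.reshape(g, -1)
        self.grads[0][...] = (d2.T @ self._win).reshape(self.W.shape)
        self.grads[1][...] = d.sum(axis=(0, 2))
        contrib = (d2 @ wmat).reshape(n, t1, f, k)
        dx = np.zeros((n, f, t), dtype=np.float32)
        for j in range(k):
            dx[:, :, j:j + t1] += contrib[:, :, :, j].transpose(0, 2, 1)
        self._win = None
        return dx


class _BatchNorm(_Layer):
    """Per-feature-map batch normalisation over (batch, time)."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n_features, dtype=np.float32)
        self.beta = np.zeros(n_features, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_features, dtype=np.float64)
        self.running_var = np.ones(n_features, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            self._std = np.sqrt(var + self.eps).astype(np.float32)
            xhat = (x - mean[None, :, None]) / self._std[None, :, None]
            self._xhat = xhat
            self._m = x.shape[0] * x.shape[2]
        else:
            std = np.sqrt(self.running_var + self.eps).astype(np.float32)
            xhat = (x - self.running_mean.astype(np.float32)[None, :, None]) / std[None, :, None]
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, d):
        xhat, m = self._xhat, self._m
        self.grads[0][...] = (d * xhat).sum(axis=(0, 2))
        self.grads[1][...] = d.sum(axis=(0, 2))
        dxhat = d * self.gamma[None, :, None]
        dx = (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2), keepdims=True))
        dx /= self._std[None, :, None]
        self._xhat = None
        return dx.astype(np.float32)


class _Square(_Layer):
    def forward(self, x, train):
        self._x = x if train else None
        return x * x

    def backward(self, d):
        dx = 2.0 * self._x * d
        self._x = None
        return dx


class _Log(_Layer):
    def __init__(self, eps: float = 1e-6):
        self.eps = eps

    def forward(self, x, train):
        clipped = np.maximum(x, self.eps)
        self._clipped = clipped if train else None
        return np.log(clipped)

    def backward(self, d):
        dx = d / self._clipped
        self._clipped = None
        return dx.astype(np.float32)


class _ELU(_Layer):
    def forward(self, x, train):
        out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0))).astype(np.float32)
        self._out = out if train else None
        self._pos = (x > 0) if train else None
        return out

    def backward(self, d):
        dx = d * np.where(self._pos, 1.0, self._out + 1.0)
        self._out = self._pos = None
        return dx.astype(np.float32)


class _AvgPool(_Layer):
    """(N, F, T) -> (N, F, P): mean pooling, arbitrary stride."""

    def __init__(self, size: int, stride: int):
        self.size, self.stride = size, stride

    def forward(self, x, train):
        n, f, t = x.shape
        p = (t - self.size) // self.stride + 1
        self._in_shape = x.shape
        out = np.empty((n, f, p), dtype=np.float32)
        for i in range(p):
            out[:, :, i] = x[:, :, i * self.stride:i * self.stride + self.size].mean(axis=2)
        return out

    def backward(self, d):
        dx = np.zeros(self._in_shape, dtype=np.float32)
        for i in range(d.shape[2]):
            dx[:, :, i * self.stride:i * self.stride + self.size] += \
                d[:, :, i:i + 1] / self.size
        return dx


class _MaxPool(_Layer):
    """(N, F, T) -> (N, F, T//size): non-overlapping max pooling."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x, train):
        n, f, t = x.shape
        p = t // self.size
        self._in_shape = x.shape
        windows = x[:, :, :p * self.size].reshape(n, f, p, self.size)
        if train:
            self._argmax = windows.argmax(axis=3)
        return windows.max(axis=3)

    def backward(self, d):
        n, f, t = self._in_shape
        p = d.shape[2]
        dx = np.zeros((n, f, p, self.size), dtype=np.float32)
        np.put_along_axis(dx, self._argmax[..., None], d[..., None], axis=3)
        out = np.zeros(self._in_shape, dtype=np.float32)
        out[:, :, :p * self.size] = dx.reshape(n, f, p * self.size)
        self._argmax = None
        return out


class _Dropout(_Layer):
    def __init__(self, p: float, rng):
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (1 - self.p)
        return x * self._mask

    def backward(self, d):
        if self._mask is None:
            return d
        dx = d * self._mask
        self._mask = None
        return dx


class _Flatten(_Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d):
        return d.reshape(self._shape)


class _Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        self.W = (rng.standard_normal((n_in, n_out)) *
                  np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.W + self.b

    def backward(self, d):
        self.grads[0][...] = self._x.T @ d
        self.grads[1][...] = d.sum(axis=0)
        dx = d @ self.W.T
        self._x = None
        return dx.astype(np.float32)


class _Adam:
    def __init__(self, layers, lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.slots = []
        for layer in layers:
            for p, g in zip(layer.params, layer.grads):
                self.slots.append((p, g, np.zeros_like(p, dtype=np.float64),
                                   np.zeros_like(p, dtype=np.float64)))

    def step(self):
        self.t += 1
        b1c = 1 - self.beta1 ** self.t
        b2c = 1 - self.beta2 ** self.t
        for p, g, m, v in self.slots:
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * (g.astype(np.float64) ** 2)
            p -= (self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)).astype(p.dtype)


def _softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# networks

class _ConvNetBase(ClassifierMixin, BaseEstimator):
    """Shared training loop / prediction machinery for both architectures."""

    def __init__(self, lr=1e-3, batch_size=32, max_epochs=100, patience=10,
                 dropout=0.5, validation_fraction=0.2, seed=0):
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.dropout = dropout
        self.validation_fraction = validation_fraction
        self.seed = seed

    # subclasses implement _build(n_channels, n_samples, n_classes, rng)

    def build(self, n_channels: int, n_samples: int, n_classes: int):
        """Initialise the layer stack without training (inspection / testing)."""
        self._rng = np.random.default_rng(self.seed)
        self.layers_, self._penultimate_index = self._build(
            n_channels, n_samples, n_classes, self._rng
        )
        self.n_channels_, self.n_samples_ = n_channels, n_samples
        self.classes_ = np.arange(n_classes)
        return self

    def n_parameters(self) -> int:
        return int(sum(p.size for layer in self.layers_ for p in layer.params))

    def _forward(self, x, train=False, upto=None):
        stop = self._penultimate_index if upto == "penultimate" else len(self.layers_)
        out = x
        for layer in self.layers_[:stop]:
            out = layer.forward(out, train)
        return out

    def _check_input(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError("expected trials x channels x samples input")
        if hasattr(self, "n_channels_") and (
            X.shape[1] != self.n_channels_ or X.shape[2] != self.n_samples_
        ):
            raise ValueError(
                f"input of shape {X.shape[1:]}, model expects "
                f"({self.n_channels_}, {self.n_samples_})"
            )
        return X

    def _split_validation(self, X, y_idx, rng):
        frac = self.validation_fraction
        idx_train, idx_val = [], []
        for c in np.unique(y_idx):
            members = np.flatnonzero(y_idx == c)
            members = members[rng.permutation(len(members))]
            n_val = max(1, int(round(frac * len(members))))
            idx_val.extend(members[:n_val])
            idx_train.extend(members[n_val:])
        return np.sort(np.array(idx_train)), np.sort(np.array(idx_val))

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("need at least two classes")
        rng = np.random.default_rng(self.seed)
        if X_val is None:
            tr, va = self._split_validation(X, y_idx, rng)
            X_val, yv_idx = X[va], y_idx[va]
            X, y_idx = X[tr], y_idx[tr]
        else:
            X_val = np.asarray(X_val, dtype=np.float32)
            yv_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        if len(X_val) == 0:
            raise ValueError("validation set is empty; early stopping undefined")
        self._rng = rng
        self.layers_, self._penultimate_index = self._build(
            X.shape[1], X.shape[2], self.classes_.size, rng
        )
        self.n_channels_, self.n_samples_ = X.shape[1], X.shape[2]
        self._train_loop(X, y_idx, X_val, yv_idx, self.lr, self.max_epochs,
                         self.patience, reset_history=True)
        return self

    def _train_loop(self, X, y_idx, X_val, yv_idx, lr, max_epochs, patience,
                    reset_history):
        rng = self._rng
        opt = _Adam(self.layers_, lr)
        onehot = np.eye(self.classes_.size, dtype=np.float32)
        if reset_history:
            self.history_ = {"train_acc": [], "val_acc": [], "loss": []}
        best_acc = self._eval_accuracy(X_val, yv_idx)
        best_weights = self._copy_weights()
        best_epoch = -1
        wait = 0
        n = len(X)
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            correct, total_loss = 0, 0.0
            for start in range(0, n, self.batch_size):
                batch = order[start:start + self.batch_size]
                xb, yb = X[batch], y_idx[batch]
                logits = self._forward(xb, train=True)
                probs = _softmax(logits)
                total_loss += float(
                    -np.log(probs[np.arange(len(yb)), yb] + 1e-12).sum()
                )
                correct += int((probs.argmax(axis=1) == yb).sum())
                dlogits = (probs - onehot[yb]) / len(yb)
                d = dlogits.astype(np.float32)
                for layer in reversed(self.layers_):
                    d = layer.backward(d)
                opt.step()
            val_acc = self._eval_accuracy(X_val, yv_idx)
            self.history_["train_acc"].append(correct / n)
            self.history_["val_acc"].append(val_acc)
            self.history_["loss"].append(total_loss / n)
            if val_acc > best_acc:
                best_acc, best_epoch, wait = val_acc, epoch, 0
                best_weights = self._copy_weights()
            else:
                wait += 1
                if wait >= patience:
                    break
        self._restore_weights(best_weights)
        self.best_val_accuracy_ = best_acc
        self.best_epoch_ = best_epoch
        return self

    def finetune(self, X, y, X_val, y_val, lr=None, max_epochs=30):
        """Continue training existing weights at a reduced learning rate."""
        if not hasattr(self, "layers_"):
            raise ValueError("finetune requires a fitted network")
        X = self._check_input(X)
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        X_val = self._check_input(X_val)
        yv_idx = np.searchsorted(self.classes_, np.asarray(y_val))
        if len(X_val) == 0:
            raise ValueError("validation set is empty; early stopping undefined")
        self._train_loop(X, y_idx, X_val, yv_idx,
                         self.lr / 10.0 if lr is None else lr,
                         max_epochs, self.patience, reset_history=False)
        return self

    def _copy_weights(self):
        state = [[p.copy() for p in layer.params] for layer in self.layers_]
        running = [
            (layer.running_mean.copy(), layer.running_var.copy())
            if isinstance(layer, _BatchNorm) else None
            for layer in self.layers_
        ]
        return state, running

    def _restore_weights(self, snapshot):
        state, running = snapshot
        for layer, params, stats in zip(self.layers_, state, running):
            for p, saved in zip(layer.params, params):
                p[...] = saved
            if stats is not None:
                layer.running_mean, layer.running_var = stats[0].copy(), stats[1].copy()

    def _eval_accuracy(self, X, y_idx):
        if len(X) == 0:
            return 0.0
        return float((self._predict_indices(X) == y_idx).mean())

    def _predict_indices(self, X, batch: int = 256):
        out = []
        for start in range(0, len(X), batch):
            logits = self._forward(X[start:start + batch], train=False)
            out.append(logits.argmax(axis=1))
        return np.concatenate(out)

    def predict_proba(self, X):
        X = self._check_input(X)
        probs = []
        for start in range(0, len(X), 256):
            probs.append(_softmax(self._forward(X[start:start + 256], train=False)))
        return np.concatenate(probs)

    def predict(self, X):
        X = self._check_input(X)
        return self.classes_[self._predict_indices(X)]

    def score(self, X, y):
        return float((self.predict(X) == np.asarray(y)).mean())

    def extract_penultimate(self, X) -> np.ndarray:
        """Features entering the dense classification layer, one row per trial."""
        X = self._check_input(X)
        feats = []
        for start in range(0, len(X), 256):
            feats.append(
                self._forward(X[start:start + 256], train=False, upto="penultimate")
            )
        return np.concatenate(feats)


class ShallowConvNet(_ConvNetBase):
    """Shallow ConvNet: temporal conv -> spatial collapse -> square ->
    mean pool -> log -> dense softmax."""

    def __init__(self, n_temporal_filters=40, n_spatial_filters=40,
                 temporal_kernel=25, pool_size=75, pool_stride=15,
                 batch_norm=True,
                 lr=1e-3, batch_size=32, max_epochs=100, patience=10,
                 dropout=0.5, validation_fraction=0.2, seed=0):
        super().__init__(lr=lr, batch_size=batch_size, max_epochs=max_epochs,
                         patience=patience, dropout=dropout,
                         validation_fraction=validation_fraction, seed=seed)
        self.n_temporal_filters = n_temporal_filters
        self.n_spatial_filters = n_spatial_filters
        self.temporal_kernel = temporal_kernel
        self.pool_size = pool_size
        self.pool_stride = pool_stride
        self.batch_norm = batch_norm

    def min_samples(self) -> int:
        return self.temporal_kernel + self.pool_size - 1

    def _build(self, n_channels, n_samples, n_classes, rng):
        if n_samples < self.min_samples():
            raise ValueError(
                f"input of {n_samples} samples is too short; the shallow net "
                f"needs at least {self.min_samples()}"
            )
        t1 = n_samples - self.temporal_kernel + 1
        n_pool = (t1 - self.pool_size) // self.pool_stride + 1
        width = self.n_spatial_filters * n_pool
        layers = [
            _TemporalConv(self.n_temporal_filters, self.temporal_kernel, rng),
            _SpatialCollapse(self.n_spatial_filters, self.n_temporal_filters,
                             n_channels, rng),
        ]
        if self.batch_norm:  # stabilises the square/log head during training
            layers.append(_BatchNorm(self.n_spatial_filters))
        layers += [
            _Square(),
            _AvgPool(self.pool_size, self.pool_stride),
            _Log(),
            _Flatten(),
            _Dropout(self.dropout, rng),
            _Dense(width, n_classes, rng),
        ]
        return layers, len(layers) - 2  # penultimate = flattened log band-power map


class DeepConvNet(_ConvNetBase):
    """Deep ConvNet: four conv/max-pool blocks (25/50/100/200 filters) with
    ELU activations and optional batch normalisation, then a dense softmax."""

    def __init__(self, n_temporal_filters=25, temporal_kernel=10,
                 block_filters=(50, 100, 200), pool_size=3, batch_norm=True,
                 lr=1e-3, batch_size=32, max_epochs=100, patience=10,
                 dropout=0.5, validation_fraction=0.2, seed=0):
        super().__init__(lr=lr, batch_size=batch_size, max_epochs=max_epochs,
                         patience=patience, dropout=dropout,
                         validation_fraction=validation_fraction, seed=seed)
        self.n_temporal_filters = n_temporal_filters
        self.temporal_kernel = temporal_kernel
        self.block_filters = block_filters
        self.pool_size = pool_size
        self.batch_norm = batch_norm

    @property
    def n_blocks(self) -> int:
        return 1 + len(self.block_filters)

    def min_samples(self) -> int:
        need = 1
        for _ in self.block_filters[::-1]:
            need = need * self.pool_size + self.temporal_kernel - 1
        need = need * self.pool_size  # first block's pooling
        return need + self.temporal_kernel - 1  # first temporal conv

    def _build(self, n_channels, n_samples, n_classes, rng):
        if n_samples < self.min_samples():
            raise ValueError(
                f"input of {n_samples} samples is too short; the deep net "
                f"needs at least {self.min_samples()}"
            )
        layers: list[_Layer] = [
            _TemporalConv(self.n_temporal_filters, self.temporal_kernel, rng),
            _SpatialCollapse(self.n_temporal_filters, self.n_temporal_filters,
                             n_channels, rng),
        ]
        t = n_samples - self.temporal_kernel + 1
        n_in = self.n_temporal_filters
        if self.batch_norm:
            layers.append(_BatchNorm(n_in))
        layers += [_ELU(), _MaxPool(self.pool_size)]
        t //= self.pool_size
        for n_out in self.block_filters:
            layers.append(_Conv1d(n_out, n_in, self.temporal_kernel, rng))
            t -= self.temporal_kernel - 1
            if self.batch_norm:
                layers.append(_BatchNorm(n_out))
            layers += [_ELU(), _MaxPool(self.pool_size)]
            t //= self.pool_size
            n_in = n_out
        width = n_in * t
        flatten_at = len(layers)
        layers += [_Flatten(), _Dropout(self.dropout, rng), _Dense(width, n_classes, rng)]
        return layers, flatten_at + 1  # penultimate = flattened last block output


# ---------------------------------------------------------------------------
# functional wrappers

def build_shallow(n_channels: int, n_samples: int, n_classes: int,
                  **kwargs) -> ShallowConvNet:
    return ShallowConvNet(**kwargs).build(n_channels, n_samples, n_classes)


def build_deep(n_channels: int, n_samples: int, n_classes: int,
               **kwargs) -> DeepConvNet:
    return DeepConvNet(**kwargs).build(n_channels, n_samples, n_classes)


def train_net(net: _ConvNetBase, X_train, y_train, X_val, y_val) -> _ConvNetBase:
    """Train with an explicit validation set; returns the fitted network
    (with per-epoch history in ``net.history_``)."""
    return net.fit(X_train, y_train, X_val=X_val, y_val=y_val)


def extract_penultimate(net: _ConvNetBase, trials) -> np.ndarray:
    return net.extract_penultimate(trials)
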