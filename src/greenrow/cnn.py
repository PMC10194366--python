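"""Patch-based convolutional network for foreground/background separation.

Each plant pixel is classified from the RGB intensities of its
(2r+1) x (2c+1) neighborhood.  The network is the pipeline's core and is
implemented directly on numpy (no deep-learning framework): four 3x3
same-padding ReLU convolutions (32, 32, 64, 64 channels), a 2x2 valid max
pool between the second and third and after the fourth, then an MLP with a
128-unit ReLU hidden layer, dropout 0.3 on both sides of it, and a sigmoid
output trained with binary cross-entropy under Adam (lr 0.001).  For the
reference neighborhood r = c = 16 the layer shapes are

    (33,33,32), (33,33,32), (16,16,64), (16,16,64), (8,8,64), 4096, 128, 1

with the flattened pool output feeding 4096 nodes into the MLP.

Training is seeded and single-pass deterministic: fixed Glorot
initialisation, fixed shuffling and dropout masks, so two fits with the same
seed produce bit-identical weights.  Dropout is active only during training;
inference is deterministic and batch-size invariant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .selftrain import PatchDataset, extract_patches

_ADAM_BETA1 = 0.9
_ADAM_BETA2 = 0.999
_ADAM_EPS = 1e-7  # Keras default


@dataclass(frozen=True)
class CnnSpec:
    """Architecture and training hyperparameters of the patch classifier."""

    r: int = 16
    c: int = 16
    conv_channels: tuple = (32, 32, 64, 64)
    kernel: int = 3
    hidden_units: int = 128
    dropout_rate: float = 0.3
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 1000
    validation_fraction: float = 0.05

    def __post_init__(self):
        h, w = 2 * self.r + 1, 2 * self.c + 1
        if h // 2 < 1 or (h // 2) // 2 < 1 or w // 2 < 1 or (w // 2) // 2 < 1:
            raise ValueError(
                f"patch {h}x{w} too small for two 2x2 max pools (need r,c >= 2)"
            )

    @property
    def input_shape(self):
        return (2 * self.r + 1, 2 * self.c + 1, 3)

    @property
    def layer_shapes(self):
        """Shapes of conv1, conv2, conv3, conv4, pool2, flatten, hidden, out."""
        h, w = 2 * self.r + 1, 2 * self.c + 1
        ch = self.conv_channels
        h1, w1 = h // 2, w // 2  # after pool between conv2 and conv3
        h2, w2 = h1 // 2, w1 // 2  # after pool following conv4
        return [
            (h, w, ch[0]),
            (h, w, ch[1]),
            (h1, w1, ch[2]),
            (h1, w1, ch[3]),
            (h2, w2, ch[3]),
            h2 * w2 * ch[3],
            self.hidden_units,
            1,
        ]

    @property
    def flatten_size(self) -> int:
        return self.layer_shapes[5]


def build_model(r: int = 16, c: int = 16, preset: str = "paper") -> CnnSpec:
    """Build the reference architecture spec for a given neighborhood size.

    ``preset`` selects the training schedule: ``"paper"`` (100 epochs, batch
    1000 — the full-scale field protocol) or ``"desk"`` (10 epochs, batch 256
    — a single-CPU profile for small synthetic scenes).
    """
    if preset == "paper":
        return CnnSpec(r=r, c=c)
    if preset == "desk":
        return CnnSpec(r=r, c=c, epochs=10, batch_size=256)
    raise ValueError(f"unknown preset {preset!r}")


@dataclass(frozen=True)
class ProbabilityMap:
    """Foreground probability for every plant pixel of one frame.

    Non-plant pixels carry no probability; ``to_dense`` fills them with NaN.
    """

    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray
    shape: tuple

    def __len__(self):
        return self.values.size

    def to_dense(self) -> np.ndarray:
        dense = np.full(self.shape, np.nan)
        dense[self.rows, self.cols] = self.values
        return dense


# ---------------------------------------------------------------------------
# numpy layers (NHWC layout throughout)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B,H,W,C) -> (B*H*W, k*k*C) patches under same padding, stride 1."""
    b, h, w, ch = x.shape
    p = k // 2
    padded = np.zeros((b, h + 2 * p, w + 2 * p, ch), dtype=x.dtype)
    padded[:, p : p + h, p : p + w] = x
    col = np.empty((b, h, w, k * k, ch), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            col[:, :, :, i * k + j] = padded[:, i : i + h, j : j + w]
    return col.reshape(b * h * w, k * k * ch)


def _col2im(dcol: np.ndarray, shape, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add column gradients back."""
    b, h, w, ch = shape
    p = k // 2
    dcol = dcol.reshape(b, h, w, k * k, ch)
    dpad = np.zeros((b, h + 2 * p, w + 2 * p, ch), dtype=dcol.dtype)
    for i in range(k):
        for j in range(k):
            dpad[:, i : i + h, j : j + w] += dcol[:, :, :, i * k + j]
    return dpad[:, p : p + h, p : p + w]


class _Conv:
    """3x3 same-padding convolution + ReLU."""

    def __init__(self, c_in, c_out, k, rng):
        fan_in, fan_out = k * k * c_in, k * k * c_out
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, (k * k * c_in, c_out)).astype(
            np.float32
        )
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k

    def forward(self, x, train):
        self._shape = x.shape
        col = _im2col(x, self.k)
        z = col @ self.W + self.b
        out = np.maximum(z, 0.0)
        if train:
            self._col = col
            self._active = z > 0
        b, h, w, _ = x.shape
        return out.reshape(b, h, w, -1)

    def backward(self, dout):
        b, h, w, c_out = dout.shape
        dz = dout.reshape(-1, c_out) * self._active
        self.dW = self._col.T @ dz
        self.db = dz.sum(axis=0)
        dcol = dz @ self.W.T
        del self._col, self._active
        return _col2im(dcol, self._shape, self.k)

    def params(self):
        return [("W", self), ("b", self)]


class _MaxPool2:
    """2x2 max pooling, stride 2, no padding (odd remainders dropped)."""

    def forward(self, x, train):
        b, h, w, ch = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, : 2 * h2, : 2 * w2]
        patches = xc.reshape(b, h2, 2, w2, 2, ch).transpose(0, 1, 3, 5, 2, 4)
        patches = patches.reshape(b, h2, w2, ch, 4)
        idx = patches.argmax(axis=-1)
        out = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = x.shape
        return out

    def backward(self, dout):
        b, h, w, ch = self._shape
        h2, w2 = h // 2, w // 2
        dpatches = np.zeros((b, h2, w2, ch, 4), dtype=dout.dtype)
        np.put_along_axis(dpatches, self._idx[..., None], dout[..., None], -1)
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dx[:, : 2 * h2, : 2 * w2] = (
            dpatches.reshape(b, h2, w2, ch, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(b, 2 * h2, 2 * w2, ch)
        )
        return dx

    def params(self):
        return []


class _Dense:
    def __init__(self, n_in, n_out, rng, relu):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.relu = relu

    def forward(self, x, train):
        z = x @ self.W + self.b
        if train:
            self._x = x
        if self.relu:
            if train:
                self._active = z > 0
            return np.maximum(z, 0.0)
        return z

    def backward(self, dout):
        if self.relu:
            dout = dout * self._active
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        dx = dout @ self.W.T
        del self._x
        return dx

    def params(self):
        return [("W", self), ("b", self)]


class _Dropout:
    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        self._identity = (not train) or self.rate == 0.0
        if self._identity:
            return x
        keep = 1.0 - self.rate
        self._mask = (
            self.rng.random(x.shape, dtype=np.float32) < keep
        ).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._identity:
            return dout
        return dout * self._mask

    def params(self):
        return []


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


def _bce_loss_and_grad(logits, y):
    """Stable sigmoid + binary cross-entropy; returns (loss, dlogits, p)."""
    z = logits.ravel()
    p = 1.0 / (1.0 + np.exp(-z))
    loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
    dz = ((p - y) / z.size).astype(np.float32)
    return float(loss), dz.reshape(logits.shape), p


class PatchCNNClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn style wrapper around the numpy patch CNN.

    Parameters mirror :class:`CnnSpec`; see the module docstring for the
    architecture.  ``X`` is an (n, 2r+1, 2c+1, 3) float array of patches (or a
    :class:`~greenrow.selftrain.PatchDataset`), ``y`` binary labels with
    1 = foreground plant.

    Attributes
    ----------
    spec_ : CnnSpec
    history_ : DataFrame with per-epoch loss/accuracy and validation metrics
        (one row per epoch, always exactly ``epochs`` rows)
    """

    def __init__(
        self,
        r: int = 16,
        c: int = 16,
        epochs: int = 10,
        batch_size: int = 256,
        learning_rate: float = 0.001,
        dropout_rate: float = 0.3,
        hidden_units: int = 128,
        conv_channels: tuple = (32, 32, 64, 64),
        validation_fraction: float = 0.05,
        random_state: int = 0,
    ):
        self.r = r
        self.c = c
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.dropout_rate = dropout_rate
        self.hidden_units = hidden_units
        self.conv_channels = conv_channels
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- construction -------------------------------------------------------

    def _make_spec(self) -> CnnSpec:
        return CnnSpec(
            r=self.r,
            c=self.c,
            conv_channels=tuple(self.conv_channels),
            hidden_units=self.hidden_units,
            dropout_rate=self.dropout_rate,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            batch_size=self.batch_size,
            validation_fraction=self.validation_fraction,
        )

    def _build_layers(self, spec: CnnSpec, rng):
        ch = spec.conv_channels
        drop_rng = np.random.default_rng(rng.integers(2**31))
        return [
            _Conv(3, ch[0], spec.kernel, rng),
            _Conv(ch[0], ch[1], spec.kernel, rng),
            _MaxPool2(),
            _Conv(ch[1], ch[2], spec.kernel, rng),
            _Conv(ch[2], ch[3], spec.kernel, rng),
            _MaxPool2(),
            _Flatten(),
            _Dropout(spec.dropout_rate, drop_rng),
            _Dense(spec.flatten_size, spec.hidden_units, rng, relu=True),
            _Dropout(spec.dropout_rate, drop_rng),
            _Dense(spec.hidden_units, 1, rng, relu=False),
        ]

    def _forward(self, x, train):
        for layer in self.layers_:
            x = layer.forward(x, train)
        return x

    def _backward(self, dout):
        for layer in reversed(self.layers_):
            dout = layer.backward(dout)

    # -- fitting -------------------------------------------------------------

    def fit(self, X, y=None):
        if isinstance(X, PatchDataset):
            X, y = X.patches, X.labels
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32).ravel()
        spec = self._make_spec()
        if X.shape[1:] != spec.input_shape:
            raise ValueError(
                f"patches {X.shape[1:]} do not match spec input "
                f"{spec.input_shape}"
            )
        rng = np.random.default_rng(self.random_state)
        self.layers_ = self._build_layers(spec, rng)

        # Adam state
        params = [p for layer in self.layers_ for p in layer.params()]
        m = [np.zeros_like(getattr(obj, name)) for name, obj in params]
        v = [np.zeros_like(getattr(obj, name)) for name, obj in params]
        t = 0

        order = rng.permutation(len(X))
        n_val = int(round(spec.validation_fraction * len(X)))
        val_idx, train_idx = order[:n_val], order[n_val:]
        Xtr, ytr = X[train_idx], y[train_idx]
        Xval, yval = X[val_idx], y[val_idx]

        history = []
        for epoch in range(spec.epochs):
            perm = rng.permutation(len(Xtr))
            losses, accs, weights = [], [], []
            for start in range(0, len(Xtr), spec.batch_size):
                batch = perm[start : start + spec.batch_size]
                xb, yb = Xtr[batch], ytr[batch]
                logits = self._forward(xb, train=True)
                loss, dlogits, p = _bce_loss_and_grad(logits, yb)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}, batch start "
                        f"{start}: loss={loss}"
                    )
                self._backward(dlogits)
                t += 1
                lr_t = (
                    spec.learning_rate
                    * np.sqrt(1 - _ADAM_BETA2**t)
                    / (1 - _ADAM_BETA1**t)
                )
                for k, (name, obj) in enumerate(params):
                    g = getattr(obj, "d" + name)
                    m[k] = _ADAM_BETA1 * m[k] + (1 - _ADAM_BETA1) * g
                    v[k] = _ADAM_BETA2 * v[k] + (1 - _ADAM_BETA2) * g * g
                    setattr(
                        obj,
                        name,
                        getattr(obj, name)
                        - lr_t * m[k] / (np.sqrt(v[k]) + _ADAM_EPS),
                    )
                losses.append(loss)
                accs.append(np.mean((p > 0.5) == (yb > 0.5)))
                weights.append(len(batch))
            weights = np.asarray(weights, dtype=np.float64)
            row = {
                "epoch": epoch,
                "loss": np.average(losses, weights=weights),
                "accuracy": np.average(accs, weights=weights),
                "val_loss": np.nan,
                "val_accuracy": np.nan,
            }
            if n_val:
                pv = self._predict_scores(Xval)
                row["val_loss"] = float(
                    np.mean(
                        -(
                            yval * np.log(np.clip(pv, 1e-12, 1))
                            + (1 - yval) * np.log(np.clip(1 - pv, 1e-12, 1))
                        )
                    )
                )
                row["val_accuracy"] = float(np.mean((pv > 0.5) == (yval > 0.5)))
            history.append(row)
        self.spec_ = spec
        self.history_ = pd.DataFrame(history)
        self.classes_ = np.array([0, 1])
        return self

    # -- inference -----------------------------------------------------------

    def _predict_scores(self, X, batch_size=None):
        """Foreground probability per patch (deterministic, dropout off)."""
        X = np.asarray(X, dtype=np.float32)
        bs = batch_size or max(self.batch_size, 256)
        out = np.empty(len(X), dtype=np.float64)
        for start in range(0, len(X), bs):
            logits = self._forward(X[start : start + bs], train=False)
            out[start : start + len(logits)] = 1.0 / (
                1.0 + np.exp(-logits.ravel())
            )
        return out

    def predict_proba(self, X, batch_size=None):
        check_is_fitted(self, "spec_")
        p = self._predict_scores(X, batch_size)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(np.uint8)

    # -- persistence ---------------------------------------------------------

    def save(self, path):
        """Serialise spec + weights to a single ``.npz`` archive."""
        check_is_fitted(self, "spec_")
        arrays = {
            f"p{i}_{name}": getattr(obj, name)
            for i, (name, obj) in enumerate(
                p for layer in self.layers_ for p in layer.params()
            )
        }
        arrays["spec_json"] = np.frombuffer(
            json.dumps(asdict(self.spec_)).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path):
        data = np.load(path)
        spec_kw = json.loads(bytes(data["spec_json"]).decode())
        spec_kw["conv_channels"] = tuple(spec_kw["conv_channels"])
        spec = CnnSpec(**spec_kw)
        est = cls(
            r=spec.r,
            c=spec.c,
            epochs=spec.epochs,
            batch_size=spec.batch_size,
            learning_rate=spec.learning_rate,
            dropout_rate=spec.dropout_rate,
            hidden_units=spec.hidden_units,
            conv_channels=spec.conv_channels,
            validation_fraction=spec.validation_fraction,
        )
        est.layers_ = est._build_layers(spec, np.random.default_rng(0))
        params = [p for layer in est.layers_ for p in layer.params()]
        for i, (name, obj) in enumerate(params):
            setattr(obj, name, data[f"p{i}_{name}"])
        est.spec_ = spec
        est.history_ = pd.DataFrame()
        est.classes_ = np.array([0, 1])
        return est


def train(dataset: PatchDataset, spec: CnnSpec, seed: int = 0):
    """Train a :class:`PatchCNNClassifier` on a patch dataset under a spec."""
    est = PatchCNNClassifier(
        r=spec.r,
        c=spec.c,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        learning_rate=spec.learning_rate,
        dropout_rate=spec.dropout_rate,
        hidden_units=spec.hidden_units,
        conv_channels=spec.conv_channels,
        validation_fraction=spec.validation_fraction,
        random_state=seed,
    )
    return est.fit(dataset)


def predict_probabilities(
    model: PatchCNNClassifier,
    bg_removed: np.ndarray,
    mask: np.ndarray,
    batch_size: int = 1024,
) -> ProbabilityMap:
    """Foreground probability for every plant pixel of one frame.

    Patches are cropped around each plant pixel of the background-removed
    image (zero padding beyond the border) and scored in batches.
    """
    check_is_fitted(model, "spec_")
    bg_removed = np.asarray(bg_removed, dtype=np.float32)
    mask = np.asarray(mask)
    if mask.shape != bg_removed.shape[:2]:
        raise ValueError("mask does not match image dimensions")
    rows, cols = np.nonzero(mask > 0)
    values = np.empty(rows.size, dtype=np.float64)
    r, c = model.spec_.r, model.spec_.c
    for start in range(0, rows.size, batch_size):
        sl = slice(start, start + batch_size)
        patches = extract_patches(bg_removed, rows[sl], cols[sl], r, c)
        values[sl] = model._predict_scores(patches, batch_size)
    return ProbabilityMap(rows, cols, values, mask.shape)
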