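"""The 1D-CNN + LSTM classifier, implemented directly in NumPy.

The network consumes one EEG epoch at a time as a ``segment_len x channels``
matrix. A stack of valid (no padding, stride 1) 1D convolutions

    C[l, r] = f( sum_{k < s, c} x[l + k, c] * w_r[k, c] + b_r ),
    l = 1 .. L - s + 1

interleaved with non-overlapping max-pooling

    h[k, r] = max( C[k*d + 1, r], ..., C[(k+1)*d, r] )

compresses the 500-sample epoch into a short high-level feature sequence,
which a three-layer LSTM stack summarises before a 2-unit sigmoid read-out.
The default architecture (see :func:`default_architecture`) is fixed by its
printed parameter counts and output shapes; kernel and pooling lengths
(s = 4,4,4,4,2 and d = 4,4,4,2) are the unique sizes consistent with them.

Training is mini-batch Adam on a per-unit binary cross-entropy over the two
sigmoid outputs; probabilities are renormalised to sum to one at predict
time. Everything — forward, backward, the optimiser — is plain NumPy, so a
fitted model is reproducible bit-for-bit from its seed on any platform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .recording import SegmentTensor

__all__ = [
    "LayerSpec", "ArchitectureSpec", "TrainConfig", "default_architecture",
    "conv1d_valid", "maxpool1d", "param_count", "CNNLSTM", "TrainingResult",
    "build_and_train",
]


# ---------------------------------------------------------------------------
# Architecture description


@dataclass(frozen=True)
class LayerSpec:
    """One layer: ``conv1d`` (r filters, kernel s), ``maxpool1d`` (pool d),
    ``lstm`` (r units) or ``dense`` (r units)."""

    kind: str
    r: int = 1
    s: int = 1
    d: int = 1
    activation: str = "relu"
    return_sequence: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("conv1d", "maxpool1d", "lstm", "dense"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.r < 1 or self.s < 1 or self.d < 1:
            raise ValueError("layer sizes must be >= 1")


def param_count(layer: LayerSpec, input_dim: int) -> int:
    """Trainable parameters of one layer given its input feature dimension.

    conv1d: ``r (input_dim * s + 1)``; lstm (single-bias gates):
    ``4 (r (input_dim + r) + r)``; dense: ``r (input_dim + 1)``; pooling: 0.
    """
    if layer.kind == "conv1d":
        return layer.r * (input_dim * layer.s + 1)
    if layer.kind == "lstm":
        return 4 * (layer.r * (input_dim + layer.r) + layer.r)
    if layer.kind == "dense":
        return layer.r * (input_dim + 1)
    return 0


@dataclass(frozen=True)
class ArchitectureSpec:
    """Ordered layer stack with shape propagation and parameter counting."""

    input_shape: tuple[int, int] = (500, 19)
    layers: tuple[LayerSpec, ...] = ()

    def propagate_shapes(self) -> list[tuple[int, ...]]:
        """Output shape after each layer: ``(L, dim)`` while a time axis
        survives, ``(dim,)`` after the final-state LSTM / dense layers."""
        shapes: list[tuple[int, ...]] = []
        L, dim = self.input_shape
        has_time = True
        for layer in self.layers:
            if layer.kind == "conv1d":
                if not has_time or L < layer.s:
                    raise ValueError(f"conv kernel {layer.s} exceeds length {L}")
                L, dim = L - layer.s + 1, layer.r
            elif layer.kind == "maxpool1d":
                if not has_time or L < layer.d:
                    raise ValueError(f"pool size {layer.d} exceeds length {L}")
                L = L // layer.d
            elif layer.kind == "lstm":
                dim = layer.r
                if not layer.return_sequence:
                    has_time = False
            else:  # dense
                dim = layer.r
                has_time = False
            if has_time and L < 1:
                raise ValueError("layer yields empty temporal dimension")
            shapes.append((L, dim) if has_time else (dim,))
        return shapes

    def param_counts(self) -> list[int]:
        counts = []
        dim = self.input_shape[1]
        for layer, shape in zip(self.layers, self.propagate_shapes()):
            counts.append(param_count(layer, dim))
            dim = shape[-1]
        return counts

    @property
    def total_params(self) -> int:
        return sum(self.param_counts())


def default_architecture(input_shape: tuple[int, int] = (500, 19)) -> ArchitectureSpec:
    """The reference CNN-LSTM: five conv stages (128/64/32/16/8 filters),
    interleaved max-pooling, a 50-25-25 LSTM stack, and a 2-unit sigmoid
    read-out. 77,792 trainable parameters for 500 x 19 input."""
    return ArchitectureSpec(input_shape=input_shape, layers=(
        LayerSpec("conv1d", r=128, s=4, activation="relu"),
        LayerSpec("maxpool1d", d=4),
        LayerSpec("conv1d", r=64, s=4, activation="relu"),
        LayerSpec("maxpool1d", d=4),
        LayerSpec("conv1d", r=32, s=4, activation="relu"),
        LayerSpec("maxpool1d", d=4),
        LayerSpec("conv1d", r=16, s=4, activation="relu"),
        LayerSpec("conv1d", r=8, s=2, activation="relu"),
        LayerSpec("maxpool1d", d=2),
        LayerSpec("lstm", r=50, activation="tanh", return_sequence=True),
        LayerSpec("lstm", r=25, activation="tanh", return_sequence=True),
        LayerSpec("lstm", r=25, activation="tanh", return_sequence=False),
        LayerSpec("dense", r=2, activation="sigmoid"),
    ))


# ---------------------------------------------------------------------------
# Functional primitives (single-epoch forms)

_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "relu": lambda a: np.maximum(a, 0.0),
    "tanh": np.tanh,
    "sigmoid": lambda a: 1.0 / (1.0 + np.exp(-a)),
    "identity": lambda a: a,
}


def conv1d_valid(x: np.ndarray, weights: np.ndarray, bias: np.ndarray,
                 activation: str = "identity") -> np.ndarray:
    """Valid stride-1 1D convolution over the time axis of one epoch.

    Parameters
    ----------
    x : ``(L, C)`` array
    weights : ``(s, C, r)`` array (kernel position, input channel, filter)
    bias : ``(r,)`` array
    activation : name of the element-wise nonlinearity

    Returns ``(L - s + 1, r)``.
    """
    x = np.asarray(x)
    w = np.asarray(weights)
    L, C = x.shape
    s, Cw, r = w.shape
    if Cw != C:
        raise ValueError("weight channel dimension does not match input")
    if L < s:
        raise ValueError(f"input length {L} shorter than kernel {s}")
    cols = sliding_window_view(x, s, axis=0)          # (L-s+1, C, s)
    out = np.einsum("lcs,scr->lr", cols, w) + np.asarray(bias)
    return _ACTIVATIONS[activation](out)


def maxpool1d(x: np.ndarray, d: int) -> np.ndarray:
    """Non-overlapping max-pooling of one epoch ``(L, r) -> (L // d, r)``;
    the remainder ``L mod d`` is discarded."""
    x = np.asarray(x)
    L, r = x.shape
    if d < 1:
        raise ValueError("pool size must be >= 1")
    if L < d:
        raise ValueError(f"input length {L} shorter than pool {d}")
    k = L // d
    return x[: k * d].reshape(k, d, r).max(axis=1)


# ---------------------------------------------------------------------------
# Trainable layers (batched, with backprop)


class _Conv1D:
    def __init__(self, c_in: int, s: int, r: int, rng: np.random.Generator,
                 dtype) -> None:
        self.c_in, self.s, self.r = c_in, s, r
        limit = np.sqrt(6.0 / (c_in * s + r))
        # flat weight layout (c, k) x r matches the sliding-window reshape
        self.W = rng.uniform(-limit, limit, (c_in * s, r)).astype(dtype)
        self.b = np.zeros(r, dtype=dtype)

    def params(self):
        return [self.W, self.b]

    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = X.shape
        Lp = L - self.s + 1
        cols = sliding_window_view(X, self.s, axis=1)   # (B, L', C, s)
        cols = np.ascontiguousarray(cols).reshape(B * Lp, C * self.s)
        A = (cols @ self.W + self.b).reshape(B, Lp, self.r)
        out = np.maximum(A, 0.0)
        if train:
            self._cols, self._mask = cols, A > 0.0
        return out

    def backward(self, dOut: np.ndarray):
        dA = dOut * self._mask
        B, Lp, r = dA.shape
        db = dA.sum(axis=(0, 1))
        dA2 = dA.reshape(B * Lp, r)
        dW = self._cols.T @ dA2
        # transposed convolution for the input gradient, as one big GEMM
        L = Lp + self.s - 1
        pad = np.zeros((B, Lp + 2 * (self.s - 1), r), dtype=dA.dtype)
        pad[:, self.s - 1: self.s - 1 + Lp] = dA
        colsB = sliding_window_view(pad, self.s, axis=1)  # (B, L, r, s)
        colsB = np.ascontiguousarray(colsB).reshape(B * L, r * self.s)
        Wcsr = self.W.reshape(self.c_in, self.s, r)
        Wb = np.ascontiguousarray(
            Wcsr[:, ::-1, :].transpose(2, 1, 0)).reshape(r * self.s, self.c_in)
        dX = (colsB @ Wb).reshape(B, L, self.c_in)
        self._cols = self._mask = None
        return dX, [dW, db]


class _MaxPool1D:
    def __init__(self, d: int) -> None:
        self.d = d

    def params(self):
        return []

    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        B, L, r = X.shape
        k = L // self.d
        blocks = X[:, : k * self.d].reshape(B, k, self.d, r)
        if train:
            self._argmax = blocks.argmax(axis=2)
            self._in_shape = X.shape
        return blocks.max(axis=2)

    def backward(self, dOut: np.ndarray):
        B, L, r = self._in_shape
        k = dOut.shape[1]
        dX = np.zeros((B, L, r), dtype=dOut.dtype)
        blocks = dX[:, : k * self.d].reshape(B, k, self.d, r)
        np.put_along_axis(blocks, self._argmax[:, :, None, :], dOut[:, :, None, :], axis=2)
        self._argmax = None
        return dX, []


class _LSTM:
    """Single-bias LSTM (gates ordered input, forget, candidate, output)."""

    def __init__(self, m: int, units: int, return_sequence: bool,
                 rng: np.random.Generator, dtype) -> None:
        self.m, self.u, self.return_sequence = m, units, return_sequence
        lim_x = np.sqrt(6.0 / (m + units))
        lim_h = np.sqrt(6.0 / (2 * units))
        self.Wx = rng.uniform(-lim_x, lim_x, (m, 4 * units)).astype(dtype)
        self.Wh = rng.uniform(-lim_h, lim_h, (units, 4 * units)).astype(dtype)
        self.b = np.zeros(4 * units, dtype=dtype)
        self.b[units: 2 * units] = 1.0  # forget-gate bias

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        B, T, m = X.shape
        u = self.u
        h = np.zeros((B, u), dtype=X.dtype)
        c = np.zeros((B, u), dtype=X.dtype)
        hs = np.empty((B, T, u), dtype=X.dtype)
        cache = []
        for t in range(T):
            a = X[:, t] @ self.Wx + h @ self.Wh + self.b
            np.clip(a, -60.0, 60.0, out=a)  # keep exp finite in float32
            i = 1.0 / (1.0 + np.exp(-a[:, :u]))
            f = 1.0 / (1.0 + np.exp(-a[:, u:2 * u]))
            g = np.tanh(a[:, 2 * u:3 * u])
            o = 1.0 / (1.0 + np.exp(-a[:, 3 * u:]))
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h = o * tc
            hs[:, t] = h
            if train:
                cache.append((X[:, t], i, f, g, o, c_prev, tc, None))
        if train:
            # store h_prev per step (h at t-1)
            self._cache = []
            h_prev = np.zeros((B, u), dtype=X.dtype)
            for t, (x_t, i, f, g, o, c_prev, tc, _) in enumerate(cache):
                self._cache.append((x_t, h_prev, i, f, g, o, c_prev, tc))
                h_prev = hs[:, t]
            self._T, self._B = T, B
        return hs if self.return_sequence else h

    def backward(self, dOut: np.ndarray):
        B, T, u = self._B, self._T, self.u
        dtype = dOut.dtype
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dX = np.empty((B, T, self.m), dtype=dtype)
        dh_next = np.zeros((B, u), dtype=dtype)
        dc_next = np.zeros((B, u), dtype=dtype)
        for t in range(T - 1, -1, -1):
            x_t, h_prev, i, f, g, o, c_prev, tc = self._cache[t]
            if self.return_sequence:
                dh = dOut[:, t] + dh_next
            else:
                dh = (dOut + dh_next) if t == T - 1 else dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dA = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            dWx += x_t.T @ dA
            dWh += h_prev.T @ dA
            db += dA.sum(axis=0)
            dX[:, t] = dA @ self.Wx.T
            dh_next = dA @ self.Wh.T
        self._cache = None
        return dX, [dWx, dWh, db]


class _Dense:
    """Linear read-out; the sigmoid is folded into the loss."""

    def __init__(self, m: int, units: int, rng: np.random.Generator, dtype) -> None:
        limit = np.sqrt(6.0 / (m + units))
        self.W = rng.uniform(-limit, limit, (m, units)).astype(dtype)
        self.b = np.zeros(units, dtype=dtype)

    def params(self):
        return [self.W, self.b]

    def forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._X = X
        return X @ self.W + self.b

    def backward(self, dOut: np.ndarray):
        dW = self._X.T @ dOut
        db = dOut.sum(axis=0)
        dX = dOut @ self.W.T
        self._X = None
        return dX, [dW, db]


# ---------------------------------------------------------------------------
# Model / Results


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyper-parameters (Adam + per-unit binary cross-entropy)."""

    batch_size: int = 128
    epochs: int = 30
    learning_rate: float = 1e-3
    seed: int = 0
    patience: int = 5
    standardize: bool = True
    shuffle: bool = True
    dtype: str = "float32"
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _as_xy(data) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(data, SegmentTensor):
        return data.data, data.labels
    if isinstance(data, tuple):
        return np.asarray(data[0]), np.asarray(data[1])
    return np.asarray(data), None


class CNNLSTM:
    """The CNN-LSTM epoch classifier.

    Build from an :class:`ArchitectureSpec` and a :class:`TrainConfig`;
    :meth:`fit` trains with Adam and early stopping on validation loss and
    returns a :class:`TrainingResult`. All randomness (weight initialisation,
    batch shuffling) derives from ``cfg.seed``.
    """

    def __init__(self, arch: ArchitectureSpec | None = None,
                 cfg: TrainConfig | None = None) -> None:
        self.arch = arch or default_architecture()
        self.cfg = cfg or TrainConfig()
        self.dtype = np.dtype(self.cfg.dtype)
        self._rng = np.random.default_rng(self.cfg.seed)
        self._build()
        self.mean_: np.ndarray | None = None
        self.std_: np.ndarray | None = None

    # -- construction -----------------------------------------------------
    def _build(self) -> None:
        self.layers: list = []
        L, dim = self.arch.input_shape
        for spec in self.arch.layers:
            if spec.kind == "conv1d":
                self.layers.append(_Conv1D(dim, spec.s, spec.r, self._rng, self.dtype))
                dim = spec.r
            elif spec.kind == "maxpool1d":
                self.layers.append(_MaxPool1D(spec.d))
            elif spec.kind == "lstm":
                self.layers.append(_LSTM(dim, spec.r, spec.return_sequence,
                                         self._rng, self.dtype))
                dim = spec.r
            else:
                self.layers.append(_Dense(dim, spec.r, self._rng, self.dtype))
                dim = spec.r
        self.n_classes = self.arch.layers[-1].r

    @property
    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params())

    # -- forward / backward ------------------------------------------------
    def _forward(self, X: np.ndarray, train: bool) -> np.ndarray:
        out = X
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def _backward(self, dZ: np.ndarray) -> list[np.ndarray]:
        grads: list[np.ndarray] = []
        d = dZ
        for layer in reversed(self.layers):
            d, g = layer.backward(d)
            grads = g + grads
        return grads

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=self.dtype)
        if self.mean_ is None:
            return X
        return (X - self.mean_) / self.std_

    # -- inference ---------------------------------------------------------
    def logits(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        X = self._standardize(X)
        outs = [self._forward(X[i:i + batch_size], train=False)
                for i in range(0, len(X), batch_size)]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, data) -> np.ndarray:
        """Class probabilities per epoch; the two sigmoid outputs are
        renormalised to sum to one."""
        X, _ = _as_xy(data)
        z = self.logits(X)
        p = 1.0 / (1.0 + np.exp(-z.astype(np.float64)))
        return p / p.sum(axis=1, keepdims=True)

    def predict(self, data) -> np.ndarray:
        return self.predict_proba(data).argmax(axis=1)

    def _eval(self, X: np.ndarray, Y: np.ndarray) -> tuple[float, float]:
        z = self.logits(X).astype(np.float64)
        p = 1.0 / (1.0 + np.exp(-z))
        eps = 1e-12
        loss = -np.mean(np.sum(Y * np.log(p + eps) + (1 - Y) * np.log(1 - p + eps), axis=1))
        acc = float(np.mean(p.argmax(axis=1) == Y.argmax(axis=1)))
        return float(loss), acc

    # -- training ----------------------------------------------------------
    def fit(self, train, val=None) -> "TrainingResult":
        """Train on ``train`` (a SegmentTensor or ``(X, y)``), early-stopping
        on validation loss, and restore the best-epoch weights."""
        cfg = self.cfg
        X, y = _as_xy(train)
        if y is None:
            raise ValueError("training data must carry labels")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain at least two classes")
        if cfg.standardize:
            mean = X.mean(axis=(0, 1), dtype=np.float64)
            std = X.std(axis=(0, 1), dtype=np.float64)
            self.mean_ = mean.astype(self.dtype)
            self.std_ = np.maximum(std, 1e-8).astype(self.dtype)
        Xs = self._standardize(X)
        Y = np.eye(self.n_classes, dtype=self.dtype)[y]

        has_val = False
        if val is not None:
            Xv, yv = _as_xy(val)
            if yv is None or len(Xv) == 0:
                warnings.warn("empty validation set; early-stopping on training loss",
                              RuntimeWarning, stacklevel=2)
            else:
                has_val = True
                Xv = self._standardize(Xv)
                Yv = np.eye(self.n_classes, dtype=self.dtype)[yv]

        params = [p for layer in self.layers for p in layer.params()]
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0

        history = []
        best_loss = np.inf
        best_state = [p.copy() for p in params]
        best_epoch = 0
        bad_epochs = 0
        n = len(Xs)
        for epoch in range(1, cfg.epochs + 1):
            order = self._rng.permutation(n) if cfg.shuffle else np.arange(n)
            epoch_loss = 0.0
            epoch_correct = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = Xs[idx], Y[idx]
                z = self._forward(xb, train=True)
                zf = z.astype(np.float64)
                p = 1.0 / (1.0 + np.exp(-zf))
                loss = -np.mean(np.sum(
                    yb * np.log(p + 1e-12) + (1 - yb) * np.log(1 - p + 1e-12), axis=1))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}; try a lower learning rate")
                epoch_loss += loss * len(idx)
                epoch_correct += int(np.sum(p.argmax(axis=1) == yb.argmax(axis=1)))
                dZ = ((p - yb) / len(idx)).astype(self.dtype)
                grads = self._backward(dZ)
                step += 1
                lr_t = cfg.learning_rate * (np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step))
                for p_, g_, m_, v_ in zip(params, grads, m_t, v_t):
                    m_ *= beta1
                    m_ += (1 - beta1) * g_
                    v_ *= beta2
                    v_ += (1 - beta2) * g_ * g_
                    p_ -= lr_t * m_ / (np.sqrt(v_) + eps)
            train_loss = epoch_loss / n
            train_acc = epoch_correct / n
            if has_val:
                val_loss, val_acc = self._eval(Xv, Yv)
            else:
                val_loss, val_acc = train_loss, train_acc
            history.append({"epoch": epoch, "train_loss": float(train_loss),
                            "train_acc": float(train_acc),
                            "val_loss": float(val_loss), "val_acc": float(val_acc)})
            if cfg.verbose:
                print(f"epoch {epoch:3d} loss {train_loss:.4f} acc {train_acc:.3f} "
                      f"val_loss {val_loss:.4f} val_acc {val_acc:.3f}")
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_state = [p.copy() for p in params]
                best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= cfg.patience:
                    break
        for p_, b_ in zip(params, best_state):
            p_[...] = b_
        return TrainingResult(model=self, history=pd.DataFrame(history),
                              best_epoch=best_epoch)

    # -- persistence -------------------------------------------------------
    def save_weights(self, path) -> None:
        arrays = {}
        for li, layer in enumerate(self.layers):
            for pi, p in enumerate(layer.params()):
                arrays[f"l{li}_p{pi}"] = p
        if self.mean_ is not None:
            arrays["mean"] = self.mean_
            arrays["std"] = self.std_
        np.savez(path, **arrays)

    def load_weights(self, path) -> None:
        with np.load(path) as z:
            for li, layer in enumerate(self.layers):
                for pi, p in enumerate(layer.params()):
                    p[...] = z[f"l{li}_p{pi}"]
            if "mean" in z:
                self.mean_ = z["mean"]
                self.std_ = z["std"]


@dataclass
class TrainingResult:
    """Outcome of one training run: the fitted model, the per-epoch history
    (train/validation loss and accuracy) and the early-stopping epoch."""

    model: CNNLSTM
    history: pd.DataFrame
    best_epoch: int

    def predict_proba(self, data) -> np.ndarray:
        return self.model.predict_proba(data)

    def predict(self, data) -> np.ndarray:
        return self.model.predict(data)

    def summary(self) -> str:
        h = self.history
        last = h.iloc[-1]
        lines = [
            "CNN-LSTM training result",
            f"  parameters:     {self.model.n_params:,}",
            f"  epochs run:     {len(h)} (best: {self.best_epoch})",
            f"  final train:    loss {last.train_loss:.4f}, acc {last.train_acc:.3f}",
            f"  final val:      loss {last.val_loss:.4f}, acc {last.val_acc:.3f}",
        ]
        return "\n".join(lines)


def build_and_train(arch: ArchitectureSpec, train, val,
                    cfg: TrainConfig | None = None) -> TrainingResult:
    """Convenience wrapper: construct a :class:`CNNLSTM` and fit it."""
    model = CNNLSTM(arch, cfg)
    return model.fit(train, val)
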