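"""A compact 1-D convolutional network classifier implemented in numpy.

The k-mer feature vector of a sequence is treated as a single-channel 1-D
signal. The stack is conv(ReLU) -> max-pool -> variance gate -> dropout ->
conv(ReLU) -> max-pool -> flatten -> dense soft-max, trained with Adam on
the cross-entropy loss. The variance gate zeroes pooled channels whose
positional variance does not exceed ``v_h`` times the mean channel variance
of that sample, discarding flat, uninformative feature maps.

All operations are dense numpy; mini-batch convolution uses an im2col
layout so the inner products run through BLAS.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

CHANNEL_RANGE = (64, 512)
KERNEL_RANGE = (3, 5)


@dataclass
class CNNConfig:
    channels: tuple[int, int] = (64, 128)
    kernels: tuple[int, int] = (3, 3)
    pool_size: int = 2
    dropout: float = 0.2
    v_h: float = 0.5
    epochs: int = 30
    learning_rate: float = 0.01
    batch_size: int = 32
    seed: int = 0

    def validate(self) -> None:
        for c in self.channels:
            if not CHANNEL_RANGE[0] <= c <= CHANNEL_RANGE[1]:
                raise ValueError(f"channel count {c} outside {CHANNEL_RANGE}")
        for k in self.kernels:
            if not KERNEL_RANGE[0] <= k <= KERNEL_RANGE[1]:
                raise ValueError(f"kernel length {k} outside {KERNEL_RANGE}")
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.v_h <= 0:
            raise ValueError("v_h must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")


def variance_gate(activations: np.ndarray, v_h: float) -> np.ndarray:
    """Zero channels whose positional variance is <= v_h * mean variance.

    Accepts ``(channels, positions)`` or ``(batch, channels, positions)``.
    Selection is strict (``var > threshold``), so a perfectly uniform layer
    gates everything.
    """
    arr = np.asarray(activations, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("activations must be 2-D or 3-D")
    var = arr.var(axis=2)                                  # (B, C)
    thr = v_h * var.mean(axis=1, keepdims=True)            # (B, 1)
    keep = (var > thr).astype(arr.dtype)[:, :, None]
    out = arr * keep
    return out[0] if squeeze else out


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x (B, Cin, L), W (Cout, Cin, k) -> out (B, Cout, L-k+1)."""
    B, Cin, L = x.shape
    Cout, _, k = W.shape
    Lo = L - k + 1
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (B,Cin,Lo,k)
    col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * Lo, Cin * k)
    out = col @ W.reshape(Cout, Cin * k).T + b
    return out.reshape(B, Lo, Cout).transpose(0, 2, 1), col


def _conv_backward(dout: np.ndarray, col: np.ndarray, W: np.ndarray, x_shape):
    B, Cin, L = x_shape
    Cout, _, k = W.shape
    Lo = L - k + 1
    dflat = np.ascontiguousarray(dout.transpose(0, 2, 1)).reshape(B * Lo, Cout)
    dW = (dflat.T @ col).reshape(Cout, Cin, k)
    db = dflat.sum(axis=0)
    dcol = (dflat @ W.reshape(Cout, Cin * k)).reshape(B, Lo, Cin, k)
    dx = np.zeros(x_shape)
    for j in range(k):
        dx[:, :, j : j + Lo] += dcol[:, :, :, j].transpose(0, 2, 1)
    return dx, dW, db


def _pool_forward(x: np.ndarray, p: int):
    """Non-overlapping max pooling, stride = size = p; trailing remainder
    positions are dropped."""
    B, C, L = x.shape
    Lp = L // p
    if Lp < 1:
        raise ValueError("feature map shorter than pool size")
    blocks = x[:, :, : Lp * p].reshape(B, C, Lp, p)
    idx = blocks.argmax(axis=3)
    out = np.take_along_axis(blocks, idx[..., None], axis=3)[..., 0]
    return out, idx


def _pool_backward(dout: np.ndarray, idx: np.ndarray, p: int, L: int):
    B, C, Lp = dout.shape
    dblocks = np.zeros((B, C, Lp, p))
    np.put_along_axis(dblocks, idx[..., None], dout[..., None], axis=3)
    dx = np.zeros((B, C, L))
    dx[:, :, : Lp * p] = dblocks.reshape(B, C, Lp * p)
    return dx


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for k in params:
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Conv1DClassifier:
    """Two conv blocks with max pooling and a variance gate, then a dense
    soft-max head. Deterministic for a fixed config seed."""

    def __init__(self, config: CNNConfig | None = None):
        self.config = config or CNNConfig()
        self.config.validate()
        self.params: dict[str, np.ndarray] | None = None
        self.n_classes_: int | None = None
        self.classes_: np.ndarray | None = None

    # -- architecture bookkeeping -------------------------------------------------
    def _shapes(self, n_features: int):
        """Layer lengths; pools degrade to size 1 when a map would vanish,
        so short (heavily masked) inputs still flow through both blocks."""
        c1, c2 = self.config.channels
        k1, k2 = self.config.kernels
        p = self.config.pool_size
        if n_features < k1:
            raise ValueError(
                f"feature length {n_features} shorter than first kernel {k1}"
            )
        L1 = n_features - k1 + 1
        self._p1 = p if L1 // p >= k2 else 1
        L1p = L1 // self._p1
        if L1p < k2:
            raise ValueError(
                f"pooled length {L1p} shorter than second kernel {k2}; "
                "reduce kernel/pool sizes or provide more features"
            )
        L2 = L1p - k2 + 1
        self._p2 = p if L2 // p >= 1 else 1
        L2p = L2 // self._p2
        return L1, L1p, L2, L2p

    def _init_params(self, n_features: int, n_classes: int, rng: np.random.Generator):
        c1, c2 = self.config.channels
        k1, k2 = self.config.kernels
        _, _, _, L2p = self._shapes(n_features)
        flat = c2 * L2p
        self.params = {
            "W1": rng.standard_normal((c1, 1, k1)) * np.sqrt(2.0 / k1),
            "b1": np.zeros(c1),
            "W2": rng.standard_normal((c2, c1, k2)) * np.sqrt(2.0 / (c1 * k2)),
            "b2": np.zeros(c2),
            "Wd": rng.standard_normal((flat, n_classes)) * np.sqrt(2.0 / flat),
            "bd": np.zeros(n_classes),
        }

    # -- forward/backward ---------------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        P = self.params
        cache: dict = {}
        z1, col1 = _conv_forward(x, P["W1"], P["b1"])
        a1 = np.maximum(z1, 0.0)
        a1p, idx1 = _pool_forward(a1, self._p1)
        var = a1p.var(axis=2)
        thr = self.config.v_h * var.mean(axis=1, keepdims=True)
        gate = (var > thr).astype(a1p.dtype)[:, :, None]
        a1g = a1p * gate
        if train and self.config.dropout > 0:
            drop = (rng.random(a1g.shape) >= self.config.dropout) / (
                1 - self.config.dropout
            )
            a1d = a1g * drop
        else:
            drop = None
            a1d = a1g
        z2, col2 = _conv_forward(a1d, P["W2"], P["b2"])
        a2 = np.maximum(z2, 0.0)
        a2p, idx2 = _pool_forward(a2, self._p2)
        B = x.shape[0]
        h = a2p.reshape(B, -1)
        logits = h @ P["Wd"] + P["bd"]
        logits -= logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        cache.update(
            x=x, z1=z1, col1=col1, a1=a1, idx1=idx1, gate=gate, drop=drop,
            a1d_shape=a1d.shape, z2=z2, col2=col2, a2=a2, idx2=idx2,
            a2p_shape=a2p.shape, h=h, probs=probs,
        )
        return probs, cache

    def _backward(self, cache: dict, y_onehot: np.ndarray):
        P = self.params
        B = y_onehot.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = (cache["probs"] - y_onehot) / B
        grads["Wd"] = cache["h"].T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dh = dlogits @ P["Wd"].T
        da2p = dh.reshape(cache["a2p_shape"])
        da2 = _pool_backward(da2p, cache["idx2"], self._p2, cache["a2"].shape[2])
        dz2 = da2 * (cache["z2"] > 0)
        da1d, grads["W2"], grads["b2"] = _conv_backward(
            dz2, cache["col2"], P["W2"], cache["a1d_shape"]
        )
        if cache["drop"] is not None:
            da1d = da1d * cache["drop"]
        da1p = da1d * cache["gate"]
        da1 = _pool_backward(da1p, cache["idx1"], self._p1, cache["a1"].shape[2])
        dz1 = da1 * (cache["z1"] > 0)
        _, grads["W1"], grads["b1"] = _conv_backward(
            dz1, cache["col1"], P["W1"], cache["x"].shape
        )
        return grads

    # -- sklearn-ish surface ------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Conv1DClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n_classes = int(y.max()) + 1
        self.classes_ = np.arange(n_classes)
        self.n_classes_ = n_classes
        if X.shape[0] < n_classes:
            raise ValueError("need at least one row per class")
        rng = np.random.default_rng(self.config.seed)
        self._init_params(X.shape[1], n_classes, rng)
        optimizer = _Adam(self.params, self.config.learning_rate)
        onehot = np.eye(n_classes)[y]
        n = X.shape[0]
        bs = min(self.config.batch_size, n)
        xin = X[:, None, :]
        for _epoch in range(self.config.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                sel = order[start : start + bs]
                probs, cache = self._forward(xin[sel], train=True, rng=rng)
                grads = self._backward(cache, onehot[sel])
                optimizer.step(self.params, grads)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        out = []
        for start in range(0, X.shape[0], 256):
            probs, _ = self._forward(
                X[start : start + 256, None, :], train=False, rng=None
            )
            out.append(probs)
        return np.vstack(out)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))
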