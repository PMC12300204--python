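"""Minimal numpy feed-forward / recurrent network engine.

Implements exactly the two architectures the identification pipeline needs —
a two-layer LSTM sequence classifier and a three-hidden-layer dense
classifier — with categorical cross-entropy, inverted dropout and Adam.
Forward and backward passes are hand-written and covered by numerical
gradient checks in the test suite.

Parameters are float32 by default and all intermediate buffers follow the
parameter dtype (casting parameters to float64 yields a float64 pass, which
the finite-difference gradient checks rely on).  Determinism comes from the
``numpy.random.Generator`` handed in by the caller.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _orthogonal(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    a = rng.standard_normal(size=(max(shape), max(shape)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))  # fix QR sign ambiguity for reproducibility
    return q[: shape[0], : shape[1]].astype(np.float32)


class AdamOptimizer:
    """Adam with the standard moment estimates (b1=0.9, b2=0.999)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


class _LSTMLayer:
    """One LSTM layer; gate order i, f, g, o; forget-gate bias initialised to 1."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_units: int, prefix: str):
        self.n_in, self.h = n_in, n_units
        self.prefix = prefix
        self.params = {
            f"{prefix}W": _glorot(rng, (n_in, 4 * n_units)),
            f"{prefix}U": _orthogonal(rng, (n_units, 4 * n_units)),
            f"{prefix}b": np.zeros(4 * n_units, dtype=np.float32),
        }
        self.params[f"{prefix}b"][n_units : 2 * n_units] = 1.0

    def forward(self, params: dict, x: np.ndarray):
        """x: (B, T, n_in) -> h_seq (B, T, H) plus a cache for backprop."""
        W, U, b = (params[f"{self.prefix}{k}"] for k in ("W", "U", "b"))
        B, T, _ = x.shape
        H = self.h
        dt = W.dtype
        h = np.zeros((B, H), dtype=dt)
        c = np.zeros((B, H), dtype=dt)
        h_seq = np.empty((B, T, H), dtype=dt)
        cache = []
        xz = x @ W  # precompute input contributions for all steps
        for t in range(T):
            z = xz[:, t] + h @ U + b
            i = 1.0 / (1.0 + np.exp(-z[:, :H]))
            f = 1.0 / (1.0 + np.exp(-z[:, H : 2 * H]))
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = 1.0 / (1.0 + np.exp(-z[:, 3 * H :]))
            c_prev, h_prev = c, h
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            h_seq[:, t] = h
            cache.append((i, f, g, o, c_prev, h_prev, tc))
        return h_seq, (x, cache)

    def backward(self, params: dict, cache, dh_seq: np.ndarray, grads: dict):
        """dh_seq: (B, T, H) upstream gradient on every output step."""
        x, steps = cache
        W, U = params[f"{self.prefix}W"], params[f"{self.prefix}U"]
        B, T, _ = x.shape
        H = self.h
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros(4 * H, dtype=W.dtype)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H), dtype=W.dtype)
        dc_next = np.zeros((B, H), dtype=W.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = steps[t]
            dh = dh_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di, df, dg = dc * g, dc * c_prev, dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                axis=1,
            )
            dW += x[:, t].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ W.T
            dh_next = dz @ U.T
        grads[f"{self.prefix}W"] = dW
        grads[f"{self.prefix}U"] = dU
        grads[f"{self.prefix}b"] = db
        return dx


class LSTMClassifier:
    """lstm(u) -> dropout -> lstm(u) -> dense(u, relu) -> softmax(l).

    The first recurrent layer returns its full hidden sequence; the second
    contributes only its final hidden state to the dense head.
    """

    def __init__(self, n_channels: int, n_labels: int, n_units: int = 64,
                 dropout: float = 0.5, seed: int = 0):
        if n_labels < 2:
            raise ValidationError("need at least 2 labels")
        rng = np.random.default_rng(seed)
        self.n_labels = n_labels
        self.dropout = dropout
        self.l1 = _LSTMLayer(rng, n_channels, n_units, "l1_")
        self.l2 = _LSTMLayer(rng, n_units, n_units, "l2_")
        self.params: dict[str, np.ndarray] = {}
        self.params.update(self.l1.params)
        self.params.update(self.l2.params)
        self.params["dW"] = _glorot(rng, (n_units, n_units))
        self.params["db"] = np.zeros(n_units, dtype=np.float32)
        self.params["oW"] = _glorot(rng, (n_units, n_labels))
        self.params["ob"] = np.zeros(n_labels, dtype=np.float32)

    def _forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None):
        dt = self.params["l1_W"].dtype
        h1, c1 = self.l1.forward(self.params, x.astype(dt))
        if train and self.dropout > 0:
            keep = 1.0 - self.dropout
            mask = (rng.random(h1.shape) < keep).astype(dt) / keep
            h1d = h1 * mask
        else:
            mask = None
            h1d = h1
        h2, c2 = self.l2.forward(self.params, h1d)
        last = h2[:, -1]
        pre = last @ self.params["dW"] + self.params["db"]
        hid = np.maximum(pre, 0.0)
        probs = softmax(hid @ self.params["oW"] + self.params["ob"])
        return probs, (c1, mask, c2, h2.shape, last, pre, hid)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        """Mean categorical cross-entropy and gradients for one minibatch."""
        probs, (c1, mask, c2, h2shape, last, pre, hid) = self._forward(x, True, rng)
        B = x.shape[0]
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-12)))
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads: dict[str, np.ndarray] = {
            "oW": hid.T @ dlogits,
            "ob": dlogits.sum(axis=0),
        }
        dhid = dlogits @ self.params["oW"].T
        dpre = dhid * (pre > 0)
        grads["dW"] = last.T @ dpre
        grads["db"] = dpre.sum(axis=0)
        dh2 = np.zeros(h2shape, dtype=self.params["l2_W"].dtype)
        dh2[:, -1] = dpre @ self.params["dW"].T
        dh1 = self.l2.backward(self.params, c2, dh2, grads)
        if mask is not None:
            dh1 = dh1 * mask
        self.l1.backward(self.params, c1, dh1, grads)
        return loss, grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [
            self._forward(x[i : i + batch_size], False, None)[0]
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)


class DenseClassifier:
    """Fully connected relu net with hidden sizes (100, 75, 50) -> softmax(l)."""

    def __init__(self, n_in: int, n_labels: int,
                 hidden: tuple[int, ...] = (100, 75, 50), seed: int = 0):
        if n_labels < 2:
            raise ValidationError("need at least 2 labels")
        rng = np.random.default_rng(seed)
        self.n_labels = n_labels
        sizes = (n_in, *hidden, n_labels)
        self.n_layers = len(sizes) - 1
        self.params = {}
        for k in range(self.n_layers):
            self.params[f"W{k}"] = _glorot(rng, (sizes[k], sizes[k + 1]))
            self.params[f"b{k}"] = np.zeros(sizes[k + 1], dtype=np.float32)

    def _forward(self, x: np.ndarray):
        acts = [x.astype(self.params["W0"].dtype)]
        pres = []
        h = acts[0]
        for k in range(self.n_layers):
            z = h @ self.params[f"W{k}"] + self.params[f"b{k}"]
            pres.append(z)
            h = softmax(z) if k == self.n_layers - 1 else np.maximum(z, 0.0)
            acts.append(h)
        return acts, pres

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator | None = None):
        acts, pres = self._forward(x)
        probs = acts[-1]
        B = x.shape[0]
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-12)))
        delta = probs.copy()
        delta[np.arange(B), y] -= 1.0
        delta /= B
        grads = {}
        for k in range(self.n_layers - 1, -1, -1):
            grads[f"W{k}"] = acts[k].T @ delta
            grads[f"b{k}"] = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ self.params[f"W{k}"].T) * (pres[k - 1] > 0)
        return loss, grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        out = [
            self._forward(x[i : i + batch_size])[0][-1]
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)


def fit(model, x: np.ndarray, y: np.ndarray, epochs: int, batch_size: int,
        lr: float, seed: int = 0) -> list[float]:
    """Minibatch Adam training; returns the per-epoch mean loss trace.

    Runs exactly ``epochs`` epochs — no early stopping — so loss traces from
    different folds and feature sets are directly comparable.
    """
    if epochs < 1:
        raise ValidationError("epochs must be >= 1")
    rng = np.random.default_rng(seed)
    opt = AdamOptimizer(model.params, lr=lr)
    n = x.shape[0]
    trace = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            loss, grads = model.loss_and_grads(x[idx], y[idx], rng)
            opt.step(model.params, grads)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return trace
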