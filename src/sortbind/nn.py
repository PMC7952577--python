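"""Minimal feed-forward / convolutional regression engine in NumPy.

Two architectures are provided, matching the binding-model designs used in
this package: a dense network with 1-3 hidden layers, per-layer dropout and
an identity output node, and a 1-D convolutional network (convolution over
sequence columns, relu, global max pooling, one hidden layer, identity
output).  Both train with mini-batch Adam on mean-squared error.  All
randomness (initialisation, batch shuffling, dropout masks) flows through a
single seeded generator so training is reproducible bit-for-bit on a single
thread.
"""

from __future__ import annotations

import json

import numpy as np

_ACT = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, h: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z, h: 1.0 - h ** 2),
    "identity": (lambda z: z, lambda z, h: np.ones_like(z)),
}


class _Adam:
    def __init__(self, params, lr=0.001, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class _Net:
    """Shared training loop and serialization."""

    params: list
    loss_history: list

    def _forward(self, X, rng=None):  # pragma: no cover - overridden
        raise NotImplementedError

    def _backward(self, cache, dout):  # pragma: no cover - overridden
        raise NotImplementedError

    def predict(self, X) -> np.ndarray:
        out, _ = self._forward(np.asarray(X, dtype=float), rng=None)
        return out.ravel()

    def fit(self, X, y, epochs, batch_size, lr=0.001, seed=0):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(seed)
        opt = _Adam(self.params, lr=lr)
        self.loss_history = []
        n = len(y)
        for _ in range(int(epochs)):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                out, cache = self._forward(X[idx], rng=rng)
                resid = out.ravel() - y[idx]
                epoch_loss += float(np.sum(resid ** 2))
                dout = (2.0 * resid / len(idx)).reshape(-1, 1)
                grads = self._backward(cache, dout)
                opt.step(grads)
            self.loss_history.append(epoch_loss / n)
        return self

    def save(self, path):
        blob = self._config()
        blob["weights"] = [p.tolist() for p in self.params]
        blob["loss_history"] = list(getattr(self, "loss_history", []))
        with open(path, "w") as fh:
            json.dump(blob, fh)

    @staticmethod
    def load(path):
        with open(path) as fh:
            blob = json.load(fh)
        kind = blob.pop("kind")
        weights = [np.asarray(w) for w in blob.pop("weights")]
        history = blob.pop("loss_history", [])
        net = {"dense": DenseNet, "conv": ConvNet}[kind](**blob)
        for p, w in zip(net.params, weights):
            p[:] = w
        net.loss_history = history
        return net


class DenseNet(_Net):
    """Fully connected regressor over flattened one-hot inputs."""

    def __init__(self, input_dim, hidden, activation="relu", dropout=0.2, seed=0):
        if activation not in _ACT:
            raise ValueError(f"unknown activation {activation!r}")
        self.input_dim = int(input_dim)
        self.hidden = [int(h) for h in hidden]
        self.activation = activation
        self.dropout = float(dropout)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        dims = [self.input_dim] + self.hidden + [1]
        self.params = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in) if activation == "relu" else np.sqrt(1.0 / fan_in)
            self.params.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.params.append(np.zeros(fan_out))
        self.loss_history = []

    def _config(self):
        return {"kind": "dense", "input_dim": self.input_dim, "hidden": self.hidden,
                "activation": self.activation, "dropout": self.dropout, "seed": self.seed}

    def _forward(self, X, rng=None):
        act, _ = _ACT[self.activation]
        a = X.reshape(len(X), -1)
        cache = {"a": [a], "z": [], "mask": []}
        n_hidden = len(self.hidden)
        for layer in range(n_hidden):
            W, b = self.params[2 * layer], self.params[2 * layer + 1]
            z = a @ W + b
            h = act(z)
            if rng is not None and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * mask
            else:
                mask = None
            cache["z"].append(z)
            cache["mask"].append(mask)
            cache["a"].append(h)
            a = h
        Wo, bo = self.params[-2], self.params[-1]
        out = a @ Wo + bo
        return out, cache

    def _backward(self, cache, dout):
        _, dact = _ACT[self.activation]
        grads = [None] * len(self.params)
        a_last = cache["a"][-1]
        grads[-2] = a_last.T @ dout
        grads[-1] = dout.sum(axis=0)
        da = dout @ self.params[-2].T
        for layer in reversed(range(len(self.hidden))):
            z = cache["z"][layer]
            mask = cache["mask"][layer]
            if mask is not None:
                da = da * mask
            dz = da * dact(z, _ACT[self.activation][0](z))
            a_prev = cache["a"][layer]
            grads[2 * layer] = a_prev.T @ dz
            grads[2 * layer + 1] = dz.sum(axis=0)
            da = dz @ self.params[2 * layer].T
        return grads


class ConvNet(_Net):
    """Conv1D -> relu -> global max pool -> dense relu stack -> identity.

    Inputs are (batch, channels, length) matrices; the convolution slides
    along the length axis, so constant flanking columns cannot dominate the
    pooled features.  ``hidden`` is the list of dense relu layer widths
    (1-3 layers) between the pooled features and the output node.
    """

    def __init__(self, in_channels, length, n_kernels, kernel_len, hidden, seed=0):
        self.in_channels = int(in_channels)
        self.length = int(length)
        self.n_kernels = int(n_kernels)
        self.kernel_len = int(kernel_len)
        self.hidden = [int(h) for h in np.atleast_1d(hidden)]
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        fan_conv = self.in_channels * self.kernel_len
        self.params = [
            rng.normal(0.0, np.sqrt(2.0 / fan_conv),
                       size=(self.n_kernels, self.in_channels, self.kernel_len)),
            np.zeros(self.n_kernels),
        ]
        dims = [self.n_kernels] + self.hidden + [1]
        for i, (fan_in, fan_out) in enumerate(zip(dims[:-1], dims[1:])):
            scale = np.sqrt(2.0 / fan_in) if fan_out != 1 else np.sqrt(1.0 / fan_in)
            self.params.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.params.append(np.zeros(fan_out))
        self.loss_history = []

    def _config(self):
        return {"kind": "conv", "in_channels": self.in_channels, "length": self.length,
                "n_kernels": self.n_kernels, "kernel_len": self.kernel_len,
                "hidden": self.hidden, "seed": self.seed}

    def _forward(self, X, rng=None):
        Wc, bc = self.params[0], self.params[1]
        if X.shape[1:] != (self.in_channels, self.length):
            raise ValueError(f"expected inputs of shape (n, {self.in_channels}, "
                             f"{self.length}), got {X.shape}")
        win = np.lib.stride_tricks.sliding_window_view(X, self.kernel_len, axis=2)
        # win: (batch, channels, positions, kernel_len)
        z = np.einsum("bcpk,fck->bpf", win, Wc) + bc
        zr = np.maximum(z, 0.0)
        argmax = zr.argmax(axis=1)                      # (batch, kernels)
        pooled = np.take_along_axis(zr, argmax[:, None, :], axis=1)[:, 0, :]
        cache = {"win": win, "z": z, "argmax": argmax, "pooled": pooled,
                 "zs": [], "hs": [pooled]}
        a = pooled
        for layer in range(len(self.hidden)):
            W, b = self.params[2 + 2 * layer], self.params[3 + 2 * layer]
            zh = a @ W + b
            a = np.maximum(zh, 0.0)
            cache["zs"].append(zh)
            cache["hs"].append(a)
        out = a @ self.params[-2] + self.params[-1]
        return out, cache

    def _backward(self, cache, dout):
        grads = [None] * len(self.params)
        grads[-2] = cache["hs"][-1].T @ dout
        grads[-1] = dout.sum(axis=0)
        da = dout @ self.params[-2].T
        for layer in reversed(range(len(self.hidden))):
            dz = da * (cache["zs"][layer] > 0)
            grads[2 + 2 * layer] = cache["hs"][layer].T @ dz
            grads[3 + 2 * layer] = dz.sum(axis=0)
            da = dz @ self.params[2 + 2 * layer].T
        dpool = da                                       # (batch, kernels)
        # route gradients to the argmax positions of the relu'd conv map
        argmax = cache["argmax"]
        z_at = np.take_along_axis(cache["z"], argmax[:, None, :], axis=1)[:, 0, :]
        dz_at = dpool * (z_at > 0)                       # relu gate at the max
        batch = np.arange(len(dout))
        # windows at the pooled positions: (batch, kernels, channels, kernel_len)
        win_at = cache["win"].transpose(0, 2, 1, 3)[batch[:, None], argmax]
        grads[0] = np.einsum("bf,bfck->fck", dz_at, win_at)
        grads[1] = dz_at.sum(axis=0)
        return grads
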