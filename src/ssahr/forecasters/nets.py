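"""NumPy network cores with explicit forward/backward passes.

Each core exposes ``init(rng) -> params``, ``forward(params, X) -> (Y,
cache)`` and ``backward(params, cache, dY) -> grads`` where ``X`` has shape
``(batch, lookback, channels)`` and ``Y`` shape ``(batch, out_dim)``.
Gradients are validated against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class RNNCore:
    """Single-layer vanilla RNN (tanh) with a linear read-out on the last
    hidden state: ``h_t = tanh(x_t Wxh + h_{t-1} Whh + bh)``,
    ``y = h_T Why + by``."""

    def __init__(self, n_channels: int, hidden: int, out_dim: int):
        self.c, self.h, self.o = n_channels, hidden, out_dim

    def init(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        c, h, o = self.c, self.h, self.o
        return {
            "Wxh": _uniform(rng, (c, h), c),
            "Whh": _uniform(rng, (h, h), h),
            "bh": np.zeros(h),
            "Why": _uniform(rng, (h, o), h),
            "by": np.zeros(o),
        }

    def forward(self, p: dict, X: np.ndarray):
        B, T, _ = X.shape
        hs = np.zeros((T + 1, B, self.h))
        for t in range(T):
            hs[t + 1] = np.tanh(X[:, t] @ p["Wxh"] + hs[t] @ p["Whh"] + p["bh"])
        Y = hs[T] @ p["Why"] + p["by"]
        return Y, (X, hs)

    def backward(self, p: dict, cache, dY: np.ndarray) -> dict:
        X, hs = cache
        B, T, _ = X.shape
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Why"] = hs[T].T @ dY
        g["by"] = dY.sum(axis=0)
        dh = dY @ p["Why"].T
        for t in range(T - 1, -1, -1):
            da = dh * (1.0 - hs[t + 1] ** 2)
            g["Wxh"] += X[:, t].T @ da
            g["Whh"] += hs[t].T @ da
            g["bh"] += da.sum(axis=0)
            dh = da @ p["Whh"].T
        return g


class LSTMCore:
    """Single-layer LSTM with forget/input/output gates and a candidate
    state, read out linearly from the last hidden state.  Gate order in the
    packed weight matrices is (i, f, o, g)."""

    def __init__(self, n_channels: int, hidden: int, out_dim: int):
        self.c, self.h, self.o = n_channels, hidden, out_dim

    def init(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        c, h, o = self.c, self.h, self.o
        params = {
            "Wx": _uniform(rng, (c, 4 * h), c),
            "Wh": _uniform(rng, (h, 4 * h), h),
            "b": np.zeros(4 * h),
            "Why": _uniform(rng, (h, o), h),
            "by": np.zeros(o),
        }
        params["b"][h : 2 * h] = 1.0  # forget-gate bias: remember by default
        return params

    def forward(self, p: dict, X: np.ndarray):
        B, T, _ = X.shape
        H = self.h
        h_t = np.zeros((B, H))
        c_t = np.zeros((B, H))
        steps = []
        for t in range(T):
            z = X[:, t] @ p["Wx"] + h_t @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            o = _sigmoid(z[:, 2 * H : 3 * H])
            gche = np.tanh(z[:, 3 * H :])
            c_prev = c_t
            c_t = f * c_prev + i * gche
            tc = np.tanh(c_t)
            h_prev = h_t
            h_t = o * tc
            steps.append((i, f, o, gche, c_prev, c_t, tc, h_prev))
        Y = h_t @ p["Why"] + p["by"]
        return Y, (X, steps, h_t)

    def backward(self, p: dict, cache, dY: np.ndarray) -> dict:
        X, steps, h_last = cache
        B, T, _ = X.shape
        H = self.h
        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Why"] = h_last.T @ dY
        g["by"] = dY.sum(axis=0)
        dh = dY @ p["Why"].T
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, o, gche, c_prev, c_t, tc, h_prev = steps[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            di = dc * gche
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                    dg * (1.0 - gche**2),
                ],
                axis=1,
            )
            g["Wx"] += X[:, t].T @ dz
            g["Wh"] += h_prev.T @ dz
            g["b"] += dz.sum(axis=0)
            dh = dz @ p["Wh"].T
            dc = dc * f
        return g


def _elu(z: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(z > 0, z, alpha * (np.expm1(np.minimum(z, 0.0))))


def _elu_grad(z: np.ndarray, alpha: float) -> np.ndarray:
    return np.where(z > 0, 1.0, alpha * np.exp(np.minimum(z, 0.0)))


class CNN1DCore:
    """Two valid 1-D convolution layers with exponential-linear activation,
    average pooling (width 2, stride 2) over time, and a dense read-out on
    the flattened pooled maps (pooling is local, not global, so the phase
    of periodic inputs survives to the dense layer).

    Requires ``lookback >= 2 * (kernel_size - 1) + 2``.
    """

    POOL = 2

    def __init__(self, n_channels: int, filters: int, kernel_size: int,
                 out_dim: int, elu_alpha: float = 1.0, lookback: int | None = None):
        self.c, self.f, self.k, self.o = n_channels, filters, kernel_size, out_dim
        self.alpha = elu_alpha
        if lookback is None:
            raise ValueError("CNN1DCore requires the lookback length")
        t2 = lookback - 2 * (kernel_size - 1)
        self.t_pool = t2 // self.POOL
        if self.t_pool < 1:
            raise ValueError("lookback too short for two conv layers + pooling")

    def init(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        c, f, k, o = self.c, self.f, self.k, self.o
        dense_in = self.t_pool * f
        return {
            "K1": _uniform(rng, (k, c, f), k * c),
            "b1": np.zeros(f),
            "K2": _uniform(rng, (k, f, f), k * f),
            "b2": np.zeros(f),
            "Wd": _uniform(rng, (dense_in, o), dense_in),
            "bd": np.zeros(o),
        }

    @staticmethod
    def _conv(X: np.ndarray, K: np.ndarray, b: np.ndarray) -> np.ndarray:
        # X: (B, T, C); K: (k, C, F) -> (B, T - k + 1, F)
        k = K.shape[0]
        win = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)  # (B, T', C, k)
        return np.einsum("btck,kcf->btf", win, K) + b

    def forward(self, p: dict, X: np.ndarray):
        a = self.alpha
        z1 = self._conv(X, p["K1"], p["b1"])
        a1 = _elu(z1, a)
        z2 = self._conv(a1, p["K2"], p["b2"])
        a2 = _elu(z2, a)
        B = X.shape[0]
        trim = self.t_pool * self.POOL
        pooled = a2[:, :trim].reshape(B, self.t_pool, self.POOL, self.f).mean(axis=2)
        flat = pooled.reshape(B, -1)
        Y = flat @ p["Wd"] + p["bd"]
        return Y, (X, z1, a1, z2, a2, flat)

    def backward(self, p: dict, cache, dY: np.ndarray) -> dict:
        X, z1, a1, z2, a2, flat = cache
        a = self.alpha
        k = self.k
        B = X.shape[0]
        g = {key: np.zeros_like(v) for key, v in p.items()}
        g["Wd"] = flat.T @ dY
        g["bd"] = dY.sum(axis=0)
        dflat = dY @ p["Wd"].T
        dpooled = dflat.reshape(B, self.t_pool, self.f)
        da2 = np.zeros_like(a2)
        trim = self.t_pool * self.POOL
        da2[:, :trim] = np.repeat(dpooled / self.POOL, self.POOL, axis=1)
        dz2 = da2 * _elu_grad(z2, a)
        T2 = a2.shape[1]
        win1 = np.lib.stride_tricks.sliding_window_view(a1, k, axis=1)
        g["K2"] = np.einsum("btck,btf->kcf", win1, dz2)
        g["b2"] = dz2.sum(axis=(0, 1))
        da1 = np.zeros_like(a1)
        for m in range(k):
            da1[:, m : m + T2] += dz2 @ p["K2"][m].T
        dz1 = da1 * _elu_grad(z1, a)
        win0 = np.lib.stride_tricks.sliding_window_view(X, k, axis=1)
        g["K1"] = np.einsum("btck,btf->kcf", win0, dz1)
        g["b1"] = dz1.sum(axis=(0, 1))
        return g


def build_core(spec, n_channels: int, lookback: int, out_dim: int):
    """Instantiate the network core for a :class:`ForecasterSpec`."""
    if spec.family in ("LSTM", "PINN"):
        return LSTMCore(n_channels, spec.hidden_units, out_dim)
    if spec.family == "RNN":
        return RNNCore(n_channels, spec.hidden_units, out_dim)
    if spec.family == "CNN1D":
        min_w = 2 * (spec.kernel_size - 1) + 2
        if lookback < min_w:
            raise ValueError(
                f"CNN1D with kernel_size={spec.kernel_size} requires lookback >= {min_w}"
            )
        return CNN1DCore(n_channels, spec.filters, spec.kernel_size, out_dim,
                         spec.elu_alpha, lookback=lookback)
    raise ValueError(f"unknown family {spec.family!r}")
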