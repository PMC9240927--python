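"""Minimal numpy neural-network engine for the recurrent hazard model.

Implements exactly what the survival model needs: stacked LSTM layers
(unrolled over the N grid intervals), optional batch normalisation,
inverted dropout, a shared dense sigmoid head producing one conditional
hazard per interval, and the Adam optimiser.  Gradients are computed by
hand (backpropagation through time) and are verified against central
finite differences in the test suite.

Everything runs in float64.  The covariate vector is constant across the
unrolled steps (only the normalised time feature varies), so the
input-to-hidden projections are batched over all steps at once and the
per-step loop touches only the recurrent part.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit

__all__ = ["SurvivalNetwork", "Adam"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return _expit(x)


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


class _LSTMLayer:
    """One LSTM layer; gate order is (input, forget, output, candidate),
    so the three sigmoid gates occupy one contiguous block."""

    def __init__(self, d_in: int, width: int, rng: np.random.Generator):
        self.d_in, self.width = d_in, width
        self.Wx = _glorot(rng, (d_in, 4 * width))
        self.Wh = _glorot(rng, (width, 4 * width))
        self.b = np.zeros(4 * width)
        self.b[width : 2 * width] = 1.0  # forget-gate bias

    @property
    def params(self):
        return [self.Wx, self.Wh, self.b]

    @property
    def l2_flags(self):
        return [True, True, False]

    def forward(self, Z: np.ndarray, need_cache: bool):
        B, T, D = Z.shape
        H = self.width
        # input projection batched over all steps; only recurrence loops
        A = (Z.reshape(B * T, D) @ self.Wx + self.b).reshape(B, T, 4 * H)
        out = np.empty((B, T, H))
        C = np.zeros((B, T + 1, H))
        TC = np.empty((B, T, H))
        h = np.zeros((B, H))
        for t in range(T):
            a = A[:, t]
            a += h @ self.Wh
            _expit(a[:, : 3 * H], out=a[:, : 3 * H])
            np.tanh(a[:, 3 * H :], out=a[:, 3 * H :])
            i, f, o, g = a[:, :H], a[:, H : 2 * H], a[:, 2 * H : 3 * H], a[:, 3 * H :]
            np.multiply(f, C[:, t], out=C[:, t + 1])
            C[:, t + 1] += i * g
            np.tanh(C[:, t + 1], out=TC[:, t])
            h = o * TC[:, t]
            out[:, t] = h
        ctx = (Z, A, C, TC, out) if need_cache else (Z,)
        return out, ctx

    def backward(self, dout: np.ndarray, ctx):
        Z, A, C, TC, Hs = ctx
        B, T, D = Z.shape
        H = self.width
        dA = np.empty_like(A)
        dWh = np.zeros_like(self.Wh)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        WhT = self.Wh.T
        for t in range(T - 1, -1, -1):
            a = A[:, t]
            i, f, o, g = a[:, :H], a[:, H : 2 * H], a[:, 2 * H : 3 * H], a[:, 3 * H :]
            tc = TC[:, t]
            dh = dout[:, t] + dh_next
            do = dh * tc
            dtc = dh * o * (1.0 - tc * tc)
            dtc += dc_next
            dc_next = dtc * f
            da = dA[:, t]
            np.multiply(dtc * g, i * (1.0 - i), out=da[:, :H])
            np.multiply(dtc * C[:, t], f * (1.0 - f), out=da[:, H : 2 * H])
            np.multiply(do, o * (1.0 - o), out=da[:, 2 * H : 3 * H])
            np.multiply(dtc * i, 1.0 - g * g, out=da[:, 3 * H :])
            if t > 0:
                dWh += Hs[:, t - 1].T @ da
            dh_next = da @ WhT
        dA2 = dA.reshape(B * T, 4 * H)
        dWx = Z.reshape(B * T, D).T @ dA2
        db = dA2.sum(axis=0)
        dZ = (dA2 @ self.Wx.T).reshape(B, T, D)
        return dZ, [dWx, dWh, db]


class _BatchNorm:
    """Feature-wise normalisation, statistics pooled over batch and time."""

    def __init__(self, width: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(width)
        self.beta = np.zeros(width)
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self.momentum = momentum
        self.eps = eps

    @property
    def params(self):
        return [self.gamma, self.beta]

    @property
    def l2_flags(self):
        return [False, False]

    def forward(self, Z: np.ndarray, train: bool, need_cache: bool):
        B, T, H = Z.shape
        x = Z.reshape(B * T, H)
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean) / std
        out = (self.gamma * xhat + self.beta).reshape(B, T, H)
        ctx = (xhat, std, Z.shape, train) if need_cache else None
        return out, ctx

    def backward(self, dout: np.ndarray, ctx):
        xhat, std, shape, train = ctx
        B, T, H = shape
        d = dout.reshape(B * T, H)
        dgamma = (d * xhat).sum(axis=0)
        dbeta = d.sum(axis=0)
        if train:
            dx = (self.gamma / std) * (
                d - d.mean(axis=0) - xhat * (d * xhat).mean(axis=0)
            )
        else:
            dx = d * (self.gamma / std)
        return dx.reshape(B, T, H), [dgamma, dbeta]


class SurvivalNetwork:
    """Stacked LSTM -> (batch norm) -> (dropout), shared sigmoid hazard head.

    ``forward(X)`` unrolls ``n_intervals`` steps; the step-t input is the
    covariate vector concatenated with the normalised interval value
    ``t / N`` and the output is one conditional hazard per step.
    """

    HEAD_BIAS_INIT = -3.0  # start near a plausible small hazard, sigmoid(-3)~0.047

    def __init__(
        self,
        n_features: int,
        n_intervals: int,
        layer_widths: list[int],
        use_batch_norm: bool = True,
        dropout_rate: float = 0.0,
        seed: int = 0,
    ):
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        if not layer_widths:
            raise ValueError("layer_widths must be a non-empty list")
        if any(w < 1 for w in layer_widths):
            raise ValueError("layer widths must be positive")
        self.n_features = n_features
        self.n_intervals = n_intervals
        self.layer_widths = list(layer_widths)
        self.use_batch_norm = use_batch_norm
        self.dropout_rate = float(dropout_rate)
        rng = np.random.default_rng(seed)
        self.layers: list[tuple[_LSTMLayer, _BatchNorm | None]] = []
        d_in = n_features + 1  # + normalised time feature
        for w in layer_widths:
            lstm = _LSTMLayer(d_in, w, rng)
            bn = _BatchNorm(w) if use_batch_norm else None
            self.layers.append((lstm, bn))
            d_in = w
        self.head_W = _glorot(rng, (d_in, 1))
        self.head_b = np.array([self.HEAD_BIAS_INIT])

    # -- parameter bookkeeping -----------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for lstm, bn in self.layers:
            out.extend(lstm.params)
            if bn is not None:
                out.extend(bn.params)
        out.extend([self.head_W, self.head_b])
        return out

    @property
    def l2_flags(self) -> list[bool]:
        out = []
        for lstm, bn in self.layers:
            out.extend(lstm.l2_flags)
            if bn is not None:
                out.extend(bn.l2_flags)
        out.extend([True, False])
        return out

    def get_state(self) -> list[np.ndarray]:
        state = [p.copy() for p in self.params]
        for _, bn in self.layers:
            if bn is not None:
                state.extend([bn.running_mean.copy(), bn.running_var.copy()])
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params
        for p, s in zip(ps, state[: len(ps)]):
            p[...] = s
        extra = state[len(ps) :]
        j = 0
        for _, bn in self.layers:
            if bn is not None:
                bn.running_mean[...] = extra[j]
                bn.running_var[...] = extra[j + 1]
                j += 2

    # -- forward / backward --------------------------------------------
    def _stack_input(self, X: np.ndarray) -> np.ndarray:
        B = X.shape[0]
        T = self.n_intervals
        Z = np.empty((B, T, self.n_features + 1))
        Z[:, :, : self.n_features] = X[:, None, :]
        Z[:, :, self.n_features] = (np.arange(1, T + 1) / T)[None, :]
        return Z

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
        need_cache: bool = False,
    ):
        Z = self._stack_input(np.asarray(X, dtype=float))
        caches = []
        for lstm, bn in self.layers:
            Z, ctx = lstm.forward(Z, need_cache)
            mask = None
            bn_ctx = None
            if bn is not None:
                Z, bn_ctx = bn.forward(Z, train, need_cache)
            if train and self.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng for dropout")
                mask = (rng.random(Z.shape) >= self.dropout_rate) / (1.0 - self.dropout_rate)
                Z = Z * mask
            caches.append((ctx, bn_ctx, mask))
        B, T, H = Z.shape
        logits = (Z.reshape(B * T, H) @ self.head_W + self.head_b).reshape(B, T)
        hazards = _sigmoid(logits)
        if not need_cache:
            return hazards, None
        return hazards, (caches, Z, hazards)

    def backward(self, d_hazards: np.ndarray, cache) -> list[np.ndarray]:
        """Gradients of the loss w.r.t. all params, given dL/d(hazards)."""
        caches, Z_last, hazards = cache
        B, T = d_hazards.shape
        H = Z_last.shape[2]
        dlogits = d_hazards * hazards * (1.0 - hazards)
        dl2 = dlogits.reshape(B * T, 1)
        d_head_W = Z_last.reshape(B * T, H).T @ dl2
        d_head_b = dl2.sum(axis=0)
        dZ = (dl2 @ self.head_W.T).reshape(B, T, H)
        grads_rev: list[np.ndarray] = [d_head_W, d_head_b]
        layer_grads: list[list[np.ndarray]] = []
        for (lstm, bn), (ctx, bn_ctx, mask) in zip(
            reversed(self.layers), reversed(caches)
        ):
            g: list[np.ndarray] = []
            if mask is not None:
                dZ = dZ * mask
            if bn is not None:
                dZ, bn_g = bn.backward(dZ, bn_ctx)
                g = bn_g
            dZ, lstm_g = lstm.backward(dZ, ctx)
            layer_grads.append(lstm_g + g)
        grads: list[np.ndarray] = []
        for g in reversed(layer_grads):
            grads.extend(g)
        grads.extend(grads_rev)
        return grads

    def predict(self, X: np.ndarray, chunk: int = 4096) -> np.ndarray:
        """Evaluation-mode hazards (dropout off, running BN statistics)."""
        X = np.asarray(X, dtype=float)
        outs = []
        for start in range(0, X.shape[0], chunk):
            h, _ = self.forward(X[start : start + chunk], train=False)
            outs.append(h)
        return np.vstack(outs)


class Adam:
    """Adam optimiser with optional L2 penalty on weight matrices."""

    def __init__(
        self,
        params: list[np.ndarray],
        l2_flags: list[bool],
        lr: float = 0.001,
        l2: float = 0.0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.l2_flags = l2_flags
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v, reg in zip(self.params, grads, self.m, self.v, self.l2_flags):
            if reg and self.l2 > 0:
                g = g + 2.0 * self.l2 * p
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
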