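"""Minimal NumPy neural-network layer: batched masked LSTM and Adam.

Only what the amortized encoder needs — a stacked LSTM over variable-length
sequences (mask semantics: for padded steps the hidden/cell state is carried
through unchanged, so the final state equals the state at each sequence's
true last step) and an Adam optimizer. Forward passes cache everything the
analytic backward pass needs; gradients are exact (verified against finite
differences in the test suite).
"""

from __future__ import annotations

import numpy as np

__all__ = ["softplus", "softplus_inv", "LSTMStack", "Adam", "init_uniform_fan_in"]


def softplus(x):
    x = np.asarray(x, dtype=float)
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    # inverse of softplus for y > 0
    y = np.asarray(y, dtype=float)
    return y + np.log(-np.expm1(-y))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def init_uniform_fan_in(rng, shape, fan_in):
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class LSTMStack:
    """Stacked LSTM over (N, T, F) inputs with per-sequence lengths.

    Gate layout along the last parameter axis is (input, forget, cell, output).
    Parameters live in ``self.params`` as a flat dict so an optimizer can
    treat them uniformly.
    """

    def __init__(self, n_features: int, hidden_dim: int, n_layers: int = 1,
                 rng: np.random.Generator | None = None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.n_features = n_features
        self.hidden_dim = hidden_dim
        self.n_layers = n_layers
        self.params: dict[str, np.ndarray] = {}
        for layer in range(n_layers):
            f_in = n_features if layer == 0 else hidden_dim
            self.params[f"W{layer}"] = init_uniform_fan_in(rng, (f_in, 4 * hidden_dim), hidden_dim)
            self.params[f"U{layer}"] = init_uniform_fan_in(rng, (hidden_dim, 4 * hidden_dim), hidden_dim)
            b = init_uniform_fan_in(rng, (4 * hidden_dim,), hidden_dim)
            # forget-gate bias offset: standard trick for gradient flow early on
            b[hidden_dim:2 * hidden_dim] += 1.0
            self.params[f"b{layer}"] = b

    def forward(self, X: np.ndarray, lengths: np.ndarray):
        """Run the stack; returns the final hidden state of the top layer.

        Returns ``(h_final (N, H), cache)``; ``cache`` feeds :meth:`backward`.
        """
        N, T, _ = X.shape
        H = self.hidden_dim
        lengths = np.asarray(lengths)
        caches = []
        inp = X
        for layer in range(self.n_layers):
            W, U, b = (self.params[f"{k}{layer}"] for k in "WUb")
            h = np.zeros((N, H))
            c = np.zeros((N, H))
            steps = []
            outs = np.empty((N, T, H))
            for t in range(T):
                m = (t < lengths).astype(float)[:, None]
                x_t = inp[:, t, :]
                a = x_t @ W + h @ U + b
                i = _sigmoid(a[:, :H])
                f = _sigmoid(a[:, H:2 * H])
                g = np.tanh(a[:, 2 * H:3 * H])
                o = _sigmoid(a[:, 3 * H:])
                c_new = f * c + i * g
                tc = np.tanh(c_new)
                h_new = o * tc
                steps.append((x_t, h, c, i, f, g, o, c_new, tc, m))
                c = m * c_new + (1.0 - m) * c
                h = m * h_new + (1.0 - m) * h
                outs[:, t, :] = h
            caches.append((steps, inp))
            inp = outs
        return h, (caches, lengths, X.shape)

    def backward(self, cache, dh_final: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. all parameters, given d loss/d h_final."""
        caches, lengths, (N, T, _) = cache
        H = self.hidden_dim
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        d_out = None  # gradient w.r.t. the full output sequence of the layer above
        for layer in range(self.n_layers - 1, -1, -1):
            steps, inp = caches[layer]
            W, U = self.params[f"W{layer}"], self.params[f"U{layer}"]
            dW, dU, db = grads[f"W{layer}"], grads[f"U{layer}"], grads[f"b{layer}"]
            dh = dh_final.copy() if layer == self.n_layers - 1 else np.zeros((N, H))
            dc = np.zeros((N, H))
            d_inp = np.zeros((N, T, inp.shape[2]))
            for t in range(T - 1, -1, -1):
                if d_out is not None:
                    dh = dh + d_out[:, t, :]
                x_t, h_prev, c_prev, i, f, g, o, c_new, tc, m = steps[t]
                dh_new = m * dh
                dh_carry = (1.0 - m) * dh
                dc_new = m * dc + dh_new * o * (1.0 - tc * tc)
                dc_carry = (1.0 - m) * dc
                do = dh_new * tc
                di = dc_new * g
                df = dc_new * c_prev
                dg = dc_new * i
                dc_prev = dc_new * f + dc_carry
                da = np.concatenate(
                    [di * i * (1.0 - i), df * f * (1.0 - f),
                     dg * (1.0 - g * g), do * o * (1.0 - o)], axis=1)
                dW += x_t.T @ da
                dU += h_prev.T @ da
                db += da.sum(axis=0)
                d_inp[:, t, :] = da @ W.T
                dh = dh_carry + da @ U.T
                dc = dc_prev
            d_out = d_inp
        return grads


class Adam:
    """Adam with bias correction over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 10.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        if self.clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if total > self.clip_norm:
                scale = self.clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            self.params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
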