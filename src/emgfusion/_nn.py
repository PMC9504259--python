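"""Minimal neural-network primitives (numpy).

Convolution uses im2col with BLAS matmuls; the LSTM is a standard
four-gate cell unrolled with backpropagation through time.  Everything
is deterministic given a seeded ``numpy.random.Generator``.  Gradients
are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Adam",
    "softmax",
    "softmax_cross_entropy",
    "conv2d_forward",
    "conv2d_backward",
    "avgpool2_forward",
    "avgpool2_backward",
    "relu_forward",
    "relu_backward",
    "lstm_forward",
    "lstm_backward",
]


class Adam:
    """Adam with decoupled-from-nothing classic L2 (penalty added to the gradient)."""

    def __init__(self, params: dict, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float, weight_decay: float = 0.0) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, p in params.items():
            g = grads[k]
            if weight_decay:
                g = g + weight_decay * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, probs, dlogits)."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    d = probs.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, probs, d / n


# ---------------------------------------------------------------------------
# convolution / pooling (NCHW)

def conv2d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int = 1, pad: int = 1):
    B, C, H, Wd = x.shape
    F, _, kh, kw = W.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    Ho = (H + 2 * pad - kh) // stride + 1
    Wo = (Wd + 2 * pad - kw) // stride + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(B * Ho * Wo, C * kh * kw)
    out = cols @ W.reshape(F, -1).T + b
    out = out.reshape(B, Ho, Wo, F).transpose(0, 3, 1, 2)
    cache = (cols, x.shape, W, stride, pad, Ho, Wo)
    return out, cache


def conv2d_backward(dout: np.ndarray, cache):
    cols, xshape, W, stride, pad, Ho, Wo = cache
    B, C, H, Wd = xshape
    F, _, kh, kw = W.shape
    d = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(B * Ho * Wo, F)
    dW = (d.T @ cols).reshape(W.shape)
    db = d.sum(axis=0)
    dcols = (d @ W.reshape(F, -1)).reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    dxp = np.zeros((B, C, H + 2 * pad, Wd + 2 * pad))
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + Ho * stride : stride, j : j + Wo * stride : stride] += dcols[
                :, :, :, :, i, j
            ]
    dx = dxp[:, :, pad : pad + H, pad : pad + Wd] if pad else dxp
    return dx, dW, db


def avgpool2_forward(x: np.ndarray):
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"avgpool2 needs even spatial dims, got {H}x{W}")
    out = x.reshape(B, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    return out, x.shape


def avgpool2_backward(dout: np.ndarray, xshape):
    B, C, H, W = xshape
    d = dout[:, :, :, None, :, None] / 4.0
    return np.broadcast_to(d, (B, C, H // 2, 2, W // 2, 2)).reshape(B, C, H, W)


def relu_forward(x: np.ndarray):
    mask = x > 0
    return x * mask, mask


def relu_backward(dout: np.ndarray, mask) -> np.ndarray:
    return dout * mask


# ---------------------------------------------------------------------------
# LSTM (single direction; gate order i, f, g, o)

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def lstm_forward(x: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Run an LSTM over ``x`` of shape (T, B, D); returns final hidden state.

    ``Wx`` is (D, 4H), ``Wh`` is (H, 4H), ``b`` is (4H,).  Returns
    ``(h_T, cache)`` where ``h_T`` is (B, H).
    """
    T, B, D = x.shape
    H = Wh.shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    steps = []
    for t in range(T):
        z = x[t] @ Wx + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c_next = f * c + i * g
        h_next = o * np.tanh(c_next)
        steps.append((x[t], h, c, i, f, g, o, c_next))
        h, c = h_next, c_next
    return h, (steps, Wx, Wh, H)


def lstm_backward(dh_T: np.ndarray, cache):
    """BPTT from a gradient on the final hidden state only (sequence-to-one)."""
    steps, Wx, Wh, H = cache
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh = dh_T.copy()
    dc = np.zeros_like(dh_T)
    dx = [None] * len(steps)
    for t in reversed(range(len(steps))):
        x_t, h_prev, c_prev, i, f, g, o, c_next = steps[t]
        tc = np.tanh(c_next)
        do = dh * tc
        dc = dc + dh * o * (1 - tc * tc)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)], axis=1
        )
        dWx += x_t.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dx[t] = dz @ Wx.T
        dh = dz @ Wh.T
        dc = dc * f
    return np.stack(dx), dWx, dWh, db
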