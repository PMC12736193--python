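"""Minimal numpy neural-network primitives shared by the CLM and the RCNN.

Manual forward/backward passes; parameters live in flat name->array dicts.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

SQRT_2 = np.sqrt(2.0)
INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / SQRT_2))


def gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / SQRT_2)) + x * INV_SQRT_2PI * np.exp(-0.5 * x * x)


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def layernorm_forward(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def layernorm_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    m1 = dxhat.mean(axis=-1, keepdims=True)
    m2 = (dxhat * xhat).mean(axis=-1, keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dg, db


class AdamW:
    """Adam with decoupled weight decay; decay skipped for 1-D parameters."""

    def __init__(self, params, lr=5e-4, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.1):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads, lr=None):
        lr = self.lr if lr is None else lr
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            upd = mhat / (np.sqrt(vhat) + self.eps)
            if p.ndim > 1 and self.weight_decay:
                upd = upd + self.weight_decay * p
            p -= lr * upd


class RMSprop:
    """Plain RMSprop (rho=0.9), matching the common deep-learning default."""

    def __init__(self, params, lr=1e-3, rho=0.9, eps=1e-7):
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.cache = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params, grads):
        for k, p in params.items():
            g = grads[k]
            self.cache[k] = self.rho * self.cache[k] + (1 - self.rho) * g * g
            p -= self.lr * g / (np.sqrt(self.cache[k]) + self.eps)


def cosine_warmup_lr(step: int, base_lr: float, warmup_steps: int, total_steps: int) -> float:
    """Linear warmup then cosine decay to zero over the optimizer steps."""
    if warmup_steps > 0 and step < warmup_steps:
        return base_lr * (step + 1) / warmup_steps
    span = max(total_steps - warmup_steps, 1)
    progress = min(max(step - warmup_steps, 0) / span, 1.0)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * progress))
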