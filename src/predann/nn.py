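"""Minimal neural-network layer kit on reverse-mode automatic differentiation.

All layers are pure functions of (parameters, inputs) built from
autograd-differentiable numpy primitives, so a whole paired-encoder model
is just a nested dict of ndarrays plus a forward function.  This keeps
training fully deterministic given a seed and makes gradient-flow
contracts (notably the stop-gradient on the stimulus branch) directly
testable with `autograd.grad`.
"""

from __future__ import annotations

import numpy as np
import autograd.numpy as anp
from autograd.extend import defvjp, primitive
from autograd.misc import flatten


@primitive
def stop_gradient(x):
    """Identity in the forward pass; blocks all gradient flow backward.

    Everything upstream of a ``stop_gradient`` receives an exactly-zero
    cotangent, not a small one: the contribution is removed from the
    computational graph, which is what the contrastive objective here
    requires on the stimulus branch.
    """
    return x


defvjp(stop_gradient, lambda ans, x: lambda g: anp.zeros_like(x))


def relu(x):
    return anp.maximum(x, 0.0)


def conv1d(x, w, b=None, padding=1):
    """Temporal convolution (cross-correlation) with stride 1.

    x: [B, C_in, T]; w: [C_out, C_in, K]; returns [B, C_out, T_out] where
    T_out = T + 2*padding - K + 1 (equal to T for K=3, padding=1).
    """
    K = w.shape[2]
    if padding:
        x = anp.pad(x, ((0, 0), (0, 0), (padding, padding)), mode="constant")
    T_out = x.shape[2] - K + 1
    if T_out < 1:
        raise ValueError(f"input too short for kernel {K} (padded length {x.shape[2]})")
    out = 0.0
    for k in range(K):
        # [B, T_out, C_out] accumulated one kernel tap at a time
        out = out + anp.tensordot(x[:, :, k : k + T_out], w[:, :, k], axes=([1], [1]))
    out = anp.transpose(out, (0, 2, 1))
    if b is not None:
        out = out + b[None, :, None]
    return out


def conv2d(x, w, b=None, padding=1):
    """2-D convolution with stride 1; x: [B, C_in, H, W], w: [C_out, C_in, KH, KW]."""
    KH, KW = w.shape[2], w.shape[3]
    if padding:
        x = anp.pad(
            x, ((0, 0), (0, 0), (padding, padding), (padding, padding)), mode="constant"
        )
    H_out = x.shape[2] - KH + 1
    W_out = x.shape[3] - KW + 1
    if H_out < 1 or W_out < 1:
        raise ValueError("input smaller than kernel after padding")
    out = 0.0
    for i in range(KH):
        for j in range(KW):
            patch = x[:, :, i : i + H_out, j : j + W_out]
            out = out + anp.tensordot(patch, w[:, :, i, j], axes=([1], [1]))
    out = anp.transpose(out, (0, 3, 1, 2))
    if b is not None:
        out = out + b[None, :, None, None]
    return out


def avg_pool1d(x, pool):
    """Non-overlapping average pooling over the last axis (trailing remainder dropped)."""
    if pool <= 1:
        return x
    B, C, T = x.shape
    T2 = (T // pool) * pool
    if T2 == 0:
        raise ValueError(f"cannot pool length {T} by {pool}")
    return anp.mean(anp.reshape(x[:, :, :T2], (B, C, T2 // pool, pool)), axis=3)


def avg_pool2d(x, pool_h, pool_w):
    B, C, H, W = x.shape
    ph = min(pool_h, H) if pool_h > 1 else 1
    pw = min(pool_w, W) if pool_w > 1 else 1
    H2, W2 = (H // ph) * ph, (W // pw) * pw
    x = x[:, :, :H2, :W2]
    x = anp.reshape(x, (B, C, H2 // ph, ph, W2 // pw, pw))
    return anp.mean(x, axis=(3, 5))


def linear(x, w, b):
    """x: [B, d_in]; w: [d_in, d_out]."""
    return anp.dot(x, w) + b


def he_init(rng, shape, fan_in):
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


def log_softmax(z, axis=-1):
    z = z - stop_gradient(anp.max(z, axis=axis, keepdims=True))
    return z - anp.log(anp.sum(anp.exp(z), axis=axis, keepdims=True))


def softmax(z, axis=-1):
    z = np.asarray(z, dtype=float)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def tree_copy(params):
    if isinstance(params, dict):
        return {k: tree_copy(v) for k, v in params.items()}
    return np.array(params, copy=True)


def parameter_count(params) -> int:
    flat, _ = flatten(params)
    return int(flat.size)


class Adam:
    """Adam optimizer over an arbitrary nested dict of ndarrays."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        flat, self._unflatten = flatten(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = np.zeros_like(flat)
        self.v = np.zeros_like(flat)
        self.t = 0

    def step(self, params, grads):
        x, unflatten = flatten(params)
        g, _ = flatten(grads)
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * g
        self.v = self.beta2 * self.v + (1 - self.beta2) * g * g
        mhat = self.m / (1 - self.beta1**self.t)
        vhat = self.v / (1 - self.beta2**self.t)
        x = x - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return unflatten(x)
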