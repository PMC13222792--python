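"""Activations and losses."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor


def mish(x: Tensor | np.ndarray):
    """Mish activation, x * tanh(softplus(x)), overflow-safe."""
    if isinstance(x, Tensor):
        return x * x.softplus().tanh()
    z = np.asarray(x, dtype=np.float64)
    sp = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    return z * np.tanh(sp)


def silu(x: Tensor | np.ndarray):
    """SiLU (swish) activation, x * sigmoid(x)."""
    if isinstance(x, Tensor):
        return x * x.sigmoid()
    z = np.asarray(x, dtype=np.float64)
    return z / (1.0 + np.exp(-np.clip(z, -60, 60)))


def softplus_np(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def log_softmax(logits: Tensor) -> Tensor:
    """Numerically stable log-softmax over the last axis."""
    zmax = Tensor(np.max(logits.data, axis=-1, keepdims=True))  # detached shift
    shifted = logits - zmax
    lse = shifted.exp().sum(axis=-1, keepdims=True).log()
    return shifted - lse


def softmax_np(logits: np.ndarray) -> np.ndarray:
    z = logits - np.max(logits, axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(logits: Tensor, y: np.ndarray,
                           class_weights: np.ndarray | None = None) -> Tensor:
    """Weighted categorical cross-entropy, mean-reduced over the batch.

    ``y`` is an integer label vector; ``class_weights`` the per-class factor
    w_i (uniform weights reduce to standard cross-entropy).  Computed via
    log-sum-exp, so a zero predicted probability never hits log(0).
    """
    n, k = logits.shape
    logp = log_softmax(logits)
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    w = np.ones(k) if class_weights is None else np.asarray(class_weights)
    picked = (logp * Tensor(onehot * w[None, :])).sum(axis=-1)
    return -picked.mean()
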