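"""Selective-scan primitives for the diagonal state-space recurrence.

The recurrence  h_t = a_t * h_{t-1} + b_t  (elementwise over a state axis)
is evaluated with an associative parallel (Hillis-Steele doubling) scan in
O(T log T) work and O(log T) depth of vector operations -- mathematically
identical to the sequential loop.  The backward pass is the adjoint
recurrence  g_t = dh_t + a_{t+1} * g_{t+1}, itself another scan.

``discretize`` maps the continuous parameters (Delta, A, B) to their
discrete counterparts; two rules are available:

* ``as_printed``: A_bar = exp(Delta*A),  B_bar = (Delta*B) * softplus(Delta)
* ``euler``:      A_bar = exp(Delta*A),  B_bar = Delta*B
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .functional import softplus_np

DISCRETIZATION_MODES = ("as_printed", "euler")


def _scan_forward(a: np.ndarray, b: np.ndarray, axis: int = 1):
    """Inclusive first-order scan along ``axis`` via doubling."""
    h = b.copy()
    A = a.copy()
    T = a.shape[axis]
    offset = 1

    def shifted(arr, off):
        sl = [slice(None)] * arr.ndim
        sl[axis] = slice(0, arr.shape[axis] - off)
        return arr[tuple(sl)]

    def tail(arr, off):
        sl = [slice(None)] * arr.ndim
        sl[axis] = slice(off, None)
        return arr[tuple(sl)]

    while offset < T:
        h_prev = shifted(h, offset).copy()
        A_prev = shifted(A, offset).copy()
        tail(h, offset)[...] += tail(A, offset) * h_prev
        tail(A, offset)[...] *= A_prev
        offset *= 2
    return h


def scan_sequential(a: np.ndarray, b: np.ndarray, axis: int = 1) -> np.ndarray:
    """Reference sequential recurrence (the oracle the parallel scan must match)."""
    a = np.moveaxis(a, axis, 0)
    b = np.moveaxis(b, axis, 0)
    h = np.zeros_like(b)
    state = np.zeros_like(b[0])
    for t in range(a.shape[0]):
        state = a[t] * state + b[t]
        h[t] = state
    return np.moveaxis(h, 0, axis)


def selective_scan(a: Tensor, b: Tensor) -> Tensor:
    """Differentiable scan over axis 1 of (..., T, ...) shaped tensors.

    ``a`` and ``b`` must share a shape of the form (B, T, ...); returns the
    hidden-state sequence h with h_0 = 0 convention (h_1 = a_1*0 + b_1).
    Rejects non-finite parameters.
    """
    if not (np.all(np.isfinite(a.data)) and np.all(np.isfinite(b.data))):
        raise ValueError("non-finite scan parameters")
    h = _scan_forward(a.data, b.data, axis=1)

    def bw(g):
        g = np.asarray(g)
        T = g.shape[1]
        # adjoint: g_t = dh_t + a_{t+1} g_{t+1}  (reverse-time scan)
        dh_rev = g[:, ::-1]
        a_rev = a.data[:, ::-1]
        ones = np.ones_like(a_rev[:, :1])
        coeff = np.concatenate([ones, a_rev[:, :-1]], axis=1)
        g_rev = _scan_forward(coeff, dh_rev, axis=1)
        gfull = g_rev[:, ::-1]
        b._accum(gfull)
        h_prev = np.concatenate([np.zeros_like(h[:, :1]), h[:, :-1]], axis=1)
        a._accum(gfull * h_prev)
    return Tensor._make(h, (a, b), bw)


def discretize(delta, A, B, mode: str = "as_printed"):
    """Discretize diagonal SSM parameters.

    Shapes: delta (..., d), A (d, N), B (..., N); returns
    (A_bar, B_bar) with shape (..., d, N).  Works on numpy arrays or
    ``Tensor``s (autograd flows through).
    """
    if mode not in DISCRETIZATION_MODES:
        raise ValueError(f"mode must be one of {DISCRETIZATION_MODES}")
    is_tensor = isinstance(delta, Tensor)
    if is_tensor:
        dA = delta.reshape(*delta.shape, 1) * A        # (...,d,N)
        a_bar = dA.exp()
        dB = delta.reshape(*delta.shape, 1) * B.reshape(*B.shape[:-1], 1, B.shape[-1])
        if mode == "as_printed":
            b_bar = dB * delta.softplus().reshape(*delta.shape, 1)
        else:
            b_bar = dB
        return a_bar, b_bar
    delta = np.asarray(delta, dtype=np.float64)
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    a_bar = np.exp(delta[..., None] * A)
    b_bar = delta[..., None] * B[..., None, :]
    if mode == "as_printed":
        b_bar = b_bar * softplus_np(delta)[..., None]
    return a_bar, b_bar
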