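"""Mamba-style block: gated selective state-space sequence layer.

Structure per block (pre-norm residual, as in Eq.-style formulations that
apply a second normalization after the residual sum):

    out = LayerNorm(h_in + inner(LayerNorm(h_in)))

where ``inner`` expands channels by a factor of 2, mixes locally with a
causal depthwise convolution (kernel 4), gates with SiLU, and runs the
input-selective diagonal SSM via the parallel scan.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .functional import silu
from .layers import LayerNorm, Linear, Module, Parameter
from .scan import discretize, selective_scan


class SelectiveSSM(Module):
    """Diagonal selective SSM: per-channel state of dimension N."""

    def __init__(self, d_inner: int, d_state: int, rng: np.random.Generator,
                 mode: str = "as_printed"):
        super().__init__()
        self.d_inner, self.d_state, self.mode = d_inner, d_state, mode
        # real negative transition init: A = -(1..N) per channel
        self.A_log = Parameter(np.log(np.tile(np.arange(1, d_state + 1,
                                                        dtype=np.float64),
                                              (d_inner, 1))))
        self.D = Parameter(np.ones(d_inner))
        self.x_proj = Linear(d_inner, 2 * d_state, rng, bias=False)
        self.dt_proj = Linear(d_inner, d_inner, rng)
        # softplus(bias) spans roughly [1e-3, 1e-1] at init
        self.dt_proj.bias.data = np.log(np.expm1(
            np.exp(rng.uniform(np.log(1e-3), np.log(1e-1), d_inner))))

    def __call__(self, x: Tensor) -> Tensor:
        Bsz, T, d = x.shape
        N = self.d_state
        delta = self.dt_proj(x).softplus()                 # (B,T,d) > 0
        bc = self.x_proj(x)                                # (B,T,2N)
        Bmat = bc[:, :, :N]
        Cmat = bc[:, :, N:]
        A = -(self.A_log.exp())                            # (d,N), negative
        a_bar, b_bar = discretize(delta, A, Bmat, self.mode)
        u = x.reshape(Bsz, T, d, 1)
        h = selective_scan(a_bar, b_bar * u)               # (B,T,d,N)
        y = (h * Cmat.reshape(Bsz, T, 1, N)).sum(axis=-1)  # (B,T,d)
        return y + x * self.D


class CausalDepthwiseConv(Module):
    """Depthwise 1-D convolution over time, left-padded so step t sees <= t."""

    def __init__(self, d: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.k = k
        bound = 1.0 / np.sqrt(k)
        self.weight = Parameter(rng.uniform(-bound, bound, (k, d)))
        self.bias = Parameter(np.zeros(d))

    def __call__(self, x: Tensor) -> Tensor:
        B, T, d = x.shape
        xp = x.pad(((0, 0), (self.k - 1, 0), (0, 0)))
        terms = [xp[:, i:i + T, :] * self.weight[i] for i in range(self.k)]
        out = terms[0]
        for t in terms[1:]:
            out = out + t
        return out + self.bias


class MambaBlock(Module):
    def __init__(self, d_model: int, rng: np.random.Generator,
                 d_state: int = 16, expand: int = 2, d_conv: int = 4,
                 mode: str = "as_printed"):
        super().__init__()
        d_inner = expand * d_model
        self.norm_in = LayerNorm(d_model)
        self.norm_out = LayerNorm(d_model)
        self.in_proj = Linear(d_model, 2 * d_inner, rng, bias=False)
        self.conv = CausalDepthwiseConv(d_inner, d_conv, rng)
        self.ssm = SelectiveSSM(d_inner, d_state, rng, mode)
        self.out_proj = Linear(d_inner, d_model, rng, bias=False)
        self.d_inner = d_inner

    def __call__(self, h_in: Tensor) -> Tensor:
        x = self.norm_in(h_in)
        xz = self.in_proj(x)
        xs = xz[:, :, :self.d_inner]
        z = xz[:, :, self.d_inner:]
        xs = silu(self.conv(xs))
        y = self.ssm(xs)
        y = y * silu(z)
        return self.norm_out(h_in + self.out_proj(y))
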