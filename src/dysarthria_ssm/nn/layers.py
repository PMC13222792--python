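"""Neural-network layers on the numpy autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, _unbroadcast


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, RNG for dropout."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for m in v:
                    if isinstance(m, Module):
                        yield m
                        yield from m.modules()

    def named_parameters(self, prefix=""):
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield from v.named_parameters(name + ".")
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield from m.named_parameters(f"{name}.{i}.")
                    elif isinstance(m, Parameter):
                        yield f"{name}.{i}", m

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.named_parameters():
            p.data = np.asarray(state[k], dtype=np.float64).reshape(p.data.shape)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = 1.0 / np.sqrt(d_in)
        self.weight = Parameter(rng.uniform(-bound, bound, (d_in, d_out)))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    """3x3 (or kxk), stride 1, same padding, via sliding windows + matmul."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 3):
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, k
        bound = 1.0 / np.sqrt(c_in * k * k)
        self.weight = Parameter(rng.uniform(-bound, bound, (c_out, c_in, k, k)))
        self.bias = Parameter(np.zeros(c_out))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.c_in:
            raise ValueError(
                f"expected {self.c_in} input channels, got {x.shape[1]}")
        return _conv2d(x, self.weight, self.bias, self.k)


def _windows(arr: np.ndarray, k: int) -> np.ndarray:
    # (B,C,H+k-1,W+k-1) -> (B,C,H,W,k,k)
    return np.lib.stride_tricks.sliding_window_view(arr, (k, k), axis=(2, 3))


def _conv2d(x: Tensor, w: Tensor, b: Tensor, k: int) -> Tensor:
    pad = k // 2
    B, C, H, W = x.shape
    O = w.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = _windows(xp, k)                       # (B,C,H,W,k,k)
    cols_m = cols.transpose(0, 2, 3, 1, 4, 5).reshape(B, H * W, C * k * k)
    wm = w.data.reshape(O, C * k * k)
    out = (cols_m @ wm.T).reshape(B, H, W, O).transpose(0, 3, 1, 2)
    out = out + b.data[None, :, None, None]

    def bw(g):
        gm = g.transpose(0, 2, 3, 1).reshape(B, H * W, O)     # (B,HW,O)
        gw = np.einsum("bpo,bpc->oc", gm, cols_m).reshape(w.data.shape)
        w._accum(gw)
        b._accum(g.sum(axis=(0, 2, 3)))
        gcols = gm @ wm                                        # (B,HW,Ckk)
        gcols = gcols.reshape(B, H, W, C, k, k)
        gx = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + H, j:j + W] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        x._accum(gx[:, :, pad:pad + H, pad:pad + W])
    return Tensor._make(out, (x, w, b), bw)


class MaxPool2d(Module):
    """2x2, stride 2."""

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("spatial dims must be divisible by 2")
        r = x.data.reshape(B, C, H // 2, 2, W // 2, 2)
        r = r.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // 2, W // 2, 4)
        idx = np.argmax(r, axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

        def bw(g):
            gr = np.zeros_like(r)
            np.put_along_axis(gr, idx[..., None], np.asarray(g)[..., None],
                              axis=-1)
            gr = gr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(
                0, 1, 2, 4, 3, 5).reshape(B, C, H, W)
            x._accum(gr)
        return Tensor._make(out, (x,), bw)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (B, H, W); running stats in eval."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def __call__(self, x: Tensor) -> Tensor:
        gamma = self.gamma.reshape(1, -1, 1, 1)
        beta = self.beta.reshape(1, -1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xn = xc / ((var + self.eps).sqrt())
        else:
            mu = self.running_mean[None, :, None, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None, None]
            xn = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return xn * gamma + beta


class LayerNorm(Module):
    """Normalization over the last dimension."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(d))
        self.beta = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps).sqrt()) * self.gamma + self.beta
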