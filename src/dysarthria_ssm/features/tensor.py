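"""Fixed-size multi-channel 2D input assembly.

The MFCC block contributes three time x 13 planes (static, delta,
delta-delta); each scalar voice-quality descriptor contributes one channel
broadcast along the feature axis.  Every channel is independently resized to
``size x size`` (default 128) with corner-aligned bilinear interpolation, so
constants stay constant and affine ramps stay affine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import FrameMatrix

SCALAR_CHANNELS = ["jitter_local", "jitter_rap", "jitter_ppq5",
                   "shimmer_local_db", "shimmer_apq3", "shimmer_apq11",
                   "hnr_db", "wavelet_entropy", "oq", "gfq", "h1_h2"]
MFCC_CHANNELS = ["mfcc_static", "mfcc_delta", "mfcc_delta2"]
DEFAULT_CHANNELS = MFCC_CHANNELS + SCALAR_CHANNELS   # C = 14


@dataclass
class FeatureTensor:
    values: np.ndarray            # size x size x C
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.ndim != 3 or self.values.shape[2] != len(self.channel_names):
            raise ValueError("tensor shape does not match channel names")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor contains non-finite values")


def bilinear_resize(a: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Corner-aligned separable bilinear resize of a 2-D array."""
    a = np.asarray(a, dtype=np.float64)
    h, w = a.shape
    oh, ow = out_shape

    def axis_interp(arr, n_in, n_out, axis):
        if n_in == 1:
            return np.repeat(arr, n_out, axis=axis)
        pos = np.linspace(0.0, n_in - 1.0, n_out)
        i0 = np.clip(np.floor(pos).astype(int), 0, n_in - 2)
        frac = pos - i0
        lo = np.take(arr, i0, axis=axis)
        hi = np.take(arr, i0 + 1, axis=axis)
        shape = [1, 1]
        shape[axis] = n_out
        f = frac.reshape(shape)
        return lo * (1 - f) + hi * f

    return axis_interp(axis_interp(a, h, oh, 0), w, ow, 1)


def assemble_tensor(frames: FrameMatrix, scalars: dict[str, float],
                    size: int = 128,
                    channels: list[str] | None = None) -> FeatureTensor:
    """Stack MFCC planes and frame-broadcast scalars into a size x size x C tensor.

    ``scalars`` must provide a finite value per scalar channel (impute
    missing values with training-set channel means before calling); a channel
    whose value is missing here is rejected.
    """
    channels = list(channels or DEFAULT_CHANNELS)
    t = frames.values
    nf = t.shape[0]
    planes = []
    for name in channels:
        if name == "mfcc_static":
            plane = t[:, 0:13]
        elif name == "mfcc_delta":
            plane = t[:, 13:26]
        elif name == "mfcc_delta2":
            plane = t[:, 26:39]
        else:
            if name not in scalars or not np.isfinite(scalars[name]):
                raise ValueError(
                    f"channel {name!r} missing or non-finite; impute before "
                    "tensor assembly")
            plane = np.full((nf, 1), float(scalars[name]))
        planes.append(bilinear_resize(plane, (size, size)))
    values = np.stack(planes, axis=-1)
    return FeatureTensor(values, tuple(channels))
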