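"""Segment-level feature extraction driver."""

from __future__ import annotations

import math

import numpy as np

from ..preprocess import SegmentRecord
from .periods import detect_periods
from .perturbation import harmonic_noise_ratio, perturbation_measures
from .spectral import glottal_measures, mfcc_with_deltas, wavelet_entropy
from .tensor import SCALAR_CHANNELS, FeatureTensor, assemble_tensor


def extract_segment_features(s: SegmentRecord):
    """Extract the frame matrix and all scalar descriptors for one segment.

    Returns ``(FrameMatrix, dict)`` where the dict has one entry per scalar
    channel; descriptors that cannot be computed (unvoiced segment, too few
    cycles) are NaN and must be imputed before tensor assembly.
    """
    track = detect_periods(s)
    pert = perturbation_measures(track).as_dict()
    scalars = dict(pert)
    scalars["hnr_db"] = harmonic_noise_ratio(s, track)
    scalars["wavelet_entropy"] = wavelet_entropy(s)
    scalars.update(glottal_measures(s, track).as_dict())
    frames = mfcc_with_deltas(s)
    assert set(scalars) == set(SCALAR_CHANNELS)
    return frames, scalars


def segment_to_tensor(s: SegmentRecord, impute: dict[str, float] | None = None,
                      size: int = 128) -> FeatureTensor:
    """One-shot extraction + assembly, imputing missing scalars.

    ``impute`` maps channel name to the fallback value (typically the
    training-split channel mean); without it, missing scalars default to 0.
    """
    frames, scalars = extract_segment_features(s)
    for k, v in scalars.items():
        if not math.isfinite(v):
            scalars[k] = (impute or {}).get(k, 0.0)
    return assemble_tensor(frames, scalars, size=size)
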