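"""Corpus-level dataset assembly: recordings -> preprocessed segments ->
feature tensors ready for the classifier.

Scalar-channel imputation (training-split means for missing values) and
per-channel standardization (training-split statistics) happen here, at
array-build time, so no information leaks from validation or test speakers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (DEFAULT_CHANNELS, MFCC_CHANNELS, SCALAR_CHANNELS,
                       bilinear_resize, extract_segment_features)
from .preprocess import PreprocessStats, Waveform, preprocess_recording
from .synth import CLASS_ORDER, read_wav

logger = logging.getLogger(__name__)


@dataclass
class SegmentFeatures:
    speaker_id: str
    label: str
    window_scale: str
    mfcc_planes: np.ndarray        # (3, size, size): static, delta, delta2
    scalars: np.ndarray            # (11,), NaN = missing


@dataclass
class CorpusFeatures:
    segments: list[SegmentFeatures]
    size: int
    channel_names: tuple[str, ...] = tuple(DEFAULT_CHANNELS)

    @property
    def speakers(self) -> np.ndarray:
        return np.array([s.speaker_id for s in self.segments])

    @property
    def labels(self) -> np.ndarray:
        return np.array([CLASS_ORDER.index(s.label) for s in self.segments])


def extract_corpus(manifest: pd.DataFrame, wav_dir: str | Path,
                   size: int = 128,
                   scales: tuple[str, ...] = ("long_4s", "short_0p75s"),
                   ) -> CorpusFeatures:
    """Preprocess every recording in the manifest and extract features."""
    wav_dir = Path(wav_dir)
    stats = PreprocessStats()
    segments: list[SegmentFeatures] = []
    for row in manifest.itertuples():
        x, fs = read_wav(wav_dir / row.path)
        segs = preprocess_recording(Waveform(x, fs), row.speaker_id,
                                    row.label, stats)
        for s in segs:
            if s.window_scale not in scales:
                continue
            frames, scal = extract_segment_features(s)
            planes = np.stack([
                bilinear_resize(frames.values[:, 0:13], (size, size)),
                bilinear_resize(frames.values[:, 13:26], (size, size)),
                bilinear_resize(frames.values[:, 26:39], (size, size)),
            ])
            segments.append(SegmentFeatures(
                s.speaker_id, s.label, s.window_scale,
                planes.astype(np.float32),
                np.array([scal[k] for k in SCALAR_CHANNELS], dtype=np.float64)))
    logger.info("extracted %d segments (%d constant segments dropped)",
                len(segments), stats.n_dropped_constant)
    return CorpusFeatures(segments, size)


@dataclass
class ArrayDataset:
    X: np.ndarray            # (n, C, size, size) standardized
    y: np.ndarray            # (n,) int class indices
    speakers: np.ndarray
    channel_names: tuple[str, ...]
    impute_means: np.ndarray     # per scalar channel
    channel_mean: np.ndarray     # per channel, from the training split
    channel_std: np.ndarray


def build_arrays(corpus: CorpusFeatures, train_mask: np.ndarray,
                 stats_from: "ArrayDataset | None" = None) -> ArrayDataset:
    """Materialize standardized input tensors.

    Imputation and standardization statistics come from the segments where
    ``train_mask`` is True (or from ``stats_from``, for applying a fitted
    dataset's statistics to new data).
    """
    n = len(corpus.segments)
    C = len(corpus.channel_names)
    size = corpus.size
    scal = np.stack([s.scalars for s in corpus.segments])      # (n, 11)

    if stats_from is None:
        train_scal = scal[train_mask]
        impute = np.nanmean(train_scal, axis=0)
        impute = np.where(np.isfinite(impute), impute, 0.0)
    else:
        impute = stats_from.impute_means
    scal_f = np.where(np.isfinite(scal), scal, impute[None, :])

    X = np.empty((n, C, size, size), dtype=np.float32)
    for i, seg in enumerate(corpus.segments):
        X[i, :3] = seg.mfcc_planes
        X[i, 3:] = scal_f[i][:, None, None]

    if stats_from is None:
        Xt = X[train_mask]
        mean = Xt.mean(axis=(0, 2, 3))
        std = Xt.std(axis=(0, 2, 3))
        std = np.where(std > 1e-8, std, 1.0)
    else:
        mean, std = stats_from.channel_mean, stats_from.channel_std
    X -= mean[None, :, None, None].astype(np.float32)
    X /= std[None, :, None, None].astype(np.float32)

    return ArrayDataset(X, corpus.labels, corpus.speakers,
                        corpus.channel_names, impute, mean, std)
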