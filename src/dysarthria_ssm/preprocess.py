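"""Signal conditioning and dual-scale segmentation.

The fixed chain, applied sequentially to every recording:

    resample to 16 kHz -> db4 wavelet denoising -> 300-3400 Hz zero-phase
    band-pass -> 80 Hz zero-phase high-pass -> non-overlapping segmentation
    (4 s and 0.75 s tilings) -> per-segment z-score normalization

All filters are zero-phase (forward-backward application), so transient
features keep their temporal alignment.  Constant (sigma = 0) segments are
dropped rather than normalized, with a counted, logged reason.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal

logger = logging.getLogger(__name__)

TARGET_FS = 16000
LONG_WINDOW_S = 4.0
SHORT_WINDOW_S = 0.75
WINDOW_SCALES = {"long_4s": LONG_WINDOW_S, "short_0p75s": SHORT_WINDOW_S}


@dataclass
class Waveform:
    samples: np.ndarray
    fs: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class SegmentRecord:
    samples: np.ndarray
    fs: int
    speaker_id: str
    label: str
    window_scale: str           # "long_4s" | "short_0p75s"
    source_offset: float        # seconds into the source recording


def resample_to_16k(w: Waveform) -> Waveform:
    """Band-limited downsampling to 16 kHz; 16 kHz input passes through."""
    if w.fs < TARGET_FS:
        raise ValueError(
            f"fs={w.fs} < {TARGET_FS}: upsampling is not supported; "
            "check the manifest")
    if w.fs == TARGET_FS:
        return w
    g = math.gcd(w.fs, TARGET_FS)
    y = signal.resample_poly(w.samples, TARGET_FS // g, w.fs // g)
    return Waveform(y, TARGET_FS)


def dwt_denoise(w: Waveform, wavelet: str = "db4", level: int = 4) -> Waveform:
    """Wavelet shrinkage: universal soft threshold on the detail levels.

    The noise scale is the median absolute deviation of the finest detail
    coefficients divided by 0.6745; the approximation band is left untouched.
    """
    min_len = 2 ** level * pywt.Wavelet(wavelet).dec_len
    if len(w.samples) < min_len:
        raise ValueError(
            f"signal too short for a {level}-level {wavelet} decomposition "
            f"(need >= {min_len} samples, got {len(w.samples)})")
    coeffs = pywt.wavedec(w.samples, wavelet, level=level, mode="periodization")
    d1 = coeffs[-1]
    sigma = np.median(np.abs(d1)) / 0.6745
    thresh = sigma * math.sqrt(2.0 * math.log(len(w.samples)))
    if thresh > 0:
        den = [coeffs[0]] + [pywt.threshold(c, thresh, mode="soft")
                             for c in coeffs[1:]]
    else:
        den = coeffs
    y = pywt.waverec(den, wavelet, mode="periodization")[: len(w.samples)]
    return Waveform(y, w.fs)


def _butter_sos(kind: str) -> np.ndarray:
    if kind == "bandpass":
        return signal.butter(4, [300.0, 3400.0], btype="bandpass",
                             fs=TARGET_FS, output="sos")
    return signal.butter(4, 80.0, btype="highpass", fs=TARGET_FS, output="sos")


def bandpass_filter(w: Waveform) -> Waveform:
    """300-3400 Hz 4th-order Butterworth, zero phase (forward-backward)."""
    if w.fs != TARGET_FS:
        raise ValueError("bandpass_filter expects 16 kHz input")
    return Waveform(signal.sosfiltfilt(_butter_sos("bandpass"), w.samples), w.fs)


def highpass_baseline(w: Waveform) -> Waveform:
    """80 Hz zero-phase IIR high-pass for baseline-wander removal."""
    if w.fs != TARGET_FS:
        raise ValueError("highpass_baseline expects 16 kHz input")
    return Waveform(signal.sosfiltfilt(_butter_sos("highpass"), w.samples), w.fs)


def zscore_segment(s: SegmentRecord, std_floor: float = 1e-12) -> SegmentRecord:
    """Normalize one segment to zero mean, unit variance.

    Raises ``ConstantSegmentError`` for sigma = 0 segments; callers drop
    these (the normalization is undefined there).
    """
    sd = float(np.std(s.samples))
    if sd <= std_floor:
        raise ConstantSegmentError(
            f"segment at {s.source_offset:.2f}s of speaker {s.speaker_id} "
            "is constant (sigma = 0)")
    y = (s.samples - np.mean(s.samples)) / sd
    return SegmentRecord(y, s.fs, s.speaker_id, s.label, s.window_scale,
                         s.source_offset)


class ConstantSegmentError(ValueError):
    pass


def segment_dual(w: Waveform, speaker_id: str = "", label: str = "") -> list[SegmentRecord]:
    """Tile a recording with non-overlapping 4 s and 0.75 s windows.

    Both tilings start at offset 0; trailing partial windows are discarded.
    A recording shorter than 0.75 s yields an empty list with a warning.
    """
    if w.duration_s < SHORT_WINDOW_S:
        logger.warning("recording shorter than %.2f s: no segments emitted",
                       SHORT_WINDOW_S)
        return []
    out: list[SegmentRecord] = []
    for scale, win_s in WINDOW_SCALES.items():
        n = round(win_s * w.fs)
        k = 0
        while (k + 1) * n <= len(w.samples):
            out.append(SegmentRecord(
                w.samples[k * n:(k + 1) * n].copy(), w.fs, speaker_id, label,
                scale, k * win_s))
            k += 1
    return out


@dataclass
class PreprocessStats:
    n_segments: int = 0
    n_dropped_constant: int = 0


def preprocess_recording(
    w: Waveform, speaker_id: str = "", label: str = "",
    stats: PreprocessStats | None = None,
) -> list[SegmentRecord]:
    """Run the full conditioning chain on one recording.

    Order is fixed: resample -> wavelet denoise -> band-pass -> high-pass ->
    segment -> z-score.
    """
    w = resample_to_16k(w)
    w = dwt_denoise(w)
    w = bandpass_filter(w)
    w = highpass_baseline(w)
    segs = segment_dual(w, speaker_id, label)
    out = []
    for s in segs:
        try:
            out.append(zscore_segment(s))
        except ConstantSegmentError as err:
            logger.info("dropping segment: %s", err)
            if stats is not None:
                stats.n_dropped_constant += 1
    if stats is not None:
        stats.n_segments += len(out)
    return out
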