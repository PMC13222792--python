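"""Spectral descriptors: MFCCs with deltas, wavelet entropy, glottal proxies."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.fft import dct, rfft

from ..preprocess import SegmentRecord
from .periods import PeriodTrack, n_frames

N_MFCC = 13
N_MEL_FILTERS = 26
FRAME_S = 0.025
HOP_S = 0.010
H1H2_CAP_DB = 40.0


@dataclass
class FrameMatrix:
    """frames x coefficients matrix on the 25 ms / 10 ms grid."""

    values: np.ndarray
    frame_hop_s: float = HOP_S
    frame_len_s: float = FRAME_S


def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def _mel_filterbank(fs: int, nfft: int, n_filters: int = N_MEL_FILTERS) -> np.ndarray:
    mels = np.linspace(_hz_to_mel(0.0), _hz_to_mel(fs / 2.0), n_filters + 2)
    hz = _mel_to_hz(mels)
    bins = np.floor((nfft + 1) * hz / fs).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for i in range(n_filters):
        lo, ce, hi = bins[i], bins[i + 1], bins[i + 2]
        if ce > lo:
            fb[i, lo:ce] = (np.arange(lo, ce) - lo) / (ce - lo)
        if hi > ce:
            fb[i, ce:hi] = (hi - np.arange(ce, hi)) / (hi - ce)
    return fb


def _delta(c: np.ndarray, width: int = 2) -> np.ndarray:
    """Regression delta over +-``width`` frames with edge replication."""
    pad = np.pad(c, ((width, width), (0, 0)), mode="edge")
    num = sum(n * (pad[width + n:len(c) + width + n] -
                   pad[width - n:len(c) + width - n]) for n in range(1, width + 1))
    return num / (2.0 * sum(n * n for n in range(1, width + 1)))


def mfcc_with_deltas(s: SegmentRecord) -> FrameMatrix:
    """13 static MFCCs + deltas + delta-deltas (39 columns).

    25 ms Hamming windows, 10 ms hop, 26-filter mel bank over 0-8 kHz,
    orthonormal DCT-II, c0 included.  Deltas use +-2-frame regression.
    """
    if s.fs != 16000:
        raise ValueError("mfcc_with_deltas expects 16 kHz input")
    x = np.asarray(s.samples, dtype=np.float64)
    frame = round(FRAME_S * s.fs)
    hop = round(HOP_S * s.fs)
    nf = n_frames(len(x), s.fs)
    if nf < 1:
        raise ValueError("segment shorter than one analysis frame")
    idx = np.arange(frame)[None, :] + hop * np.arange(nf)[:, None]
    frames = x[idx] * np.hamming(frame)[None, :]
    nfft = 512
    power = np.abs(rfft(frames, nfft, axis=1)) ** 2
    fb = _mel_filterbank(s.fs, nfft)
    logmel = np.log(np.maximum(power @ fb.T, 1e-12))
    cc = dct(logmel, type=2, norm="ortho", axis=1)[:, :N_MFCC]
    d1 = _delta(cc)
    d2 = _delta(d1)
    return FrameMatrix(np.hstack([cc, d1, d2]))


def wavelet_entropy(s: SegmentRecord, wavelet: str = "db4",
                    level: int = 4) -> float:
    """Shannon entropy of relative subband energies of a db4 decomposition.

    Five subbands (4 detail + 1 approximation); range [0, ln 5].  NaN for a
    zero-energy segment.
    """
    x = np.asarray(s.samples, dtype=np.float64)
    min_len = 2 ** level * pywt.Wavelet(wavelet).dec_len
    if len(x) < min_len:
        raise ValueError("segment too short for a 4-level decomposition")
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="periodization")
    energies = np.array([float(np.sum(c ** 2)) for c in coeffs])
    total = energies.sum()
    if total <= 0:
        return math.nan
    p = energies / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


@dataclass
class GlottalMeasures:
    oq: float     # open quotient proxy, fraction of the cycle
    gfq: float    # glottal flow quotient proxy (opening-phase fraction)
    h1_h2: float  # first minus second harmonic level, dB

    def as_dict(self) -> dict[str, float]:
        return dict(oq=self.oq, gfq=self.gfq, h1_h2=self.h1_h2)


def glottal_measures(s: SegmentRecord, t: PeriodTrack) -> GlottalMeasures:
    """Simplified glottal source descriptors.

    H1-H2 is measured on the segment spectrum at the detected F0 (difference
    in dB of the first two harmonic peak levels, capped at +-40 dB).  OQ and
    GFQ come from a low-passed source proxy: per cycle, OQ is the fraction of
    samples above the 50% amplitude threshold and GFQ the fraction of the
    open phase spent opening (proxy derivative positive).  Both are labeled
    approximations of inverse-filtered measures.
    """
    nan = math.nan
    if t.n_cycles == 0 or t.voiced_fraction == 0:
        return GlottalMeasures(nan, nan, nan)
    x = np.asarray(s.samples, dtype=np.float64)
    fs = s.fs

    f0 = float(1.0 / np.mean(t.cycle_periods))
    h1_h2 = _h1_h2(x, fs, f0)

    # source proxy: remove components above ~2.5 x F0 to flatten formants
    proxy = _lowpass(x, fs, cutoff=min(2.5 * f0, 0.45 * fs))
    oqs, gfqs = [], []
    marks = (t.cycle_start_times * fs).astype(int)
    med = float(np.median(np.diff(marks))) if len(marks) > 2 else 0.0
    for a, b in zip(marks[:-1], marks[1:]):
        cyc = proxy[a:b]
        # skip non-cycle gaps between separate voiced runs
        if len(cyc) < 4 or (med > 0 and not 0.5 * med <= b - a <= 1.5 * med):
            continue
        lo, hi = float(np.min(cyc)), float(np.max(cyc))
        if hi - lo <= 0:
            continue
        above = cyc > (lo + 0.5 * (hi - lo))
        oqs.append(float(np.mean(above)))
        d = np.diff(cyc)
        open_idx = np.flatnonzero(above[:-1])
        if len(open_idx):
            gfqs.append(float(np.mean(d[open_idx] > 0)))
    oq = float(np.mean(oqs)) if oqs else nan
    gfq = float(np.mean(gfqs)) if gfqs else nan
    return GlottalMeasures(oq, gfq, h1_h2)


def _lowpass(x: np.ndarray, fs: int, cutoff: float) -> np.ndarray:
    from scipy import signal
    sos = signal.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _h1_h2(x: np.ndarray, fs: int, f0: float, cap: float = H1H2_CAP_DB) -> float:
    n = len(x)
    w = np.hanning(n)
    spec = np.abs(rfft(x * w))
    freqs = np.arange(len(spec)) * fs / ((len(spec) - 1) * 2)
    half = 0.35 * f0
    a1 = _peak_level(spec, freqs, f0, half)
    a2 = _peak_level(spec, freqs, 2.0 * f0, half)
    if a1 <= 0:
        return math.nan
    if a2 <= 0:
        return cap
    return float(np.clip(20.0 * math.log10(a1 / a2), -cap, cap))


def _peak_level(spec, freqs, target, half):
    sel = (freqs >= target - half) & (freqs <= target + half)
    if not np.any(sel):
        return 0.0
    return float(np.max(spec[sel]))
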