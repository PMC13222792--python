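"""Cycle-to-cycle perturbation measures and harmonics-to-noise ratio.

Formulas follow the Praat conventions: local jitter is the mean absolute
difference of consecutive periods over the mean period; RAP and PPQ5 compare
each period against 3- and 5-point moving averages; local shimmer (dB) is the
mean absolute log-amplitude ratio of consecutive cycles; APQ3 and APQ11 use
3- and 11-point amplitude moving averages relative to the mean amplitude.
Measures with too few cycles are reported as missing (NaN), never as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..preprocess import SegmentRecord
from .periods import PeriodTrack

HNR_CEILING_DB = 40.0


@dataclass
class PerturbationMeasures:
    jitter_local: float      # %
    jitter_rap: float        # %
    jitter_ppq5: float       # %
    shimmer_local_db: float  # dB
    shimmer_apq3: float      # %
    shimmer_apq11: float     # %

    def as_dict(self) -> dict[str, float]:
        return dict(jitter_local=self.jitter_local, jitter_rap=self.jitter_rap,
                    jitter_ppq5=self.jitter_ppq5,
                    shimmer_local_db=self.shimmer_local_db,
                    shimmer_apq3=self.shimmer_apq3,
                    shimmer_apq11=self.shimmer_apq11)


def _ppq(values: np.ndarray, k: int) -> float:
    """k-point period/amplitude perturbation quotient, % of the mean."""
    if len(values) < k:
        return math.nan
    half = k // 2
    kernel = np.ones(k) / k
    smooth = np.convolve(values, kernel, mode="valid")
    center = values[half:len(values) - half]
    return float(np.mean(np.abs(center - smooth)) / np.mean(values) * 100.0)


def perturbation_measures(t: PeriodTrack) -> PerturbationMeasures:
    """Praat-convention jitter and shimmer from a detected period track."""
    T = np.asarray(t.cycle_periods, dtype=np.float64)
    A = np.asarray(t.cycle_peak_amplitudes, dtype=np.float64)
    nan = math.nan

    if len(T) >= 2:
        jitter_local = float(np.mean(np.abs(np.diff(T))) / np.mean(T) * 100.0)
    else:
        jitter_local = nan
    jitter_rap = _ppq(T, 3)
    jitter_ppq5 = _ppq(T, 5)

    if len(A) >= 2 and np.all(A > 0):
        shimmer_local_db = float(np.mean(np.abs(
            20.0 * np.log10(A[1:] / A[:-1]))))
    else:
        shimmer_local_db = nan
    shimmer_apq3 = _ppq(A, 3) if np.all(A > 0) else nan
    shimmer_apq11 = _ppq(A, 11) if np.all(A > 0) else nan

    return PerturbationMeasures(jitter_local, jitter_rap, jitter_ppq5,
                                shimmer_local_db, shimmer_apq3, shimmer_apq11)


def harmonic_noise_ratio(s: SegmentRecord, t: PeriodTrack,
                         ceiling_db: float = HNR_CEILING_DB) -> float:
    """Autocorrelation HNR in dB, averaged over voiced frames.

    Per frame, HNR = 10 log10(r / (1 - r)) where r is the normalized
    autocorrelation peak at the detected period; capped at ``ceiling_db``.
    Missing (NaN) when no frame is voiced.
    """
    if len(t.frame_r) == 0:
        return math.nan
    voiced = (t.frame_r >= 0.45) & (t.frame_f0 > 0)
    if not np.any(voiced):
        return math.nan
    r = np.clip(t.frame_r[voiced], 1e-6, None)
    floor = 10.0 ** (-ceiling_db / 10.0)
    hnr = 10.0 * np.log10(r / np.maximum(1.0 - r, floor))
    return float(np.mean(np.minimum(hnr, ceiling_db)))


def tremor_rate_am(s: SegmentRecord, band: tuple[float, float] = (2.0, 10.0)) -> float:
    """Dominant amplitude-modulation rate (Hz) from the envelope spectrum.

    The amplitude envelope (magnitude of the analytic signal, low-passed by
    decimation to a 100 Hz frame rate) is Fourier-analysed; the peak within
    ``band`` is returned, refined by parabolic interpolation.  NaN when the
    segment is too short to resolve the band.
    """
    from scipy.signal import hilbert

    x = np.asarray(s.samples, dtype=np.float64)
    dur = len(x) / s.fs
    if dur * band[0] < 2:  # need at least ~2 modulation cycles
        return math.nan
    env = np.abs(hilbert(x))
    hop = round(s.fs * 0.01)
    env = env[: (len(env) // hop) * hop].reshape(-1, hop).mean(axis=1)
    env = env - np.mean(env)
    fs_env = 100.0
    nfft = 1 << int(np.ceil(np.log2(len(env) * 8)))
    spec = np.abs(np.fft.rfft(env * np.hanning(len(env)), nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs_env)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        return math.nan
    idx = np.flatnonzero(sel)
    i = idx[int(np.argmax(spec[idx]))]
    if 0 < i < len(spec) - 1:
        a, b, c = spec[i - 1], spec[i], spec[i + 1]
        d = a - 2 * b + c
        if abs(d) > 1e-12:
            return float(freqs[i] + 0.5 * (a - c) / d * (freqs[1] - freqs[0]))
    return float(freqs[i])
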