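"""Fundamental-period detection.

Frame-wise normalized-autocorrelation F0 tracking (search band 60-400 Hz,
voicing threshold 0.45 on the autocorrelation peak), followed by cycle-mark
refinement to waveform peaks.  The voiced mask lives on the same 10 ms frame
grid as the MFCC sequence so scalar descriptors can be frame-aligned later.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..preprocess import SegmentRecord

F0_MIN = 60.0
F0_MAX = 400.0
VOICING_THRESHOLD = 0.45
F0_FRAME_S = 0.040
HOP_S = 0.010
MFCC_FRAME_S = 0.025


@dataclass
class PeriodTrack:
    cycle_start_times: np.ndarray    # seconds, one per cycle boundary mark
    cycle_periods: np.ndarray        # seconds, len = len(marks) - 1
    cycle_peak_amplitudes: np.ndarray  # one per period
    voiced_mask_frames: np.ndarray   # bool, on the 10 ms MFCC frame grid
    frame_f0: np.ndarray = field(default_factory=lambda: np.empty(0))
    frame_r: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_periods)

    @property
    def voiced_fraction(self) -> float:
        if len(self.voiced_mask_frames) == 0:
            return 0.0
        return float(np.mean(self.voiced_mask_frames))


def n_frames(n_samples: int, fs: int, frame_s: float = MFCC_FRAME_S,
             hop_s: float = HOP_S) -> int:
    frame = round(frame_s * fs)
    hop = round(hop_s * fs)
    if n_samples < frame:
        return 0
    return (n_samples - frame) // hop + 1


def _frame_autocorr(frame: np.ndarray, lag_min: int, lag_max: int):
    """Peak of the normalized autocorrelation in [lag_min, lag_max].

    Returns (best_lag_float, peak_value); parabolic interpolation around the
    integer peak.
    """
    n = len(frame)
    frame = frame - np.mean(frame)
    e0 = np.dot(frame, frame)
    if e0 <= 0:
        return 0.0, 0.0
    # FFT autocorrelation, then normalize per-lag by the running energies
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frame, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[:lag_max + 2]
    csum = np.concatenate([[0.0], np.cumsum(frame ** 2)])
    lags = np.arange(lag_min, min(lag_max + 1, n - 1))
    if len(lags) == 0:
        return 0.0, 0.0
    e_head = csum[n - lags] - csum[0]
    e_tail = csum[n] - csum[lags]
    denom = np.sqrt(e_head * e_tail)
    r = np.where(denom > 0, ac[lags] / np.maximum(denom, 1e-300), 0.0)
    # octave cost: prefer the shortest lag among near-equal peaks, so a
    # perfectly periodic frame does not lock onto twice the true period
    score = r - 0.05 * np.log2(lags / lags[0])
    i = int(np.argmax(score))
    best, rbest = float(lags[i]), float(r[i])
    if 0 < i < len(r) - 1:  # parabolic lag refinement
        a, b, c = r[i - 1], r[i], r[i + 1]
        d = a - 2 * b + c
        if abs(d) > 1e-12:
            best += 0.5 * (a - c) / d
            # exact autocorrelation at the fractional lag via the spectral
            # cosine sum (the 3-point parabola is unreliable for the peak
            # *value* when high-frequency energy makes r oscillate)
            P = (spec * np.conj(spec)).real
            ks = np.arange(len(P))
            ac_frac = (P[0] + 2.0 * np.sum(P[1:-1] * np.cos(
                2 * np.pi * ks[1:-1] * best / nfft))
                + P[-1] * np.cos(np.pi * best)) / nfft
            e_h = np.interp(best, lags, e_head)
            e_t = np.interp(best, lags, e_tail)
            if e_h > 0 and e_t > 0:
                rbest = float(ac_frac / np.sqrt(e_h * e_t))
    return best, min(rbest, 1.0)


def detect_periods(s: SegmentRecord) -> PeriodTrack:
    """Detect glottal cycles in a 16 kHz segment.

    Fully unvoiced input (silence, noise) yields an empty track; downstream
    perturbation measures then report missing values rather than zeros.
    """
    if s.fs != 16000:
        raise ValueError("detect_periods expects 16 kHz input")
    x = np.asarray(s.samples, dtype=np.float64)
    fs = s.fs
    hop = round(HOP_S * fs)
    f0_frame = round(F0_FRAME_S * fs)
    lag_min = int(fs / F0_MAX)
    lag_max = int(np.ceil(fs / F0_MIN))

    n_mfcc_frames = n_frames(len(x), fs)
    n_f0_frames = max((len(x) - f0_frame) // hop + 1, 0)

    f0s = np.zeros(n_f0_frames)
    rs = np.zeros(n_f0_frames)
    global_peak = np.max(np.abs(x)) if len(x) else 0.0
    for k in range(n_f0_frames):
        fr = x[k * hop:k * hop + f0_frame]
        if global_peak > 0 and np.sqrt(np.mean(fr ** 2)) < 0.01 * global_peak:
            continue  # silence gate
        lag, r = _frame_autocorr(fr, lag_min, lag_max)
        if lag > 0:
            f0s[k] = fs / lag
            rs[k] = r
    voiced_f0 = (rs >= VOICING_THRESHOLD) & (f0s > 0)

    # project onto the MFCC frame grid (same hop, shorter frame)
    mask = np.zeros(n_mfcc_frames, dtype=bool)
    m = min(n_mfcc_frames, n_f0_frames)
    mask[:m] = voiced_f0[:m]

    runs = _track_cycles(x, fs, hop, f0_frame, f0s, voiced_f0)
    starts_l, periods_l, amps_l = [], [], []
    for marks, periods in runs:
        if len(periods) < 1:
            continue
        amps = _cycle_amplitudes(x, np.asarray(marks))
        starts_l.append(np.asarray(marks) / fs)
        periods_l.append(np.asarray(periods))
        amps_l.append(amps)
    if periods_l:
        starts = np.concatenate(starts_l)
        periods = np.concatenate(periods_l)
        amps = np.concatenate(amps_l)
    else:
        starts = periods = amps = np.empty(0)
    return PeriodTrack(starts, periods, amps, mask, f0s, rs)


def _track_cycles(x, fs, hop, f0_frame, f0s, voiced):
    """Waveform-similarity cycle tracking within each voiced run.

    From an anchor at the strongest excitation peak of the first expected
    period, each following period is the lag (within +-20% of the local
    period estimate) that maximizes the normalized cross-correlation between
    the current cycle window and its shifted copy; parabolic interpolation
    of the correlation peak gives sub-sample periods.  The window spans 0.75
    of a period so it contains a single excitation event, which keeps
    period-to-period differences unbiased.  Returns a list of
    (integer marks, float periods-in-seconds) per run.
    """
    runs = []
    k = 0
    n_fr = len(voiced)
    while k < n_fr:
        if not voiced[k]:
            k += 1
            continue
        run_end = k
        while run_end < n_fr and voiced[run_end]:
            run_end += 1
        s0 = k * hop
        s1 = min((run_end - 1) * hop + f0_frame, len(x))
        period = fs / f0s[k]
        seg0 = x[s0:s0 + int(round(period))]
        if len(seg0) == 0:
            k = run_end
            continue
        m_f = float(s0 + int(np.argmax(np.abs(seg0))))
        marks = [int(round(m_f))]
        periods: list[float] = []
        while True:
            m = int(round(m_f))
            W = int(round(0.75 * period))
            lo, hi = int(0.8 * period), int(1.2 * period)
            if m + hi + W >= s1 or W < 4:
                break
            ref = x[m:m + W]
            e0 = float(np.dot(ref, ref))
            if e0 <= 0:
                break
            seg = x[m + lo:m + hi + W]
            dots = np.correlate(seg, ref, mode="valid")
            c2 = np.concatenate([[0.0], np.cumsum(seg ** 2)])
            energies = c2[W:] - c2[:-W]
            rs = dots / np.sqrt(np.maximum(e0 * energies, 1e-300))
            i = int(np.argmax(rs))
            frac = 0.0
            if 0 < i < len(rs) - 1:
                a, b, c = rs[i - 1], rs[i], rs[i + 1]
                d = a - 2 * b + c
                if abs(d) > 1e-12:
                    frac = 0.5 * (a - c) / d
            tau = lo + i + frac
            periods.append(tau / fs)
            # float accumulation keeps windows phase-locked to the cycle
            m_f += tau
            marks.append(int(round(m_f)))
            period = 0.8 * period + 0.2 * tau
        runs.append((marks, periods))
        k = run_end
    return runs


def _cycle_amplitudes(x, marks: np.ndarray,
                      window_frac: float = 0.38) -> np.ndarray:
    """Per-cycle amplitudes by matched-filter template projection.

    Each mark sits on the glottal-closure excitation; the window covers only
    the early ``window_frac`` of the cycle, which holds the closure ringing
    but excludes the next cycle's opening phase (whose amplitude belongs to
    the next period and would otherwise smooth amplitude differences).
    Windows are projected onto the run's average normalized cycle shape,
    averaging noise over the window rather than sampling one peak.  Falls
    back to peak magnitude for runs with fewer than 3 usable cycles.
    Returns one amplitude per period (pairs of consecutive marks).
    """
    n_per = len(marks) - 1
    if n_per < 1:
        return np.empty(0)
    tbar = int(round(np.median(np.diff(marks))))
    L = max(int(window_frac * tbar), 6)
    wins, idx = [], []
    for j, m in enumerate(marks[:-1]):
        if m >= 0 and m + L <= len(x):
            wins.append(x[m:m + L])
            idx.append(j)
    peak_amps = np.array([np.max(np.abs(x[a:b]))
                          for a, b in zip(marks[:-1], marks[1:])])
    if len(wins) < 3:
        return peak_amps
    W = np.stack(wins)
    a0 = np.max(np.abs(W), axis=1)
    a0 = np.where(a0 > 0, a0, 1.0)
    tmpl = (W / a0[:, None]).mean(axis=0)
    norm = float(np.dot(tmpl, tmpl))
    if norm <= 0:
        return peak_amps
    proj = np.abs(W @ tmpl) / math.sqrt(norm)
    out = peak_amps.copy()
    out[np.asarray(idx)] = proj
    return out
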