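"""Synthetic dysarthric-phonation corpus generator.

Produces speaker-structured sustained-phonation audio with independently
controllable voice-quality parameters (jitter, shimmer, harmonics-to-noise
ratio, vocal tremor, pitch monotonicity) via a source-filter scheme: a
Rosenberg-style glottal pulse train with per-cycle period and amplitude
perturbation, excited through a cascade of second-order formant resonators,
plus additive broadband noise scaled to a target HNR.

Because every recording carries known ground-truth parameters, the generator
serves as the reference surface against which the feature extractors and the
full classification pipeline are validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import lfilter

CLASS_ORDER = ["Normal", "Mild", "Moderate", "Severe", "TremorDominant"]

#: Reference speaker-level cohort compositions the generator's default
#: cohort proportions are modelled on (Spanish research corpus and a Mandarin
#: clinical cohort; Normal/Mild/Moderate/Severe/Tremor-dominant).
PCGITA_SPEAKER_COUNTS = {
    "Normal": 50, "Mild": 18, "Moderate": 15, "Severe": 10, "TremorDominant": 7,
}
MANDARIN_SPEAKER_COUNTS = {
    "Normal": 63, "Mild": 46, "Moderate": 38, "Severe": 26, "TremorDominant": 16,
}

VALID_FS = (16000, 44100)


@dataclass(frozen=True)
class SpeakerProfile:
    """Stable per-speaker vocal characteristics."""

    speaker_id: str
    f0_base: float                      # Hz, [80, 300]
    formant_freqs: tuple[float, ...]    # Hz, strictly increasing, >= 3
    formant_bandwidths: tuple[float, ...]
    base_amplitude: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (80.0 <= self.f0_base <= 300.0):
            raise ValueError(f"f0_base must lie in [80, 300] Hz, got {self.f0_base}")
        if len(self.formant_freqs) < 3:
            raise ValueError("need at least 3 formant frequencies")
        if any(b <= a for a, b in zip(self.formant_freqs, self.formant_freqs[1:])):
            raise ValueError("formant_freqs must be strictly increasing")
        if len(self.formant_bandwidths) != len(self.formant_freqs):
            raise ValueError("one bandwidth per formant required")


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional voice-quality parameters (the ground truth)."""

    label: str
    jitter_pct: float       # local jitter, % of mean period
    shimmer_db: float       # local shimmer, dB
    hnr_db: float           # harmonics-to-noise ratio, dB
    tremor_rate: float      # Hz (0 disables tremor)
    tremor_depth: float     # fraction of amplitude (f0 modulated at half depth)
    monotonicity: float     # fraction suppressing natural f0 declination/wander

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise ValueError(f"unknown label {self.label!r}")
        if self.jitter_pct < 0:
            raise ValueError("jitter_pct must be >= 0")
        if not (0.0 <= self.tremor_depth <= 1.0):
            raise ValueError("tremor_depth must lie in [0, 1]")
        if not (0.0 <= self.monotonicity <= 1.0):
            raise ValueError("monotonicity must lie in [0, 1]")


# Class-conditional parameter ranges (low, high) for per-speaker draws.
# The paper-style severity gradient holds: jitter/shimmer increase and HNR
# decreases monotonically from Normal to Severe; the tremor-dominant class is
# moderate perturbation plus strong 4-7 Hz modulation (simulator convention).
CLASS_DEFAULTS: dict[str, dict[str, tuple[float, float]]] = {
    "Normal": dict(jitter_pct=(0.2, 0.5), shimmer_db=(0.15, 0.35),
                   hnr_db=(22.0, 28.0), tremor_rate=(0.0, 0.0),
                   tremor_depth=(0.0, 0.02), monotonicity=(0.0, 0.1)),
    "Mild": dict(jitter_pct=(0.8, 1.5), shimmer_db=(0.4, 0.8),
                 hnr_db=(17.0, 21.0), tremor_rate=(4.0, 6.0),
                 tremor_depth=(0.02, 0.08), monotonicity=(0.2, 0.4)),
    "Moderate": dict(jitter_pct=(1.8, 3.0), shimmer_db=(0.9, 1.5),
                     hnr_db=(12.0, 16.0), tremor_rate=(4.0, 6.0),
                     tremor_depth=(0.08, 0.15), monotonicity=(0.5, 0.7)),
    "Severe": dict(jitter_pct=(3.5, 6.0), shimmer_db=(1.6, 2.5),
                   hnr_db=(5.0, 10.0), tremor_rate=(4.0, 6.0),
                   tremor_depth=(0.1, 0.2), monotonicity=(0.7, 0.9)),
    "TremorDominant": dict(jitter_pct=(1.5, 2.5), shimmer_db=(0.8, 1.4),
                           hnr_db=(14.0, 18.0), tremor_rate=(4.0, 7.0),
                           tremor_depth=(0.35, 0.6), monotonicity=(0.4, 0.6)),
}

# |x - y| of two iid N(0, s) has mean 2s/sqrt(pi); invert so that the
# realized mean cycle-to-cycle statistic matches the requested value.
_HALF_NORMAL = math.sqrt(math.pi) / 2.0


@dataclass
class PhonationCycles:
    """Internal per-cycle record of a synthesized phonation."""

    start_times_s: np.ndarray      # cycle onset, seconds
    periods_s: np.ndarray          # cycle durations, seconds (exact)
    amplitudes: np.ndarray         # per-cycle source gain (tremor included)


def _rosenberg_deriv(phase: np.ndarray, open_quotient: float = 0.6) -> np.ndarray:
    """Analytic Rosenberg glottal flow derivative at cycle phases in [0, 1).

    The closed phase comes first; the open phase (opening 2/3, closing 1/3)
    ends exactly at the cycle boundary, so the abrupt flow stop -- the main
    acoustic excitation -- coincides with the boundary and the interval
    between successive excitations equals the synthesized period exactly.
    Continuous-phase evaluation lets cycles start at fractional sample
    positions, so periods carry no sample quantization.
    """
    oq = open_quotient
    q = (phase - (1.0 - oq)) / oq             # position within the open phase
    tp = 2.0 / 3.0                            # end of opening, within open phase
    d = np.zeros_like(phase)
    rise = (q >= 0) & (q < tp)
    fall = q >= tp
    d[rise] = 0.5 * np.pi / tp * np.sin(np.pi * q[rise] / tp) / oq
    d[fall] = -np.pi / (2.0 * (1.0 - tp)) * np.sin(
        np.pi * (q[fall] - tp) / (2.0 * (1.0 - tp))) / oq
    return d


def _resonator_cascade(x: np.ndarray, freqs, bws, fs: float) -> np.ndarray:
    """Apply cascaded two-pole formant resonators."""
    y = x
    for f, bw in zip(freqs, bws):
        r = math.exp(-math.pi * bw / fs)
        theta = 2.0 * math.pi * f / fs
        a = [1.0, -2.0 * r * math.cos(theta), r * r]
        b = [1.0 - r]  # keep unity-ish low-frequency gain
        y = lfilter(b, a, y)
    return y


def synth_phonation(
    profile: SpeakerProfile,
    params: ClassParams,
    duration_s: float,
    fs: int = 16000,
    return_cycles: bool = False,
):
    """Synthesize one sustained phonation.

    Returns ``(samples, fs)`` or ``(samples, fs, PhonationCycles)`` when
    ``return_cycles`` is true.  Deterministic given ``profile.rng_seed``.
    """
    if fs not in VALID_FS:
        raise ValueError(f"fs must be one of {VALID_FS}, got {fs}")
    if duration_s * profile.f0_base < 10:
        raise ValueError("duration too short: need at least 10 glottal cycles")
    if params.tremor_rate >= profile.f0_base / 2.0:
        raise ValueError(
            f"tremor_rate {params.tremor_rate} Hz >= f0_base/2 "
            f"({profile.f0_base / 2:.1f} Hz): modulation would alias into the voicing band"
        )

    rng = np.random.default_rng(profile.rng_seed)
    n_samples = round(duration_s * fs)
    # synthesize the deterministic part oversampled: the glottal closure is
    # a spectral discontinuity, and direct sampling at the target rate would
    # alias it into cycle-to-cycle waveform noise
    up = 4
    fs_up = up * fs
    n_up = n_samples * up

    # slow f0 contour: declination plus band-limited wander, both suppressed
    # by the monotonicity fraction
    t_axis = np.arange(n_samples) / fs
    declin = -0.08 * (t_axis / max(duration_s, 1e-9))
    n_knots = max(int(duration_s * 2) + 2, 4)
    knots = rng.normal(0.0, 0.02, n_knots)
    wander = np.interp(t_axis, np.linspace(0, duration_s, n_knots), knots)
    contour = 1.0 + (1.0 - params.monotonicity) * (declin + wander)

    sigma_j = params.jitter_pct / 100.0 * _HALF_NORMAL
    sigma_s_db = params.shimmer_db * _HALF_NORMAL
    phase = rng.uniform(0, 2 * math.pi)

    starts, periods, amps = [], [], []
    src = np.zeros(n_up)
    t0 = 0.0                      # cycle onset, seconds (fractional samples)
    while True:
        f0_now = profile.f0_base * contour[min(int(t0 * fs), n_samples - 1)]
        if params.tremor_rate > 0:
            f0_now *= 1.0 + 0.5 * params.tremor_depth * math.sin(
                2 * math.pi * params.tremor_rate * t0 + phase)
        period = (1.0 / f0_now) * (1.0 + sigma_j * rng.standard_normal())
        period = max(period, 4.0 / fs)
        n0 = int(math.ceil(t0 * fs_up))
        n1 = int(math.ceil((t0 + period) * fs_up))
        if n1 > n_up:
            break
        amp = 10.0 ** (sigma_s_db * rng.standard_normal() / 20.0)
        if params.tremor_rate > 0:
            amp *= 1.0 + params.tremor_depth * math.sin(
                2 * math.pi * params.tremor_rate * t0 + phase)
        cyc_phase = (np.arange(n0, n1) / fs_up - t0) / period
        src[n0:n1] = amp * _rosenberg_deriv(cyc_phase)
        starts.append(t0)
        periods.append(period)
        amps.append(amp)
        t0 += period

    voiced_up = _resonator_cascade(src, profile.formant_freqs,
                                   profile.formant_bandwidths, fs_up)
    from scipy.signal import resample_poly
    voiced = resample_poly(voiced_up, 1, up)[:n_samples]
    if len(voiced) < n_samples:
        voiced = np.pad(voiced, (0, n_samples - len(voiced)))
    e_per = float(np.sum(voiced ** 2))
    if params.hnr_db < 80 and e_per > 0:
        e_noise = e_per / (10.0 ** (params.hnr_db / 10.0))
        noise = rng.standard_normal(n_samples)
        noise *= math.sqrt(e_noise / np.sum(noise ** 2))
    else:
        noise = np.zeros(n_samples)
    x = voiced + noise

    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak * min(8.0 * profile.base_amplitude, 0.95)

    cycles = PhonationCycles(np.asarray(starts), np.asarray(periods),
                             np.asarray(amps))
    if return_cycles:
        return x, fs, cycles
    return x, fs


def draw_class_params(label: str, rng: np.random.Generator,
                      ranges: dict | None = None) -> ClassParams:
    """Draw one speaker's ground-truth parameters for ``label``."""
    spec = (ranges or CLASS_DEFAULTS)[label]
    vals = {k: float(rng.uniform(*spec[k])) for k in spec}
    return ClassParams(label=label, **vals)


def draw_speaker_profile(speaker_id: str, rng: np.random.Generator) -> SpeakerProfile:
    f0 = float(rng.uniform(100.0, 220.0))
    f1 = rng.uniform(650.0, 850.0)
    formants = (f1, f1 + rng.uniform(350.0, 550.0),
                rng.uniform(2400.0, 2900.0), rng.uniform(3300.0, 3800.0))
    # bandwidths at the wide (breathy/pathological) end of reported ranges:
    # the cycle response then decays well within one period, keeping the
    # per-cycle amplitude parameter identifiable from the waveform
    bws = (120.0, 160.0, 220.0, 300.0)
    return SpeakerProfile(
        speaker_id=speaker_id, f0_base=f0,
        formant_freqs=tuple(round(f, 1) for f in formants),
        formant_bandwidths=bws,
        base_amplitude=float(rng.uniform(0.06, 0.12)),
        rng_seed=int(rng.integers(0, 2 ** 31 - 1)),
    )


MANIFEST_COLUMNS = ["path", "speaker_id", "label", "duration_s", "jitter_pct",
                    "shimmer_db", "hnr_db", "tremor_rate", "tremor_depth"]


def make_corpus(
    out_dir: str | Path,
    n_speakers_per_class: int = 20,
    recordings_per_speaker: int = 2,
    duration_s: float = 4.0,
    fs: int = 16000,
    seed: int = 0,
    class_ranges: dict | None = None,
) -> pd.DataFrame:
    """Generate a labeled synthetic corpus and write WAV files + manifest CSV.

    Every speaker has exactly one label and stable vocal characteristics;
    recordings of one speaker differ only in their stochastic realization.
    Deterministic (bit-identical audio) for a fixed seed.
    """
    if n_speakers_per_class < 1 or recordings_per_speaker < 1:
        raise ValueError("speaker and recording counts must be >= 1")
    if duration_s < 1.0:
        raise ValueError("duration_s must be >= 1 second")
    if fs not in VALID_FS:
        raise ValueError(f"fs must be one of {VALID_FS}, got {fs}")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for label in CLASS_ORDER:
        for s in range(n_speakers_per_class):
            sid = f"{label[:4].lower()}{s:03d}"
            profile = draw_speaker_profile(sid, rng)
            params = draw_class_params(label, rng, class_ranges)
            for r in range(recordings_per_speaker):
                rec_profile = replace(profile,
                                      rng_seed=int(rng.integers(0, 2 ** 31 - 1)))
                x, _ = synth_phonation(rec_profile, params, duration_s, fs)
                rel = f"{sid}_r{r}.wav"
                write_wav(out_dir / rel, x, fs)
                rows.append(dict(path=rel, speaker_id=sid, label=label,
                                 duration_s=duration_s,
                                 jitter_pct=params.jitter_pct,
                                 shimmer_db=params.shimmer_db,
                                 hnr_db=params.hnr_db,
                                 tremor_rate=params.tremor_rate,
                                 tremor_depth=params.tremor_depth))
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def write_wav(path: str | Path, x: np.ndarray, fs: int) -> None:
    """Write mono 16-bit PCM."""
    q = np.clip(x, -1.0, 1.0)
    wavfile.write(str(path), fs, (q * 32767.0).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    fs, data = wavfile.read(str(path))
    if data.ndim != 1:
        raise ValueError("expected mono audio")
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32768.0
    else:
        data = data.astype(np.float64)
    return data, int(fs)
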