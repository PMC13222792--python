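# Methods

This note records the models, estimators, numerical choices and known
limitations behind `dysarthria_ssm`. It is written for a reader who wants
to judge what the package's passing tests do — and do not — establish.

## The synthetic phonation model

The generator emulates sustained-vowel phonation with a classical
source–filter scheme. Each cycle i has period
T_i = (1/f0(t_i)) · (1 + σ_j ε_i), ε_i ~ N(0,1), with
σ_j = (jitter_pct/100)·√π/2 so that the realized Praat-style local jitter
(mean |T_i − T_{i−1}| / mean T) equals the requested value in expectation.
Per-cycle source gains follow A_i = 10^{σ_s ξ_i/20} with
σ_s = shimmer_db·√π/2, giving the requested local shimmer in dB. Tremor
multiplies f0 (at half depth) and amplitude by 1 + depth·sin(2π·rate·t).
A monotonicity fraction in [0,1] scales down a natural f0 declination
(−8% across the utterance) and a band-limited random wander (2% RMS).
White noise is added at an exact energy ratio to the voiced part to hit
the requested HNR.

Three implementation details matter for identifiability:

- **Closure at the cycle boundary.** The Rosenberg flow pulse is laid out
  closed-phase-first, so the glottal-closure discontinuity — the main
  acoustic excitation — falls exactly on the cycle boundary. If the pulse
  were scaled into the cycle with closure at an interior phase, the
  observable closure-to-closure intervals would be weighted averages of
  adjacent periods and any waveform-based jitter estimate would be biased
  low by a factor of about √(0.56/2) ≈ 0.53.
- **Fractional-sample cycle onsets, 4× oversampled synthesis.** Cycles
  start at fractional sample positions and the source + resonator cascade
  run at 64 kHz before anti-aliased decimation to 16 kHz. Direct sampling
  of the discontinuous flow derivative at 16 kHz aliases into
  cycle-to-cycle waveform noise that shows up as a spurious ~0.6% jitter
  floor and caps the measurable HNR near 22 dB.
- **Wide formant bandwidths** (120/160/220/300 Hz), at the broad, breathy
  end of reported ranges. The cycle impulse response then decays well
  within one period, keeping per-cycle amplitude (shimmer) identifiable
  from the waveform. Narrow bandwidths leak each cycle's ringing into the
  next and attenuate any amplitude-perturbation estimate.

Default class parameter ranges (uniform per speaker, stable across a
speaker's recordings):

| class | jitter % | shimmer dB | HNR dB | tremor rate Hz | tremor depth | monotonicity |
|---|---|---|---|---|---|---|
| Normal | 0.2–0.5 | 0.15–0.35 | 22–28 | – | 0–0.02 | 0–0.1 |
| Mild | 0.8–1.5 | 0.4–0.8 | 17–21 | 4–6 | 0.02–0.08 | 0.2–0.4 |
| Moderate | 1.8–3.0 | 0.9–1.5 | 12–16 | 4–6 | 0.08–0.15 | 0.5–0.7 |
| Severe | 3.5–6.0 | 1.6–2.5 | 5–10 | 4–6 | 0.1–0.2 | 0.7–0.9 |
| Tremor-dominant | 1.5–2.5 | 0.8–1.4 | 14–18 | 4–7 | 0.35–0.6 | 0.4–0.6 |

These are simulator conventions, not clinical claims: the ordinal gradient
(jitter/shimmer up, HNR down) reflects the qualitative direction reported
for hypokinetic dysarthria, and the tremor-dominant class is defined as
moderate perturbation plus strong low-frequency modulation. Speaker f0 is
drawn from 100–220 Hz; formants approximate a sustained /a/. The default
cohort (20 speakers per class, 2 × 4 s recordings) is a scaled-down,
class-balanced analogue of the reference cohort compositions kept in
`PCGITA_SPEAKER_COUNTS` / `MANDARIN_SPEAKER_COUNTS`.

## Preprocessing

The chain is fixed: resample (polyphase, band-limited) → 4-level db4
wavelet shrinkage → 4th-order zero-phase Butterworth band-pass
300–3400 Hz → 4th-order zero-phase high-pass 80 Hz → dual segmentation →
per-segment z-scoring. Choices on points the chain itself leaves open:

- Wavelet threshold: universal soft threshold σ√(2 ln N) with σ from the
  MAD of the finest detail band, details only. Boundary mode is
  `periodization` (orthogonal), which guarantees the shrinkage never
  increases signal energy; symmetric extension is slightly redundant and
  lacks that guarantee.
- The 80 Hz high-pass is largely redundant after a 300 Hz band edge; it is
  kept because the chain is specified that way, and it is harmless.
- Segment tilings start at offset 0; trailing partial windows are
  discarded (the model needs fixed-size inputs). σ = 0 segments are
  dropped and counted — z-scoring is undefined for them.
- The filters are applied forward–backward (`sosfiltfilt`), so the
  effective magnitude response is squared and phase is exactly zero; a
  symmetric pulse stays symmetric, which the tests check by
  cross-correlation.

## Voice-quality estimators

**Period tracking.** Frame-wise normalized autocorrelation (40 ms frames,
10 ms hop, search 60–400 Hz, voicing threshold 0.45) with two
refinements: an octave cost of 0.05·log2(lag/lag_min) so perfectly
periodic frames do not lock onto twice the period, and evaluation of the
autocorrelation at the parabolic fractional lag via the spectral cosine
sum (a 3-point parabola through an oscillatory correlation curve
misestimates the peak value badly when energy extends to high
frequencies). Within each voiced run, cycles are then tracked by waveform
similarity: each period is the lag in ±20% of the local period estimate
maximizing the normalized cross-correlation between the current cycle
window (0.75 of a period, so it spans a single excitation event) and its
shifted copy, with parabolic sub-sample interpolation; the running mark
position is accumulated as a float so analysis windows stay phase-locked.

**Amplitudes (shimmer).** Per cycle, a matched-filter projection of the
first 38% of the cycle (closure ringing only — the remainder of the
window contains the *next* cycle's opening phase, whose amplitude belongs
to the next period and would smooth amplitude differences) onto the run's
average normalized cycle shape. On generator ground truth this recovers
local shimmer within ±25% for 0.5–2 dB at HNR 25 and speaker f0 up to
about 160 Hz; peak-picking alone is biased low by 20–40%.

**HNR.** Per voiced frame, 10·log10(r/(1−r)) at the refined
autocorrelation peak r, averaged over voiced frames and capped at a
configurable ceiling (default 40 dB). Jitter and shimmer decorrelate
frames and therefore depress this estimator — as they do any
autocorrelation HNR — so recovery is validated at small perturbation.

**MFCCs.** 13 coefficients (c0 included) from a 26-filter mel bank over
0–8 kHz, 512-point FFT, orthonormal DCT-II; Δ and ΔΔ by ±2-frame
regression with edge replication. No pre-emphasis (the band-pass already
shapes the spectrum).

**Glottal proxies.** H1−H2 is the dB difference of the spectral peaks at
the detected F0 and 2F0 (capped at ±40 dB). OQ and GFQ come from a
low-passed (2.5·F0) source proxy: per cycle, OQ is the fraction of
samples above the 50% amplitude threshold, GFQ the fraction of the open
phase with positive slope. These are deliberate simplifications of
inverse-filtered measures and are labelled approximate; only their
qualitative behaviour is relied on.

**Tremor rate.** Parabolic-refined peak of the Fourier spectrum of the
10 ms-frame amplitude envelope in 2–10 Hz.

**Tensor assembly.** Channels: 3 MFCC planes (static/Δ/ΔΔ, the 13
coefficients treated as a continuous feature axis) + 11 scalar channels
broadcast along the feature axis, each independently resized to S×S by
corner-aligned bilinear interpolation (C = 14; every named descriptor
gets exactly one channel). Missing scalars (unvoiced or too few cycles)
are imputed with training-split channel means; channels are standardized
with training-split statistics.

## The classifier

Paper-scale configuration (`ModelConfig()`): 128×128×14 input, conv
channels 32→64→128→256 (3×3, stride 1, pad 1), each block ordered
conv → Mish → batch-norm → 2×2 max-pool → dropout 0.1, giving 8×8×256
maps flattened row-major to a 64-step sequence; four Mamba-style blocks
(state dim N = 16, expansion 2, causal depthwise conv k = 4, SiLU gating,
pre- and post-LayerNorm around the residual); mean pooling, dropout 0.3,
single linear softmax head. About 2.1 M trainable parameters with this
head layout (the reference architecture's exact head is not specified, so
counts in the low millions are treated as consistent; the count is logged,
not asserted).

Two discretization rules are implemented behind
`discretization_mode`: `as_printed` — B̄_t = (Δ_t ⊙ B_t)·softplus(Δ_t) —
and the standard `euler` rule B̄_t = Δ_t ⊙ B_t. The printed rule's extra
softplus factor is unusual but harmless (a smooth, positive rescaling the
network can absorb); it is the default, and the selective scan is verified
against a sequential-recurrence oracle under both. A is initialized to
−(1..N) per channel, Δ via softplus of a bias drawn so Δ ≈ 0.001–0.1;
Δ > 0 is guaranteed by the softplus parameterization.

The scan is a Hillis–Steele doubling scan (log2 T passes of elementwise
work); its backward pass is the adjoint recurrence
g_t = dh_t + a_{t+1} g_{t+1}, itself computed by the same scan in reverse.
Gradient correctness is checked end-to-end through a Mamba block against
central differences (global relative error < 10⁻³ at ε = 10⁻⁴; tighter ε
only measures round-off cancellation).

`ModelConfig.small()` (32×32 input, channels 16→32→64, two Mamba blocks,
N = 8, ~116 k parameters) is the profile used for the bundled experiments
and the acceptance script: the synthetic classes are controlled by
constant-per-segment scalar channels plus modulation patterns, for which
the reduced capacity is ample, and three seeds train in minutes on one
CPU. The architecture is otherwise identical.

## Training protocol

Speaker-level stratified splits (5-fold, or 60/20/20 train/val/test);
every segment of a speaker lives in exactly one partition, asserted on
every run including after oversampling. Minority classes are balanced by
duplicating whole speaker blocks round-robin (training partition only) up
to the majority-class count (configurable target). Class weights are
w_i = 1/f_i on the post-balancing training labels. AdamW
(weight decay 0.01), batch 64, gradient clipping at global norm 1.0,
linear warm-up over the first 10% of steps to 10⁻³ then cosine annealing
to 10⁻⁶, early stopping on segment-level validation MCC (patience 15 of
max 200 epochs by default; the bundled experiments use 40–50 epochs with
patience 6–15, which is past convergence on the default corpus). The best
checkpoint by validation MCC is restored, including batch-norm running
statistics. Runs are deterministic on CPU for a fixed seed. Validation
MCC is computed at segment level; speaker-level early stopping would need
enough validation speakers per class to be stable, which small synthetic
cohorts do not have.

## Evaluation

All macro metrics derive from the 5×5 confusion matrix; classes absent
from the truth vector are excluded from macro averages with a warning.
Multi-class MCC uses the covariance form (reducing to TP·TN−FP·FN/√(...)
for two classes) with the 0/0 → 0 convention. Speaker aggregation:
majority vote with ties broken by the higher mean posterior among tied
classes (keeping the two rules consistent), or argmax of the mean
posterior. The paired permutation test flips signs of paired differences
(default 10,000 permutations, add-one p-value); bootstrap CIs are
percentile intervals over resampled speakers (default 2,000). Seed
summaries report mean ± sample SD (n−1), rounded half-up to one decimal.
Channel attribution replaces one channel at a time with its background
mean plane and records the drop in true-class probability — an occlusion
analogue of feature-attribution analyses that needs no model internals.

## What passing tests show — and what they do not

The synthetic corpus gives every downstream stage a known ground truth:
closure tests show the extractors recover controlled jitter (±20%),
shimmer (±25%), HNR (±3 dB) and tremor rate (±0.5 Hz), and the end-to-end
experiment shows the full pipeline separates classes whose acoustics
differ the way the severity literature describes. The simulator does not
emulate articulation, phonotactics, intelligibility loss, recording
channel variation, or the overlap and label noise of perceptual severity
ratings; synthetic classes are far more separable than clinical ones.
High synthetic accuracies therefore validate the machinery, not clinical
performance. The tremor-dominant class is a simulator convention
(moderate perturbation + strong 4–7 Hz modulation), mirroring the
exploratory status of that phenotype. Measured perturbation values after
the 300–3400 Hz band-pass are inflated relative to ground truth (the
fundamental is attenuated, so cycle tracking works on formant-band
structure); class ordering is preserved, and recovery closure is
validated on raw signals.

## Problem sizes used in bundled runs

Default experiment and acceptance script: 20 speakers/class × 2
recordings × 4 s (1,200 segments), 32×32×14 tensors, `ModelConfig.small()`,
three training seeds (42, 123, 456), ≤ 40–50 epochs. These sizes are the
package's default study conditions; the paper-scale 128×128 architecture
is fully implemented and unit-tested, and all pipeline code is
configuration-driven, so larger runs only change the config.
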