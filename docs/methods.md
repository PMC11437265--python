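# Methods

## Overview

`neckvitals` estimates pulse rate (PR, beats/min) and respiratory rate (RR,
breaths/min) from a neck-worn sensor pair: dual-wavelength reflectance PPG
(Red + IR, 400 Hz) and a triaxial accelerometer (Y/Z axes, 100 Hz; the X
axis carries little breathing motion at this placement and is never read).
The method is spectral: it does not detect individual beats or breaths, but
tracks the dominant in-band frequency of a standardized, artifact-dissected
30-s window, smoothed over time by a per-rate EWMA, and reports interval
("rate band") estimates with a confidence gate. All estimation is causal:
the output at time *t* uses samples from (*t* − 30 s, *t*] only, and is
timestamped at the window end.

## Preprocessing pipelines

**Pulse (PPG Red + IR).** Per 30-s window and channel: polyphase decimation
400 → 100 Hz (with built-in anti-aliasing; plain subsampling would fold
wideband noise into the passband), 0.05-s (5-sample) median filter against
single-sample spikes, 1st-order Butterworth band-pass [0.5, 4] Hz,
standardization; the two standardized channels are summed time-wise. A
2nd-order Savitzky–Golay (SG) fit over a 1.6-s window is subtracted as a
baseline estimate, and the result standardized. Output: 3000 samples at
100 Hz, zero mean, unit variance.

**Respiration (PPG Red + IR or Acc Y + Z).** A 1st-order Butterworth
band-pass [0.1, 1] Hz runs over the *whole* channel stream before windowing
(the filter is stateful; running it per-window would lose the low-frequency
continuity that matters most in this band). Per window and channel: SG
smooth (order 2, 2-s window), standardize, sum channels, SG smooth again,
then a numerical first derivative (first difference × fs, first value
repeated to preserve length) to suppress residual baseline wander, and a
final standardization.

Numerical choices: all IIR filters run forward–backward (zero phase) —
downstream magnitude spectra are phase-insensitive and zero-phase filtering
avoids group-delay asymmetry at window edges; SG windows given in seconds
are converted to the nearest odd sample count (1.6 s @ 100 Hz → 161;
2 s → 201 @ 100 Hz, 801 @ 400 Hz); median filtering uses reflect padding;
a constant (degenerate) input standardizes to all zeros and propagates as
zeros. Channel-wise affine rescaling (gain/offset drift) does not change
the output, because standardization follows the linear filters.

## Rate probabilities

Each (sub-)segment's real-input DFT is zero-padded to exactly 60·fs points,
making the bin spacing 1/60 Hz = 1 per-minute unit, so bin *k* maps
one-to-one onto integer rate *k* with no rounding collisions at any
sub-segment length. Magnitudes are restricted to the task band ([0, 4] Hz →
rates 0..240 BPM; [0, 1] Hz → 0..60 BrPM), standardized over the in-range
bins only, and passed through a softmax (temperature 1). The result is a
probability vector over integer rates summing to 1, invariant to positive
rescaling of the input; components below 0.1 are treated as negligible
downstream. An all-zero segment yields the uniform distribution.

## Dominance scores and artifact dissection

A standardized segment with excursions beyond ±3 standard units is split at
those excursions; the maximal clean stretches of at least 5 s are
re-standardized (so the ±3 criterion stays scale-appropriate at depth) and
scored recursively, to depth at most 20. Each scored (sub-)segment
contributes `p(r)/level` to the sparse dominance map for every rate with
p(r) ≥ 0.1; the weight 1/level (root = 1) discounts the less certain
spectra of shorter sub-segments. A contaminated segment whose clean
stretches are all shorter than 5 s falls back to contributing its own
(contaminated) estimate at the current level — every timestep therefore
produces scores, and the EWMA plus confidence gate absorb the damage. When
accepted sub-segments exist, the parent contributes nothing. No guard
margin is placed around excursions (margin exposed as config, default 0).
Modalities are fused by rate-wise addition of their score maps.

## EWMA tracking, bands, confidence

Per-band evidence sums dominance scores over the clinical variation range
[R − ⌊s/2⌋, R + ⌈s/2⌉] around each *observed* rate R (slack s = 5 BPM for
pulse — the ±5 BPM monitoring standard — and 3 BrPM for respiration,
matching the reference capnograph's margin); unobserved rates score zero.
The EWMA update uses α = 0.3, so one observation's influence stays above
2.5% for 7 timesteps. At t = 1 the EWMA is initialized to a normal prior
over rates — (μ, σ) = (80, 20) for pulse, (14, 4) for respiration —
rescaled to unit maximum: a raw density with σ = 20 would peak near 0.02,
below the 0.1 threshold, and the start-up would be vacuously unconfident;
unit-max scaling keeps rates within about μ ± 2.15σ above threshold
initially.

The band center is the above-threshold (EWMA > 0.1) rate nearest the
previous band (first step: global argmax); ties prefer the larger EWMA,
then the lower rate (biasing toward fundamentals over harmonics). The
estimate is confident unless the above-threshold rates spread beyond the
slack on *both* sides of their median (quartiles with linear interpolation,
over the unweighted rate set; an OR variant is exposed as
`confidence_mode`). Only confident timesteps produce output; the rate value
(dominance argmax) is attached only when it lies inside the band, so value
output is always a subset of band output. When no rate clears the
threshold, the previous band is carried forward internally (keeping the
next step's distance term defined) but nothing is emitted.

**Double-peak adjustment (pulse only).** PPG pulses carry a secondary
(dicrotic-related) peak that injects energy at twice the pulse frequency.
Before the argmax, observed rates above the 75th percentile that lie within
the slack of twice the median are halved, provided the minimum observed
rate agrees (within slack) with the last confident estimate — before any
confident estimate exists the harmonic check applies alone. A second check
covers harmonic-dominated windows where the fundamental fell below the 0.1
floor entirely: when the minimum observed rate lies within the slack of
twice the last confident rate, every rate in that doubled neighbourhood is
halved. The adjustment runs before value extraction so the emitted value
sees adjusted scores.

## Evaluation

Band errors are 0 inside the band and the distance to the nearest bound
outside. Value errors are |value − reference|. Reports give RMSE, MAE and
the standard deviation of the signed error over emitted estimates, the
percentage of processed windows with output, and the percentage of outputs
within the clinical margin (±slack for values; ±slack/2 beyond the bounds
for bands). The denominator of the output percentage is the number of
processed windows (timesteps before the first complete window are not
counted). Bland–Altman 95% limits of agreement for repeated per-subject
measurements use the one-way random-effects decomposition of the paired
differences: between/within variance components from the ANOVA mean
squares with the n₀ correction for unequal group sizes, negative estimates
truncated at zero, LoA = bias ± 1.96·√(σ²_b + σ²_w); a single subject
reduces exactly to the classical limits. The difference convention is
estimate − reference; estimate/reference pairing is nearest-timestamp
within 1 s.

**Latency convention.** A 30-s window's estimate describes the preceding
30 s. The synthetic-recovery tests therefore score estimates against the
schedule at the window *center* (`pair_records(..., lag_s=15)`), so the
inherent half-window latency is not double-counted as tracking error. The
CLI's `evaluate` command defaults to same-timestamp pairing (no lag),
which is the stricter, monitoring-style reading.

## Synthetic data

The generator is deliberately phenomenological — the framework consumes
only spectral structure, so harmonically correct quasi-periodic waveforms
with realistic modulation and artifact phenomenology suffice for
verification; it is not a hemodynamic model. Ingredients: a pulse waveform
`sin φ + 0.5·sin(2φ + π/4)` (the 0.5 second-harmonic emulates a prominent
double peak and deliberately exercises the harmonic adjustment);
respiratory amplitude modulation of the pulse envelope (depth 0.3) plus an
*additive* respiratory baseline swing (amplitude 0.4) — the additive
component is essential, since pure amplitude modulation leaves no spectral
energy at the respiratory frequency inside [0.1, 1] Hz; accelerometer axes
carrying a unit-amplitude breathing sinusoid (Y/Z in phase quadrature) on
small static offsets; plus Gaussian noise, slow sinusoidal baseline wander,
and Poisson-timed half-sine spike/motion bursts of random sign. Phases are
integrated cumulatively, so rate steps never cause phase jumps. IR is the
clean waveform at 0.8 gain with independent noise draws. All randomness
derives from a single seed; regeneration is bit-identical.

Noise presets (fixed as the package's study conditions): `clean` (no
noise), `moderate` (Gaussian SD 0.3 of unit signal amplitude, wander 0.5 at
0.03 Hz, 1 spike/min of amplitude 5 and 0.5 s), `artifact` (Gaussian 0.4,
wander 0.8 at 0.04 Hz, 4 spikes/min of amplitude 10 and 1 s).

Protocols: `make_metronome_schedule()` reproduces a metronome-guided
breathing staircase — 2-BrPM steps 14 → 27 and back, descent 14 → 4, then
two abrupt +5 BrPM jumps, 60-s plateaus (≈ 22 min).
`make_altitude_schedule()` emulates an altitude-driven pulse protocol
spanning 45–124 BPM with 90-s stages; because heart rate responds to
altitude steps through autonomic low-pass dynamics rather than
instantaneously, stages are joined by 20-s linear ramps discretized to
1-s steps (≈ 0.5 BPM/s).

**What passing these tests does and does not show.** The simulator
reproduces the spectral phenomena the method manipulates (in-band
quasi-periodicity, harmonics, sidebands, wander, transient artifacts), so
recovery results verify the *algorithmic chain*. It does not reproduce
waveform morphology, sensor-contact or perfusion variability, correlated
multi-axis motion, or reference-device measurement error, so synthetic
accuracy figures do not predict clinical accuracy.

## Known limitations

* The SG baseline subtraction (1.6 s) attenuates 0.75–0.85 Hz fundamentals
  substantially; with a strong (0.5) second harmonic, sustained rates below
  ~50 BPM can emit the harmonic instead of the fundamental when no recent
  confident anchor exists. The double-peak checks mitigate but cannot
  recover a fundamental that never clears the 0.1 probability floor.
* Pulse estimation requires PPG; the accelerometer carries no usable pulse
  signal at this placement and `pulse` + `acc` is rejected as a
  configuration error.
* Problem sizes in the test suite: full-length metronome staircase
  (~22 min) and altitude ramp (~21 min) at three seeds each for recovery
  checks; the demo uses a half-scale staircase.
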