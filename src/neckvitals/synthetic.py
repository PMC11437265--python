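"""Synthetic neck-worn PPG and accelerometer signals with known rate schedules.

The generator is deliberately phenomenological: the estimation framework
consumes only the spectral structure of its inputs, so quasi-periodic
waveforms with the right frequency content, modulation, and artifact
phenomenology are sufficient for verification.  Modelled features:

* pulse waveform with a secondary (dicrotic-like) peak at twice the pulse
  frequency, which injects the harmonic energy that invites double-peak
  errors;
* respiratory modulation of PPG, both multiplicative (amplitude modulation
  of the pulse envelope) and additive (baseline swing in the respiratory
  band — the component the respiratory band-pass actually extracts);
* low-frequency breathing motion on the accelerometer Y/Z axes (X carries
  no useful breathing signal at this placement and is never generated);
* Gaussian sensor noise, slow baseline wander, and Poisson-timed transient
  spike / motion-artifact bursts.

All waveforms are phase-continuous across rate steps, and all randomness
flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .io_windowing import RateSeries, SignalChannel

PPG_FS = 400.0
ACC_FS = 100.0


@dataclass(frozen=True)
class RateSchedule:
    """Piecewise-constant rate schedule: ordered (duration s, rate) plateaus."""

    segments: Tuple[Tuple[float, float], ...]

    def __post_init__(self):
        if any(d <= 0 for d, _ in self.segments):
            raise ValueError("plateau durations must be positive")

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def rate_at(self, t: np.ndarray) -> np.ndarray:
        """Vectorized piecewise-constant lookup (rates per minute)."""
        t = np.asarray(t, dtype=float)
        bounds = np.cumsum([d for d, _ in self.segments])
        idx = np.minimum(np.searchsorted(bounds, t, side="right"),
                         len(self.segments) - 1)
        rates = np.array([r for _, r in self.segments])
        return rates[idx]

    def scaled(self, factor: float) -> "RateSchedule":
        """Same rates, durations multiplied by ``factor``."""
        return RateSchedule(tuple((d * factor, r) for d, r in self.segments))

    def as_series(self, dt: float = 1.0, units: str = "BrPM") -> RateSeries:
        t = np.arange(0.0, self.total_duration, dt)
        return RateSeries(times=t, values=self.rate_at(t), units=units)


@dataclass(frozen=True)
class NoiseSpec:
    """Artifact and noise levels, relative to unit signal amplitude."""

    gaussian_sd: float = 0.0
    wander_amp: float = 0.0
    wander_freq: float = 0.03
    spike_rate: float = 0.0        # events per minute
    spike_amp: float = 0.0         # multiples of signal amplitude
    spike_dur_s: float = 0.5
    resp_mod_depth: float = 0.3    # AM of the pulse envelope by respiration
    resp_baseline_amp: float = 0.4 # additive respiratory-band baseline swing
    double_peak_ratio: float = 0.5 # secondary/primary pulse peak amplitude
    seed: int = 0


# Study-condition presets, fixed once; see docs/methods.md.
PRESETS = {
    "clean": NoiseSpec(),
    "moderate": NoiseSpec(gaussian_sd=0.3, wander_amp=0.5, wander_freq=0.03,
                          spike_rate=1.0, spike_amp=5.0, spike_dur_s=0.5),
    "artifact": NoiseSpec(gaussian_sd=0.4, wander_amp=0.8, wander_freq=0.04,
                          spike_rate=4.0, spike_amp=10.0, spike_dur_s=1.0),
}


def noise_preset(name: str, seed: int = 0) -> NoiseSpec:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], seed=seed)


def make_metronome_schedule(scale: float = 1.0) -> RateSchedule:
    """Metronome-guided breathing protocol: 2-BrPM staircase 14->27 and back,
    then 14->4, closing with two abrupt +5 BrPM jumps; 60-s plateaus."""
    rates = (
        [14, 16, 18, 20, 22, 24, 26, 27]      # gradual increments to the top
        + [25, 23, 21, 19, 17, 15, 14]        # decrements back to baseline
        + [12, 10, 8, 6, 4]                   # descent to the slowest rate
        + [9, 14]                             # two abrupt 5-BrPM jumps
    )
    sched = RateSchedule(tuple((60.0, float(r)) for r in rates))
    return sched.scaled(scale) if scale != 1.0 else sched


def make_altitude_schedule(scale: float = 1.0, ramp_s: float = 20.0) -> RateSchedule:
    """Pulse-rate protocol shape: plateaus rising with simulated altitude to
    the maximum recorded rate, then recovery down to the minimum (45-124 BPM).

    The altitude steps are discrete but heart rate responds through autonomic
    low-pass dynamics, so plateaus are joined by ``ramp_s``-second linear
    ramps (discretized to 1-s steps, about 0.5 BPM/s) rather than
    instantaneous jumps.
    """
    rates = [62, 70, 78, 88, 98, 108, 118, 124, 110, 95, 78, 60, 50, 45]
    segs: List[Tuple[float, float]] = []
    for i, r in enumerate(rates):
        if i > 0 and ramp_s > 0:
            prev = rates[i - 1]
            n = max(1, int(round(ramp_s)))
            for k in range(1, n + 1):
                segs.append((1.0, prev + (r - prev) * k / n))
        segs.append((90.0 - (ramp_s if i > 0 else 0.0), float(r)))
    sched = RateSchedule(tuple(segs))
    return sched.scaled(scale) if scale != 1.0 else sched


def _phase(schedule: RateSchedule, t: np.ndarray, fs: float) -> np.ndarray:
    """Integrated instantaneous phase (radians), continuous across steps."""
    inst_hz = schedule.rate_at(t) / 60.0
    return 2 * np.pi * np.cumsum(inst_hz) / fs


def _spikes(rng, n: int, fs: float, noise: NoiseSpec) -> np.ndarray:
    """Poisson-timed half-sine bursts of random sign."""
    out = np.zeros(n)
    if noise.spike_rate <= 0 or noise.spike_amp <= 0:
        return out
    n_events = rng.poisson(noise.spike_rate * n / fs / 60.0)
    width = max(2, int(round(noise.spike_dur_s * fs)))
    burst = np.sin(np.linspace(0, np.pi, width))
    for _ in range(n_events):
        start = rng.integers(0, max(1, n - width))
        out[start : start + width] += rng.choice([-1, 1]) * noise.spike_amp * burst
    return out


def _wander(rng, t: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    if noise.wander_amp <= 0:
        return np.zeros_like(t)
    phase0 = rng.uniform(0, 2 * np.pi)
    return noise.wander_amp * np.sin(2 * np.pi * noise.wander_freq * t + phase0)


def gen_ppg(
    schedule_pr: RateSchedule,
    schedule_rr: Optional[RateSchedule] = None,
    dur: Optional[float] = None,
    fs: float = PPG_FS,
    noise: NoiseSpec = NoiseSpec(),
) -> Tuple[SignalChannel, SignalChannel]:
    """Generate Red and IR PPG channels with known pulse (and breathing) rates.

    The clean waveform is ``sin(phi) + double_peak_ratio*sin(2*phi + pi/4)``
    with phase rate ``2*pi*pr(t)/60``, amplitude-modulated by respiration and
    riding on an additive respiratory baseline.  IR is the same clean
    waveform at 0.8 gain with independent noise and artifacts.
    """
    dur = schedule_pr.total_duration if dur is None else dur
    if dur > schedule_pr.total_duration + 1e-9:
        raise ValueError("requested duration exceeds the schedule")
    rng = np.random.default_rng(noise.seed)
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    phi = _phase(schedule_pr, t, fs)
    pulse = np.sin(phi) + noise.double_peak_ratio * np.sin(2 * phi + np.pi / 4)
    if schedule_rr is not None:
        psi = _phase(schedule_rr, t, fs)
        clean = pulse * (1 + noise.resp_mod_depth * np.sin(psi))
        clean = clean + noise.resp_baseline_amp * np.sin(psi)
    else:
        clean = pulse
    red = clean + _wander(rng, t, noise)
    if noise.gaussian_sd > 0:
        red = red + rng.normal(0, noise.gaussian_sd, n)
    red = red + _spikes(rng, n, fs, noise)
    ir = 0.8 * clean + _wander(rng, t, noise)
    if noise.gaussian_sd > 0:
        ir = ir + rng.normal(0, noise.gaussian_sd, n)
    ir = ir + _spikes(rng, n, fs, noise)
    return (
        SignalChannel(label="red", fs=fs, samples=red),
        SignalChannel(label="ir", fs=fs, samples=ir),
    )


def gen_acc(
    schedule_rr: RateSchedule,
    dur: Optional[float] = None,
    fs: float = ACC_FS,
    noise: NoiseSpec = NoiseSpec(),
) -> Tuple[SignalChannel, SignalChannel]:
    """Generate accelerometer Y and Z channels carrying breathing motion."""
    dur = schedule_rr.total_duration if dur is None else dur
    if dur > schedule_rr.total_duration + 1e-9:
        raise ValueError("requested duration exceeds the schedule")
    rng = np.random.default_rng(noise.seed + 1)
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    psi = _phase(schedule_rr, t, fs)
    chans = []
    for label, offset, ph in (("acc_y", 0.2, 0.0), ("acc_z", -0.1, np.pi / 2)):
        x = offset + np.sin(psi + ph) + _wander(rng, t, noise)
        if noise.gaussian_sd > 0:
            x = x + rng.normal(0, noise.gaussian_sd, n)
        x = x + _spikes(rng, n, fs, noise)
        chans.append(SignalChannel(label=label, fs=fs, samples=x))
    return chans[0], chans[1]
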