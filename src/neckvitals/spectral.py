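"""Per-rate probability estimation from the softmaxed amplitude spectrum.

A (sub-)segment's DFT magnitude, restricted to the task's frequency range,
standardized and passed through a softmax, is read as the likelihood of each
integer per-minute rate being present in the signal.  Zero-padding every DFT
to exactly ``60 * fs`` points makes the bin spacing exactly one per-minute
unit, so bin *k* maps one-to-one onto rate *k* with no rounding collisions,
regardless of sub-segment length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax as _softmax


@dataclass
class TaskConfig:
    """All tunable parameters of the framework for one measurement task.

    Defaults are the operating values of the method: frequency ranges
    [0, 4] Hz (pulse) / [0, 1] Hz (respiratory), rate grids [0..240] BPM /
    [0..60] BrPM, slack 5 BPM / 3 BrPM (the clinical error allowances),
    EWMA weight alpha = 0.3, confidence/aggregation threshold 0.1, normal
    prior (80, 20) / (14, 4), recursion capped at depth 20 and 5-s
    sub-segments, amplitude-deviation bound +/-3 (in standardized units).
    """

    m: str = "pulse"
    freq_range: tuple = (0.0, 4.0)
    rate_max: int = 240
    slack: int = 5
    mu0: float = 80.0
    sigma0: float = 20.0
    alpha: float = 0.3
    thresh: float = 0.1
    proba_floor: float = 0.1
    max_depth: int = 20
    min_subseg_s: float = 5.0
    dev_bound: float = 3.0
    dev_margin_s: float = 0.0
    confidence_mode: str = "and"   # 'and' per the wording "in both directions"

    @property
    def rate_range(self) -> np.ndarray:
        return np.arange(self.rate_max + 1)

    @classmethod
    def for_task(cls, m: str, **overrides) -> "TaskConfig":
        if m == "pulse":
            base = dict(m="pulse", freq_range=(0.0, 4.0), rate_max=240,
                        slack=5, mu0=80.0, sigma0=20.0)
        elif m == "respiratory":
            base = dict(m="respiratory", freq_range=(0.0, 1.0), rate_max=60,
                        slack=3, mu0=14.0, sigma0=4.0)
        else:
            raise ValueError(f"unknown task {m!r}; expected 'pulse' or 'respiratory'")
        base.update(overrides)
        return cls(**base)


@dataclass
class RateProbability:
    """Softmax probabilities over the task's integer rate grid (sum to 1)."""

    rates: np.ndarray
    probs: np.ndarray


def amplitude_spectrum(x, fs: float, pad_to: int):
    """Zero-padded real-input DFT magnitude; freqs[k] = k * fs / pad_to."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if pad_to < x.size:
        raise ValueError("pad_to must be >= input length")
    mags = np.abs(np.fft.rfft(x, n=pad_to))
    freqs = np.fft.rfftfreq(pad_to, d=1.0 / fs)
    return freqs, mags


def get_proba_estimations(x, fs: float, cfg: TaskConfig) -> RateProbability:
    """Per-rate probability of a segment: standardized in-range spectrum -> softmax.

    The spectrum is bounded to the task's frequency range; standardization
    statistics use the in-range bins only, so probabilities are invariant to
    any positive rescaling of the raw signal.
    """
    x = np.asarray(x, dtype=float)
    if x.size < cfg.min_subseg_s * fs:
        raise ValueError(
            f"segment of {x.size / fs:.2f} s is shorter than the "
            f"{cfg.min_subseg_s:.0f}-s minimum"
        )
    pad_to = int(round(60 * fs))
    _, mags = amplitude_spectrum(x, fs, pad_to)
    # bin k corresponds to k/60 Hz, i.e. integer rate k per minute
    rates = np.arange(cfg.rate_max + 1)
    in_range = mags[: cfg.rate_max + 1]
    sd = in_range.std()
    if sd == 0:
        z = np.zeros_like(in_range)
    else:
        z = (in_range - in_range.mean()) / sd
    return RateProbability(rates=rates, probs=_softmax(z))
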