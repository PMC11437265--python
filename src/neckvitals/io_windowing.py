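"""Signal file I/O and sliding-window segmentation.

Recordings are plain CSV files with a ``time`` column (seconds) and one
column per sensor channel (``red``, ``ir``, ``acc_x``, ``acc_y``, ``acc_z``).
Channels are uniformly sampled; the per-channel sampling rate is either
declared by the caller or inferred from the median time delta.

All downstream processing runs on 30-s windows hopped by 1 s.  Window
timestamps are anchored at the window END, so the estimate at time *t* is
computed from the preceding 30 s only (causal, monitoring-style).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

KNOWN_CHANNELS = ("red", "ir", "acc_x", "acc_y", "acc_z")


@dataclass
class SignalChannel:
    """A uniformly sampled raw sensor trace."""

    label: str
    fs: float
    samples: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.size == 0:
            raise ValueError("channel has no samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: 30-s windows hopped by 1 s by default."""

    length_s: float = 30.0
    step_s: float = 1.0

    def __post_init__(self) -> None:
        if self.length_s <= 0 or self.step_s <= 0:
            raise ValueError("window length and step must be positive")
        if self.step_s > self.length_s:
            raise ValueError("step must not exceed window length")


@dataclass
class RateSeries:
    """A reference (ground-truth) rate trace in per-minute units."""

    times: np.ndarray
    values: np.ndarray
    units: str = "BPM"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values differ in length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("rates must be non-negative")


@dataclass
class RateEstimate:
    """Per-timestep output of the tracker.

    ``band_center/low/high`` and ``rate_value`` are absent (None) when the
    timestep was gated out as unconfident; such timesteps are still written
    so that output percentages can be computed against all processed windows.
    """

    t: float
    band_center: Optional[int] = None
    band_low: Optional[int] = None
    band_high: Optional[int] = None
    rate_value: Optional[int] = None
    confident: bool = False


def read_recording(
    path,
    expected_channels: Sequence[str],
    fs: Optional[dict] = None,
) -> dict:
    """Load the requested channels from a recording CSV.

    Parameters
    ----------
    path:
        CSV file with a header naming a ``time`` column plus channel columns.
    expected_channels:
        Channel labels to load; a missing one raises ``KeyError``.
    fs:
        Optional map label -> sampling rate in Hz; when omitted the rate is
        inferred from the median time delta.
    """
    df = pd.read_csv(path)
    if "time" not in df.columns:
        raise ValueError(f"{path}: no 'time' column in header")
    t = df["time"].to_numpy(dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: time column is not strictly increasing")
    channels = {}
    for label in expected_channels:
        if label not in df.columns:
            raise KeyError(f"channel {label} not found in {path}")
        col = df[label].to_numpy(dtype=float)
        mask = ~np.isnan(col)
        rate = None if fs is None else fs.get(label)
        if rate is None:
            tt = t[mask]
            if tt.size < 2:
                raise ValueError(f"{path}: cannot infer fs for channel {label}")
            rate = 1.0 / float(np.median(np.diff(tt)))
        channels[label] = SignalChannel(
            label=label, fs=float(rate), samples=col[mask], t0=float(t[mask][0])
        )
    t0s = {c.t0 for c in channels.values()}
    if len(t0s) > 1 and max(t0s) - min(t0s) > 1e-9:
        raise ValueError(f"{path}: channels do not share a common start time")
    return channels


def sliding_windows(
    channel: SignalChannel, spec: WindowSpec = WindowSpec()
) -> Iterator[tuple]:
    """Yield ``(t_end, samples)`` windows of ``spec.length_s`` seconds.

    Windows end at t = length_s, length_s + step_s, ...; each covers exactly
    ``length_s * fs`` samples.  A recording shorter than one window yields
    nothing (with a warning).
    """
    n_win = int(round(spec.length_s * channel.fs))
    n_step = spec.step_s * channel.fs
    if channel.samples.size < n_win:
        warnings.warn(
            f"channel {channel.label}: {channel.duration:.1f} s is shorter "
            f"than one {spec.length_s:.0f}-s window; no windows produced"
        )
        return
    n_total = channel.samples.size
    count = int(np.floor((n_total - n_win) / n_step)) + 1
    for i in range(count):
        end = n_win + int(round(i * n_step))
        t_end = channel.t0 + end / channel.fs
        yield t_end, channel.samples[end - n_win : end]


def write_estimates(path, estimates: Sequence[RateEstimate]) -> None:
    """Write estimates to CSV: t, rate_value, band_low, band_high, confident.

    Suppressed (unconfident) timesteps appear with empty value/band columns
    and confident=0, preserving the full timeline.
    """
    rows = []
    for e in estimates:
        rows.append(
            {
                "t": e.t,
                "rate_value": e.rate_value,
                "band_low": e.band_low,
                "band_high": e.band_high,
                "confident": int(e.confident),
            }
        )
    df = pd.DataFrame(rows, columns=["t", "rate_value", "band_low", "band_high", "confident"])
    df.to_csv(path, index=False)


def read_estimates(path) -> list:
    """Read back a file written by :func:`write_estimates` (lossless)."""
    df = pd.read_csv(path)
    out = []
    for row in df.itertuples(index=False):
        low = None if pd.isna(row.band_low) else int(row.band_low)
        high = None if pd.isna(row.band_high) else int(row.band_high)
        # band spans [c - floor(slack/2), c + ceil(slack/2)], so the center
        # is recoverable as low + floor((high - low)/2)
        center = None if low is None else low + (high - low) // 2
        out.append(
            RateEstimate(
                t=float(row.t),
                band_center=center,
                band_low=low,
                band_high=high,
                rate_value=None if pd.isna(row.rate_value) else int(row.rate_value),
                confident=bool(row.confident),
            )
        )
    return out


def write_rate_series(path, series: RateSeries) -> None:
    pd.DataFrame({"time": series.times, "rate": series.values}).to_csv(path, index=False)


def read_rate_series(path, units: str = "BPM") -> RateSeries:
    df = pd.read_csv(path)
    return RateSeries(df["time"].to_numpy(), df["rate"].to_numpy(), units=units)
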