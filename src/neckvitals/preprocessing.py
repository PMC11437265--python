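"""Filter pipelines turning raw dual-channel windows into standardized segments.

Two pipelines are implemented, one per measurement task:

* **Pulse** (PPG Red + IR, 400 Hz in, 100 Hz out): polyphase decimation with
  anti-aliasing, a 0.05-s median filter against transient spikes, a 1st-order
  [0.5, 4] Hz Butterworth band-pass, per-channel standardization, time-wise
  addition of the two channels, baseline removal by subtracting a 2nd-order
  Savitzky-Golay fit (1.6-s window), and a final standardization.

* **Respiratory** (PPG Red + IR or Acc Y + Z, native fs): a 1st-order
  [0.1, 1] Hz Butterworth band-pass applied to the full-length stream before
  windowing, then per window a 2nd-order 2-s Savitzky-Golay smooth, per-channel
  standardization, time-wise addition, a second identical smooth, a numerical
  first derivative to suppress residual baseline wander, and standardization.

All IIR filters run forward-backward (zero-phase): the spectral steps
downstream are phase-insensitive and zero-phase filtering avoids group-delay
asymmetry at window edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

PULSE_FS_OUT = 100.0
PULSE_BAND_HZ = (0.5, 4.0)
RESP_BAND_HZ = (0.1, 1.0)
MEDIAN_WIN_S = 0.05
PULSE_SG_WIN_S = 1.6
RESP_SG_WIN_S = 2.0
SG_ORDER = 2


@dataclass
class ProcessedSegment:
    """One standardized 30-s analysis window ready for spectral scoring."""

    t: float
    task: str          # 'pulse' | 'respiratory'
    modality: str      # 'ppg' | 'acc'
    fs: float
    samples: np.ndarray


def standardize(x) -> np.ndarray:
    """(x - mean) / std; a (numerically) constant input maps to all zeros.

    The degenerate threshold is relative to the data magnitude so that
    float residue left behind by filtering a constant signal is not blown
    up to unit variance.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("cannot standardize an empty sequence")
    sd = x.std()
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _odd_window(seconds: float, fs: float) -> int:
    n = int(round(seconds * fs))
    return n + 1 if n % 2 == 0 else n


def _bandpass(x: np.ndarray, band, fs: float) -> np.ndarray:
    sos = signal.butter(1, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def preprocess_pulse_window(
    red: np.ndarray, ir: np.ndarray, fs_in: float = 400.0, t: float = 0.0
) -> ProcessedSegment:
    """Run the pulse pipeline on one 30-s Red/IR window pair."""
    red = np.asarray(red, dtype=float)
    ir = np.asarray(ir, dtype=float)
    if red.size != ir.size:
        raise ValueError("red and ir windows differ in length")
    q = int(round(fs_in / PULSE_FS_OUT))
    fs = fs_in / q if q > 1 else fs_in

    chans = []
    for x in (red, ir):
        if q > 1:
            x = signal.decimate(x, q, zero_phase=True)
        k = _odd_window(MEDIAN_WIN_S, fs)
        x = ndimage.median_filter(x, size=k, mode="reflect")
        x = _bandpass(x, PULSE_BAND_HZ, fs)
        chans.append(standardize(x))
    combined = chans[0] + chans[1]
    win = _odd_window(PULSE_SG_WIN_S, fs)
    baseline = signal.savgol_filter(combined, win, SG_ORDER)
    out = standardize(combined - baseline)
    return ProcessedSegment(t=t, task="pulse", modality="ppg", fs=fs, samples=out)


def resp_stream_filter(x: np.ndarray, fs: float) -> np.ndarray:
    """Respiratory band-pass applied to the full channel stream (pre-window)."""
    return _bandpass(np.asarray(x, dtype=float), RESP_BAND_HZ, fs)


def preprocess_resp_window(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    fs: float,
    modality: str = "ppg",
    t: float = 0.0,
    prefiltered: bool = True,
) -> ProcessedSegment:
    """Run the respiratory pipeline on one window pair.

    ``ch_a``/``ch_b`` are (red, ir) or (acc_y, acc_z) windows.  The stream
    band-pass is stateful across windows, so callers normally filter whole
    channels with :func:`resp_stream_filter` first and pass
    ``prefiltered=True``; ``prefiltered=False`` filters the window itself
    (acceptable for isolated windows).
    """
    a = np.asarray(ch_a, dtype=float)
    b = np.asarray(ch_b, dtype=float)
    if a.size != b.size:
        raise ValueError("channel windows differ in length")
    win = _odd_window(RESP_SG_WIN_S, fs)

    chans = []
    for x in (a, b):
        if not prefiltered:
            x = _bandpass(x, RESP_BAND_HZ, fs)
        x = signal.savgol_filter(x, win, SG_ORDER)
        chans.append(standardize(x))
    combined = chans[0] + chans[1]
    combined = signal.savgol_filter(combined, win, SG_ORDER)
    # numerical first derivative (first difference x fs, length preserved)
    d = np.diff(combined)
    if d.size == 0:
        d = np.zeros(1)
    deriv = np.concatenate(([d[0]], d)) * fs
    out = standardize(deriv)
    return ProcessedSegment(t=t, task="respiratory", modality=modality, fs=fs, samples=out)
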