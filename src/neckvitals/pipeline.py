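"""End-to-end orchestration: windows -> preprocessing -> dominance -> tracking.

The per-modality dominance scores are computed once per timestep and can be
fused in any combination afterwards, so comparing PPG-only, Acc-only and
PPG+Acc trackers costs a single preprocessing pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .dominance import DominanceScores, combine_modalities, get_dominance_scores
from .estimator import init_state, step
from .io_windowing import RateEstimate, SignalChannel, WindowSpec, sliding_windows
from .preprocessing import (
    preprocess_pulse_window,
    preprocess_resp_window,
    resp_stream_filter,
)
from .spectral import TaskConfig

log = logging.getLogger("neckvitals")

MODALITY_CHANNELS = {"ppg": ("red", "ir"), "acc": ("acc_y", "acc_z")}


def validate_task_modalities(task: str, modalities: Sequence[str]) -> None:
    mods = set(modalities)
    if not mods or not mods <= set(MODALITY_CHANNELS):
        raise ValueError(f"modalities must be a non-empty subset of "
                         f"{sorted(MODALITY_CHANNELS)}, got {sorted(mods)}")
    if task == "pulse" and mods != {"ppg"}:
        raise ValueError("pulse rate estimation supports the PPG modality only")


def _segments(channels: Dict[str, SignalChannel], cfg: TaskConfig,
              modality: str, window: WindowSpec):
    a_label, b_label = MODALITY_CHANNELS[modality]
    a, b = channels[a_label], channels[b_label]
    if a.fs != b.fs:
        raise ValueError(f"{a_label}/{b_label} sampling rates differ")
    if cfg.m == "respiratory":
        # stateful stream filter runs over the whole channel before windowing
        a = SignalChannel(a.label, a.fs, resp_stream_filter(a.samples, a.fs), a.t0)
        b = SignalChannel(b.label, b.fs, resp_stream_filter(b.samples, b.fs), b.t0)
    for (ta, xa), (_, xb) in zip(sliding_windows(a, window), sliding_windows(b, window)):
        if cfg.m == "pulse":
            yield preprocess_pulse_window(xa, xb, fs_in=a.fs, t=ta)
        else:
            yield preprocess_resp_window(xa, xb, a.fs, modality=modality,
                                         t=ta, prefiltered=True)


def compute_dominance_series(
    channels: Dict[str, SignalChannel],
    cfg: TaskConfig,
    modalities: Sequence[str] = ("ppg",),
    window: WindowSpec = WindowSpec(),
) -> List[Tuple[float, Dict[str, DominanceScores]]]:
    """Per-timestep dominance scores for each requested modality."""
    validate_task_modalities(cfg.m, modalities)
    iters = {m: _segments(channels, cfg, m, window) for m in modalities}
    series: List[Tuple[float, Dict[str, DominanceScores]]] = []
    while True:
        ds_map: Dict[str, DominanceScores] = {}
        t = None
        try:
            for m in modalities:
                seg = next(iters[m])
                t = seg.t if t is None else t
                ds_map[m] = get_dominance_scores(seg.samples, seg.fs, cfg)
        except StopIteration:
            break
        series.append((t, ds_map))
    return series


def track(
    ds_series: Sequence[Tuple[float, Dict[str, DominanceScores]]],
    cfg: TaskConfig,
    modalities: Optional[Sequence[str]] = None,
) -> List[RateEstimate]:
    """Run the EWMA tracker over a dominance-score series.

    Suppressed timesteps appear as unconfident placeholder estimates so the
    output covers every processed window.
    """
    state = init_state(cfg)
    out: List[RateEstimate] = []
    for t, ds_map in ds_series:
        mods = list(ds_map) if modalities is None else list(modalities)
        ds: DominanceScores = {}
        for m in mods:
            ds = combine_modalities(ds, ds_map[m])
        est, state = step(ds, state, cfg, t_s=t)
        out.append(est if est is not None else RateEstimate(t=t, confident=False))
    return out


def run_estimate(
    channels: Dict[str, SignalChannel],
    cfg: TaskConfig,
    modalities: Sequence[str] = ("ppg",),
    window: WindowSpec = WindowSpec(),
) -> List[RateEstimate]:
    """Full pipeline on loaded channels; logs the confident-output fraction."""
    series = compute_dominance_series(channels, cfg, modalities, window)
    estimates = track(series, cfg, modalities)
    if estimates:
        pct = 100.0 * sum(e.confident for e in estimates) / len(estimates)
        log.info("confident output on %.1f%% of %d timesteps", pct, len(estimates))
    return estimates
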