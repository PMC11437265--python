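"""Recursive artifact-guided dissection and per-rate dominance scoring.

A standardized segment is scanned for amplitude excursions beyond +/-3
standard units.  Clean stretches around the excursions, when at least 5 s
long, are re-standardized and scored recursively; each (sub-)segment's
softmax rate probabilities are aggregated into a sparse per-rate dominance
score with weight 1/level, so shorter (deeper) sub-segments — whose spectra
are less certain — contribute proportionally less.  Probabilities below 0.1
are dropped as negligible.  Recursion stops beyond depth 20 or below 5 s.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .preprocessing import standardize
from .spectral import RateProbability, TaskConfig, get_proba_estimations

DominanceScores = Dict[int, float]


def find_clean_subsegments(
    x: np.ndarray, fs: float, cfg: TaskConfig
) -> List[Tuple[int, int]]:
    """Maximal deviation-free sample intervals of at least ``min_subseg_s``.

    Returns ``[]`` both when the segment has no excursion beyond
    ``+/-dev_bound`` (no dissection needed) and when excursions exist but no
    clean stretch is long enough (the caller then falls back to scoring the
    contaminated segment itself).
    """
    x = np.asarray(x, dtype=float)
    bad = np.abs(x) > cfg.dev_bound
    if not bad.any():
        return []
    margin = int(round(cfg.dev_margin_s * fs))
    if margin:
        bad = np.convolve(bad, np.ones(2 * margin + 1), mode="same") > 0
    min_n = int(round(cfg.min_subseg_s * fs))
    out = []
    # clean intervals = complement gaps between runs of bad samples
    edges = np.flatnonzero(np.diff(np.concatenate(([True], bad, [True]))))
    for start, end in zip(edges[::2], edges[1::2]):
        if end - start >= min_n:
            out.append((int(start), int(end)))
    return out


def update_ds(
    ds: DominanceScores, proba: RateProbability, level: int, cfg: TaskConfig
) -> DominanceScores:
    """Aggregate one probability estimate into the dominance scores.

    Rates whose probability reaches ``proba_floor`` (0.1) gain
    ``proba / level``; everything else is untouched.  Mutates and returns
    ``ds``.
    """
    if level < 1:
        raise ValueError("recursion level starts at 1")
    keep = proba.probs >= cfg.proba_floor
    for r, p in zip(proba.rates[keep], proba.probs[keep]):
        ds[int(r)] = ds.get(int(r), 0.0) + float(p) / level
    return ds


def get_dominance_scores(
    x: np.ndarray, fs: float, cfg: TaskConfig, level: int = 1
) -> DominanceScores:
    """Score a standardized segment, dissecting recursively around artifacts.

    When accepted clean sub-segments exist (and the depth cap is not hit),
    only they contribute — re-standardized, at ``level + 1``; the
    contaminated parent contributes nothing.  Otherwise the segment itself
    is scored at the current level.
    """
    x = np.asarray(x, dtype=float)
    ds: DominanceScores = {}
    intervals = [] if level >= cfg.max_depth else find_clean_subsegments(x, fs, cfg)
    if not intervals:
        return update_ds(ds, get_proba_estimations(x, fs, cfg), level, cfg)
    for start, end in intervals:
        child = get_dominance_scores(standardize(x[start:end]), fs, cfg, level + 1)
        for r, s in child.items():
            ds[r] = ds.get(r, 0.0) + s
    return ds


def combine_modalities(
    ds_a: DominanceScores, ds_b: DominanceScores
) -> DominanceScores:
    """Rate-wise additive fusion of per-modality dominance scores."""
    out = dict(ds_a)
    for r, s in ds_b.items():
        out[r] = out.get(r, 0.0) + s
    return out
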