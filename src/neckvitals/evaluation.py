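"""Band-aware agreement statistics against a reference rate trace.

Errors for band estimates are measured to the nearest band bound (zero when
the truth falls inside the band).  Summary metrics follow monitoring-study
conventions: RMSE / MAE / error STD over emitted estimates, the percentage
of timesteps with output, and the percentage of outputs within the clinical
margin.  Bland-Altman limits of agreement use the components-of-variance
formulation for repeated measurements per subject (one-way random-effects
decomposition of the differences).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .io_windowing import RateEstimate, RateSeries
from .spectral import TaskConfig


@dataclass
class PairedRecord:
    subject: str
    t: float
    estimate: RateEstimate
    reference: float


@dataclass
class AgreementReport:
    rmse: float
    mae: float
    error_std: float
    pct_output: float
    pct_within_margin: float
    bias: Optional[float] = None
    loa_low: Optional[float] = None
    loa_high: Optional[float] = None
    n_emitted: int = 0
    n_total: int = 0


def band_error(band_low: float, band_high: float, truth: float) -> float:
    """0 inside the band, else the distance to the nearest bound."""
    if band_low > band_high:
        raise ValueError("band_low must not exceed band_high")
    if band_low <= truth <= band_high:
        return 0.0
    return min(abs(truth - band_low), abs(truth - band_high))


def pair_records(
    estimates: Sequence[RateEstimate],
    reference: RateSeries,
    subject: str = "s1",
    tol_s: float = 1.0,
    lag_s: float = 0.0,
) -> list:
    """Pair every estimate with the nearest reference sample within ``tol_s``.

    Estimates are timestamped at the window END; ``lag_s`` shifts the lookup
    back in time (e.g. half the window length to score against the truth at
    the window center, so the inherent window latency is not double-counted).
    """
    out = []
    rt = reference.times
    for e in estimates:
        i = int(np.argmin(np.abs(rt - (e.t - lag_s))))
        if abs(rt[i] - (e.t - lag_s)) <= tol_s:
            out.append(PairedRecord(subject=subject, t=e.t, estimate=e,
                                    reference=float(reference.values[i])))
    return out


def _signed_error(e: RateEstimate, truth: float, mode: str) -> Optional[float]:
    """estimate - reference; band mode measures from the violated bound."""
    if mode == "value":
        if e.rate_value is None:
            return None
        return e.rate_value - truth
    if not e.confident or e.band_low is None:
        return None
    if truth > e.band_high:
        return e.band_high - truth
    if truth < e.band_low:
        return e.band_low - truth
    return 0.0


def summarize(
    records: Sequence[PairedRecord], cfg: TaskConfig, mode: str = "value"
) -> AgreementReport:
    """Error metrics over the emitted estimates of a full timeline.

    ``records`` should cover every processed window, including suppressed
    timesteps, so that ``pct_output`` is meaningful.

    ``mode='value'`` scores |rate_value - truth|; ``mode='band'`` scores the
    band-aware error.  The clinical margin is the slack for values and
    slack/2 beyond the band bounds for bands.
    """
    errs = []
    for rec in records:
        d = _signed_error(rec.estimate, rec.reference, mode)
        if d is not None:
            errs.append(d)
    n_total = len(records)
    n = len(errs)
    pct_output = 100.0 * n / n_total if n_total else 0.0
    if n == 0:
        return AgreementReport(rmse=math.nan, mae=math.nan, error_std=math.nan,
                               pct_output=pct_output, pct_within_margin=0.0,
                               n_emitted=0, n_total=n_total)
    d = np.asarray(errs)
    margin = cfg.slack if mode == "value" else cfg.slack / 2.0
    return AgreementReport(
        rmse=float(np.sqrt(np.mean(d**2))),
        mae=float(np.mean(np.abs(d))),
        error_std=float(np.std(d)),
        pct_output=pct_output,
        pct_within_margin=100.0 * float(np.mean(np.abs(d) <= margin)),
        n_emitted=n,
        n_total=n_total,
    )


def bland_altman_cov(groups: Dict[str, np.ndarray]):
    """Bias and 95% limits of agreement for repeated measures per subject.

    ``groups`` maps subject id -> array of paired differences
    (estimate - reference).  Between- and within-subject variance components
    come from the one-way ANOVA mean squares, with the standard n0 correction
    for unequal group sizes; negative component estimates are truncated at
    zero.  LoA = bias +/- 1.96 * sqrt(var_between + var_within).  A single
    subject reduces to the classical Bland-Altman limits.
    """
    arrs = [np.asarray(v, dtype=float) for v in groups.values() if len(v) > 0]
    if not arrs:
        raise ValueError("no differences supplied")
    alld = np.concatenate(arrs)
    if alld.size < 2:
        raise ValueError("at least two paired differences are required")
    bias = float(alld.mean())
    k = len(arrs)
    if k == 1:
        sd = float(alld.std(ddof=1))
        return bias, bias - 1.96 * sd, bias + 1.96 * sd
    n_i = np.array([a.size for a in arrs], dtype=float)
    n_tot = n_i.sum()
    grand = alld.mean()
    ssb = float(sum(n * (a.mean() - grand) ** 2 for n, a in zip(n_i, arrs)))
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    msb = ssb / (k - 1)
    msw = ssw / (n_tot - k) if n_tot > k else 0.0
    n0 = (n_tot - (n_i**2).sum() / n_tot) / (k - 1)
    var_between = max(0.0, (msb - msw) / n0)
    var_within = msw
    half = 1.96 * math.sqrt(var_between + var_within)
    return bias, bias - half, bias + half
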