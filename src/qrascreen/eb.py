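"""Empirical-Bayes expected crash frequency with a time-trend adjustment.

Each segment's expected annual crash frequency N_i combines the model
prediction N~_i (from the crash prediction model) with the observed mean
annual count Nbar_i through a single global weight:

    beta = 1 / (1 + V(N~) / E(N~))
    N_i  = [beta * N~_i + (1 - beta) * Nbar_i] * [1 - ny * (alpha / 100)]

where V and E are the sample variance (n-1 denominator) and mean of the
predictions across the screened network, ny is the number of study years and
alpha a signed annual trend percentage (positive = assumed annual reduction
under the multiplier's literal sign convention).

Note this weight is a *global* cross-segment scalar, not the classical
per-site EB weight derived from the NB dispersion; the method is implemented
as specified for network screening, where a single shrinkage factor is shared
by all segments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cpm import CpmCoefficients, predict_crash_frequency
from .data_model import CrashRecord, Segment, StudyConfig

__all__ = ["EBEstimate", "compute_weight", "expected_frequency", "eb_screen"]


@dataclass(frozen=True)
class EBEstimate:
    segment_id: int
    predicted: float  # N~_i, crashes/yr
    observed_mean: float  # Nbar_i, crashes/yr
    weight: float  # beta, global
    expected: float  # N_i after trend adjustment


def compute_weight(predictions: Sequence[float]) -> float:
    """Global EB weight beta = 1 / (1 + V(N~)/E(N~)) over the screened segments.

    Uses the n-1 sample variance. Requires at least two segments and a
    positive mean prediction.
    """
    preds = np.asarray(predictions, dtype=float)
    if preds.size < 2:
        raise ValueError("need predictions for at least 2 segments")
    mean = preds.mean()
    if mean <= 0:
        raise ValueError("mean predicted frequency must be > 0")
    var = preds.var(ddof=1)
    return 1.0 / (1.0 + var / mean)


def expected_frequency(
    pred: float, obs_mean: float, weight: float, trend_pct: float, years: int
) -> float:
    """EB expected annual crash frequency with the trend multiplier applied."""
    factor = 1.0 - years * (trend_pct / 100.0)
    if factor <= 0:
        raise ValueError(
            f"trend multiplier 1 - {years}*({trend_pct}/100) = {factor:.3f} is "
            "nonpositive; shorten the study period or revisit the trend percentage"
        )
    return (weight * pred + (1.0 - weight) * obs_mean) * factor


def eb_screen(
    segments: Sequence[Segment],
    crashes: Sequence[CrashRecord],
    coef: CpmCoefficients,
    config: StudyConfig,
) -> pd.DataFrame:
    """EB-screen a network: one row per segment with predicted, observed and
    expected annual crash frequencies.

    The observed mean is total crashes over the study period divided by the
    number of study years; beta is the single global weight over all screened
    segments.
    """
    counts: dict[int, int] = {s.segment_id: 0 for s in segments}
    for c in crashes:
        if c.segment_id in counts:
            counts[c.segment_id] += 1

    preds = {s.segment_id: predict_crash_frequency(s, coef) for s in segments}
    beta = compute_weight(list(preds.values()))

    rows = []
    for s in segments:
        pred = preds[s.segment_id]
        obs = counts[s.segment_id] / config.study_years
        rows.append(
            {
                "segment_id": s.segment_id,
                "predicted": pred,
                "observed_mean": obs,
                "weight": beta,
                "expected": expected_frequency(
                    pred, obs, beta, config.trend_pct_per_year, config.study_years
                ),
            }
        )
    return pd.DataFrame(rows).sort_values("segment_id").reset_index(drop=True)
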