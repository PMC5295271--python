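"""Monetized crash consequences and segment risk scores.

A crash's consequence is the sum of a direct loss (property damage and
occupant injury, looked up per crash type) and an indirect loss: the
non-recurrent congestion delay it causes, converted to money at the value of
time c / (td * th) yuan per vehicle-hour (annual income over annual working
hours, one occupant per vehicle). The expected loss per crash on a segment
averages these over the joint time/type distribution, either exactly
(probability-weighted sum over the joint support) or by seeded Monte-Carlo
sampling. The segment's risk is

    R_i = N_i * E[loss per crash]

i.e. expected crash frequency times monetized consequence, and hotspots are
ranked by R_i (QRA) or by N_i alone (conventional EB screening).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .crash_profile import CrashProfile, sample_crash_events
from .data_model import CrashRecord, CrashType, Segment, StudyConfig, crash_duration
from .queuing import QueueScenario, non_recurrent_delay, reduced_capacity, initial_queue

__all__ = [
    "monetize_delay",
    "direct_loss",
    "mean_durations",
    "expected_loss_per_crash",
    "risk_score",
    "rank_hotspots",
    "risk_screen",
]

logger = logging.getLogger(__name__)


def monetize_delay(ncd: float, income_per_year: float, work_days: float, work_hours: float) -> float:
    """Indirect loss (yuan) of a delay in vehicle-hours.

    Value of time is annual income / (working days * working hours per day),
    i.e. yuan per vehicle-hour assuming one occupant per vehicle.
    """
    if work_days <= 0 or work_hours <= 0:
        raise ValueError("working days and hours must be > 0")
    return ncd * income_per_year / (work_days * work_hours)


def direct_loss(crash_type: CrashType, table: Mapping[CrashType, float]) -> float:
    """Direct monetary loss of one crash of the given type (table lookup)."""
    try:
        return table[crash_type]
    except KeyError:
        raise KeyError(f"no direct-loss entry for crash type {crash_type!r}") from None


def mean_durations(
    crashes: Sequence[CrashRecord], rounding: str = "nearest_minute"
) -> dict[CrashType, float]:
    """Mean crash duration (hours) per type, falling back to the global mean
    for types with no observed crashes."""
    if not crashes:
        raise ValueError("need at least one crash to estimate durations")
    durations: dict[CrashType, list[float]] = {t: [] for t in CrashType}
    for c in crashes:
        durations[c.crash_type].append(crash_duration(c, rounding))
    overall = float(np.mean([d for ds in durations.values() for d in ds]))
    return {
        t: (float(np.mean(ds)) if ds else overall) for t, ds in durations.items()
    }


def _cell_losses(
    segment: Segment,
    traffic: pd.DataFrame,
    profile: CrashProfile,
    config: StudyConfig,
    durations: Mapping[CrashType, float],
) -> tuple[list[tuple[CrashType, int]], np.ndarray, np.ndarray]:
    """Total loss (direct + indirect, yuan) for every joint (type, hour) cell.

    Traffic conditions are conditioned on the hour bin only: volume and speed
    from the segment detector give the initial queue, the approach-detector
    flow gives the arrival rate.
    """
    rows = traffic[traffic["segment_id"] == segment.segment_id].set_index("hour")
    keys, p = profile.cells()
    needed = sorted({t for (_, t), pi in zip(keys, p) if pi > 0})
    missing = [t for t in needed if t not in rows.index]
    if missing:
        raise ValueError(
            f"segment {segment.segment_id}: no traffic rows for hours {missing} "
            "with positive crash probability"
        )
    losses = np.empty(len(keys))
    for i, (s, t) in enumerate(keys):
        if p[i] == 0:
            losses[i] = 0.0
            continue
        row = rows.loc[t]
        q0 = initial_queue(segment.length_km, float(row["speed"]), float(row["volume"]))
        scenario = QueueScenario(
            initial_queue=q0,
            approach_flow=float(row["approach_flow"]),
            reduced_capacity=reduced_capacity(segment.capacity, config.capacity_reduction[s]),
            capacity=segment.capacity,
            incident_duration=durations[s],
        )
        idl = monetize_delay(
            non_recurrent_delay(scenario).ncd,
            config.income_per_year,
            config.work_days_per_year,
            config.work_hours_per_day,
        )
        losses[i] = idl + direct_loss(s, config.direct_loss)
    return keys, p, losses


def expected_loss_per_crash(
    segment: Segment,
    profile: CrashProfile,
    traffic: pd.DataFrame,
    config: StudyConfig,
    durations: Mapping[CrashType, float],
    mode: Literal["exact", "monte_carlo"] = "exact",
    n_draws: int = 10_000,
    seed: int | None = None,
) -> float:
    """Expected total loss (yuan) of one crash on a segment.

    ``exact`` computes sum over (s, t) of (IDL + DL) * P(s, t). ``monte_carlo``
    averages the loss over ``n_draws`` sampled (s, t) events per replicate
    across ``config.mc_reps`` replicates with the given seed.
    """
    keys, p, losses = _cell_losses(segment, traffic, profile, config, durations)
    if mode == "exact":
        return float(np.dot(p, losses))
    if mode != "monte_carlo":
        raise ValueError(f"unknown mode {mode!r}")
    if seed is None:
        seed = config.seed
    loss_of = {k: losses[i] for i, k in enumerate(keys)}
    reps = sample_crash_events(n_draws, profile, seed=seed, reps=config.mc_reps)
    return float(np.mean([np.mean([loss_of[k] for k in rep]) for rep in reps]))


def risk_score(expected_crashes: float, loss_per_crash: float) -> float:
    """Segment risk R_i = N_i * E[loss per crash] (yuan)."""
    if expected_crashes < 0 or loss_per_crash < 0:
        raise ValueError("risk inputs must be >= 0")
    return expected_crashes * loss_per_crash


def rank_hotspots(
    scores: pd.DataFrame, top_n: int | None = None, method: str = "qra"
) -> pd.DataFrame:
    """Rank segments by descending score; ties break by ascending segment_id.

    ``scores`` needs columns segment_id and score. Returns columns
    (rank, segment_id, score, method).
    """
    if method not in {"qra", "eb"}:
        raise ValueError("method must be 'qra' or 'eb'")
    m = len(scores)
    if top_n is None:
        top_n = m
    elif top_n > m:
        logger.warning("top_n=%d exceeds %d segments; returning all", top_n, m)
        top_n = m
    out = (
        scores[["segment_id", "score"]]
        .sort_values(["score", "segment_id"], ascending=[False, True], kind="mergesort")
        .head(top_n)
        .reset_index(drop=True)
    )
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    out["method"] = method
    return out


def risk_screen(
    segments: Sequence[Segment],
    traffic: pd.DataFrame,
    crashes: Sequence[CrashRecord],
    eb_estimates: pd.DataFrame,
    profile: CrashProfile,
    config: StudyConfig,
    mode: Literal["exact", "monte_carlo"] = "exact",
    n_draws: int = 10_000,
) -> pd.DataFrame:
    """Full loss/risk table for a screened network.

    Combines the EB expected crash frequencies with per-crash expected losses
    into one row per segment: expected crashes, direct and indirect expected
    loss components, expected loss per crash, risk, and the ranks under both
    the QRA (risk) and EB (frequency) criteria.
    """
    durations = mean_durations(crashes)
    expected = eb_estimates.set_index("segment_id")["expected"]
    exp_direct = sum(profile.type_probs[s] * config.direct_loss[s] for s in profile.type_probs)

    rows = []
    for seg in segments:
        loss = expected_loss_per_crash(
            seg, profile, traffic, config, durations,
            mode=mode, n_draws=n_draws, seed=config.seed + seg.segment_id,
        )
        ni = float(expected.loc[seg.segment_id])
        rows.append(
            {
                "segment_id": seg.segment_id,
                "expected_crashes": ni,
                "direct": ni * exp_direct,
                "indirect": ni * max(loss - exp_direct, 0.0),
                "expected_loss_per_crash": loss,
                "risk": risk_score(ni, loss),
            }
        )
    table = pd.DataFrame(rows)
    qra = rank_hotspots(table.rename(columns={"risk": "score"}), method="qra")
    eb = rank_hotspots(table.rename(columns={"expected_crashes": "score"}), method="eb")
    table = table.merge(
        qra[["segment_id", "rank"]].rename(columns={"rank": "rank_qra"}), on="segment_id"
    ).merge(
        eb[["segment_id", "rank"]].rename(columns={"rank": "rank_eb"}), on="segment_id"
    )
    return table.sort_values("segment_id").reset_index(drop=True)
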