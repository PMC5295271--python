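"""Crash time-of-day and type distributions, and Monte-Carlo event sampling.

The occurrence hour t and type s of a crash are treated as independent of
each other and of location, so the joint probability is the product of the
empirical marginals, P(s, t) = Ps(s) * Pt(t). Hours outside the active
operating window (expressways here close overnight for maintenance) carry
zero mass. Expected crash counts are assigned concrete (type, hour) pairs by
seeded sampling from the joint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import CrashRecord, CrashType

__all__ = ["CrashProfile", "estimate_profile", "sample_crash_events"]

_TYPE_ORDER = [CrashType.SINGLE, CrashType.TWO, CrashType.MULTI]


@dataclass(frozen=True)
class CrashProfile:
    """Marginal type/hour distributions and their product joint."""

    type_probs: dict[CrashType, float]
    hour_probs: dict[int, float]

    def __post_init__(self) -> None:
        for name, probs in (("type_probs", self.type_probs), ("hour_probs", self.hour_probs)):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, expected 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"{name} contains negative probabilities")

    @property
    def joint(self) -> dict[tuple[CrashType, int], float]:
        """P(s, t) = Ps(s) * Pt(t)."""
        return {
            (s, t): ps * pt
            for s, ps in self.type_probs.items()
            for t, pt in self.hour_probs.items()
        }

    def cells(self) -> tuple[list[tuple[CrashType, int]], np.ndarray]:
        """Joint support in a deterministic order with its probability vector."""
        hours = sorted(self.hour_probs)
        keys = [(s, t) for s in _TYPE_ORDER if s in self.type_probs for t in hours]
        p = np.array([self.type_probs[s] * self.hour_probs[t] for s, t in keys])
        return keys, p

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        tp = pd.DataFrame(
            {"crash_type": [s.value for s in _TYPE_ORDER if s in self.type_probs],
             "probability": [self.type_probs[s] for s in _TYPE_ORDER if s in self.type_probs]}
        )
        hp = pd.DataFrame(sorted(self.hour_probs.items()), columns=["hour", "probability"])
        return tp, hp


def estimate_profile(
    crashes: Sequence[CrashRecord], active_hours: Iterable[int]
) -> CrashProfile:
    """Empirical type and hour marginals from the crash history.

    Crashes whose start hour falls outside ``active_hours`` are dropped
    before estimation; if none remain, raises ValueError.
    """
    active = sorted(set(active_hours))
    kept = [c for c in crashes if c.start_time.hour in active]
    if not kept:
        raise ValueError("no crashes within the active hours; cannot estimate a profile")

    n = len(kept)
    type_probs = {
        s: sum(1 for c in kept if c.crash_type == s) / n for s in _TYPE_ORDER
    }
    hour_counts = {t: 0 for t in active}
    for c in kept:
        hour_counts[c.start_time.hour] += 1
    hour_probs = {t: cnt / n for t, cnt in hour_counts.items()}
    return CrashProfile(type_probs=type_probs, hour_probs=hour_probs)


def sample_crash_events(
    n_expected: float,
    profile: CrashProfile,
    seed: int,
    reps: int = 1,
) -> list[list[tuple[CrashType, int]]]:
    """Draw (type, hour) pairs for an expected crash count, per replicate.

    The expected count is rounded half-up to a whole number of events per
    replicate; each replicate draws independently from the joint. Identical
    (seed, reps, profile) give bit-identical draws.
    """
    if n_expected < 0:
        raise ValueError("expected crash count must be >= 0")
    n_events = int(np.floor(n_expected + 0.5))
    keys, p = profile.cells()
    rng = np.random.default_rng(seed)
    out: list[list[tuple[CrashType, int]]] = []
    for _ in range(reps):
        if n_events == 0:
            out.append([])
            continue
        idx = rng.choice(len(keys), size=n_events, p=p)
        out.append([keys[i] for i in idx])
    return out
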