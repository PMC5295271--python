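"""Non-recurrent congestion delay from a deterministic queuing diagram.

While a crash blocks lanes for a duration t1, the segment discharges at a
reduced capacity Q2 = k * C instead of its full capacity C, while vehicles
keep arriving at the approach flow rate Q1. Vehicles already queued when the
crash starts are

    Q0 = (L / Vbar) * Qbar

(segment length over average speed times average volume). The closed-form
delay used for screening is

    NCD = [ (Q1 - Q2)(C - Q2) t1^2 + 2 Q0 (C - Q2) t1 ] / [ 2 (C - Q1) ]

in vehicle-hours. For Q0 = 0 this is the exact area of the triangle between
the cumulative arrival and departure curves. For Q0 > 0 the closed form is
*not* the exact cumulative-curve area: it ignores the extension of the queue
clearance period needed to discharge the initial queue itself. The closed
form is kept verbatim as the screening formula; :func:`simulate_queue_delay`
provides the exact discrete cumulative-curve construction as an independent
oracle, and the gap between the two quantifies the approximation.

A negative closed-form value (possible when Q2 > Q1 with a small initial
queue) is clamped to zero with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QueueScenario",
    "DelayResult",
    "initial_queue",
    "reduced_capacity",
    "non_recurrent_delay",
    "simulate_queue_delay",
]

logger = logging.getLogger(__name__)

_warned_negative = False


class UnboundedQueueError(ValueError):
    """Approach flow at or above capacity: the queue never dissipates."""


@dataclass(frozen=True)
class QueueScenario:
    """Inputs of one incident-delay computation (flows in veh/h, times in h)."""

    initial_queue: float  # Q0, veh
    approach_flow: float  # Q1, veh/h
    reduced_capacity: float  # Q2, veh/h
    capacity: float  # C, veh/h
    incident_duration: float  # t1, h

    def __post_init__(self) -> None:
        if self.capacity <= 0:
            raise ValueError("capacity must be > 0")
        if not 0 <= self.reduced_capacity <= self.capacity:
            raise ValueError("reduced capacity must satisfy 0 <= Q2 <= C")
        if self.incident_duration < 0:
            raise ValueError("incident duration must be >= 0")
        if self.initial_queue < 0:
            raise ValueError("initial queue must be >= 0")
        if self.approach_flow < 0:
            raise ValueError("approach flow must be >= 0")
        if self.approach_flow >= self.capacity:
            raise UnboundedQueueError(
                f"approach flow Q1={self.approach_flow} >= capacity C={self.capacity}: "
                "the queue grows without bound and the delay is undefined"
            )


@dataclass(frozen=True)
class DelayResult:
    ncd: float  # vehicle-hours
    clearance_time: float  # hours after incident start until the queue clears


def initial_queue(length_km: float, speed: float, volume: float) -> float:
    """Vehicles on the segment when the crash starts: Q0 = (L / Vbar) * Qbar."""
    if speed <= 0:
        raise ValueError("speed must be > 0")
    if length_km < 0 or volume < 0:
        raise ValueError("length and volume must be >= 0")
    return length_km / speed * volume


def reduced_capacity(capacity: float, k: float) -> float:
    """Discharge rate while the crash blocks lanes: Q2 = k * C."""
    if not 0 <= k <= 1:
        raise ValueError(f"capacity-reduction factor k={k} outside [0, 1]")
    return k * capacity


def _clearance_from_geometry(s: QueueScenario) -> float:
    """Time (h after incident start) when the queue, including Q0, reaches zero."""
    r1 = s.approach_flow - s.reduced_capacity  # net rate during incident
    q_end = s.initial_queue + r1 * s.incident_duration
    if q_end <= 0:
        # queue dissolves during the incident (Q2 > Q1 and small Q0)
        if r1 >= 0:
            return 0.0 if s.initial_queue == 0 else s.incident_duration
        return min(s.incident_duration, s.initial_queue / (-r1))
    recovery = s.capacity - s.approach_flow  # > 0 by scenario invariant
    return s.incident_duration + q_end / recovery


def non_recurrent_delay(scenario: QueueScenario) -> DelayResult:
    """Closed-form non-recurrent delay (vehicle-hours) for one incident."""
    s = scenario
    num = (
        (s.approach_flow - s.reduced_capacity)
        * (s.capacity - s.reduced_capacity)
        * s.incident_duration**2
        + 2.0 * s.initial_queue * (s.capacity - s.reduced_capacity) * s.incident_duration
    )
    ncd = num / (2.0 * (s.capacity - s.approach_flow))
    if ncd < 0:
        # routine for off-peak hours where Q2 > Q1; warn once, then debug
        global _warned_negative
        level = logging.DEBUG if _warned_negative else logging.WARNING
        logger.log(
            level,
            "closed-form delay %.3f veh-h is negative (Q2 > Q1 with small Q0); "
            "clamping to 0%s",
            ncd,
            "" if _warned_negative else " (further occurrences logged at DEBUG)",
        )
        _warned_negative = True
        ncd = 0.0
    return DelayResult(ncd=ncd, clearance_time=_clearance_from_geometry(s))


def simulate_queue_delay(scenario: QueueScenario, dt: float = 1.0 / 3600.0) -> DelayResult:
    """Discrete cumulative-curve oracle for the incident delay.

    Builds the cumulative arrival curve (Q0 vehicles present at time zero,
    then the approach flow Q1) and the cumulative departure curve (Q2 during
    the incident, C afterwards, never exceeding arrivals), and integrates the
    queue length over time with a trapezoidal rule on a grid of step ``dt``
    (hours) until the queue returns to zero. This is the exact
    area-between-curves delay, up to discretisation.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    s = scenario
    t_end = _clearance_from_geometry(s)
    if t_end == 0.0:
        return DelayResult(ncd=0.0, clearance_time=0.0)
    n = int(np.ceil(t_end / dt))
    t = np.linspace(0.0, n * dt, n + 1)

    r1 = s.approach_flow - s.reduced_capacity
    # queue during the incident: monotone in one direction, so a clip at zero
    # reproduces the served-when-available departure curve exactly
    q_inc = np.clip(s.initial_queue + r1 * np.minimum(t, s.incident_duration), 0.0, None)
    q_at_t1 = max(0.0, s.initial_queue + r1 * s.incident_duration)
    q_rec = np.clip(q_at_t1 - (s.capacity - s.approach_flow) * (t - s.incident_duration), 0.0, None)
    queue = np.where(t <= s.incident_duration, q_inc, q_rec)
    if scenario.initial_queue > 0 and r1 < 0:
        # queue may hit zero before t1 and stay there
        hit = s.initial_queue / (-r1)
        queue = np.where((t <= s.incident_duration) & (t > hit), 0.0, queue)

    ncd = float(np.trapezoid(queue, t))
    return DelayResult(ncd=ncd, clearance_time=t_end)
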