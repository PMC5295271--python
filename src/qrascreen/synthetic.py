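"""Seeded synthetic expressway networks with realistic crash structure.

Emulates the statistical shape of an urban expressway surveillance dataset:
~167 ramp-to-ramp segments, hourly traffic with morning and evening peaks,
annual crash counts that are negative-binomially dispersed around the crash
prediction model's mean with a year-on-year trend, a heavily two-vehicle
crash-type mixture (12% / 87% / 1%), about 70% of crashes inside the peak
windows, and short lognormal crash durations (median around ten minutes).

The hour-of-day distribution is a two-Gaussian mixture over the active hours
whose mass inside the peak windows is rescaled to equal ``peak_share``
exactly, since only the peak share of the real data is known, not the full
histogram. The generator writes the same CSV schemas the loaders read.

What it does not emulate: within-hour timing structure, spatial correlation
between neighbouring segments, day-of-week effects, or raw loop-detector
noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cpm import CpmCoefficients, predict_crash_frequency
from .data_model import (
    CrashRecord,
    CrashType,
    Segment,
    write_crashes,
    write_segments,
    write_traffic,
)

__all__ = ["GeneratorSpec", "generate_network", "generate_crashes", "generate_dataset"]

_TYPE_ORDER = [CrashType.SINGLE, CrashType.TWO, CrashType.MULTI]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic network and crash history."""

    n_segments: int = 167
    years: int = 3
    start_year: int = 2010
    type_mixture: tuple[float, float, float] = (0.12, 0.87, 0.01)  # single, two, multi
    peak_share: float = 0.70
    peak_windows: tuple[tuple[int, int], ...] = ((7, 10), (16, 19))
    active_hours: tuple[int, ...] = tuple(range(6, 24))
    duration_median_min: float = 10.0
    duration_sigma: float = 0.5  # lognormal shape on the log-minute scale
    trend_pct_per_year: float = 8.0  # annual growth of crash means
    cpm_truth: CpmCoefficients = field(default_factory=CpmCoefficients)
    nb_dispersion: float = 5.0  # NB2 theta: variance = mu + mu^2/theta
    # covariate ranges: LM (m), ADT (pcu/day), CI, MR
    lm_range: tuple[float, float] = (300.0, 2000.0)
    adt_range: tuple[float, float] = (20_000.0, 70_000.0)
    ci_range: tuple[float, float] = (0.05, 0.4)
    mr_range: tuple[float, float] = (0.0, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.type_mixture) - 1.0) > 1e-9:
            raise ValueError("type mixture must sum to 1")
        if not 0 <= self.peak_share <= 1:
            raise ValueError("peak_share must lie in [0, 1]")
        if self.n_segments < 1:
            raise ValueError("need at least one segment")

    def peak_hours(self) -> set[int]:
        hours: set[int] = set()
        for lo, hi in self.peak_windows:
            hours.update(range(lo, hi + 1))
        return hours & set(self.active_hours)


def hour_distribution(spec: GeneratorSpec) -> dict[int, float]:
    """Hour-of-day crash probability over the active hours.

    A mixture of two Gaussian bumps (centred on the morning and evening
    peaks) evaluated at each active hour, then rescaled so the total mass
    inside the peak windows equals ``peak_share`` exactly.
    """
    hours = np.array(sorted(spec.active_hours), dtype=float)
    base = np.exp(-0.5 * ((hours - 8.5) / 2.0) ** 2) + np.exp(
        -0.5 * ((hours - 17.5) / 2.0) ** 2
    )
    base /= base.sum()
    peak = np.array([int(h) in spec.peak_hours() for h in hours])
    mass_in = base[peak].sum()
    if 0 < mass_in < 1 and 0 < spec.peak_share < 1:
        base[peak] *= spec.peak_share / mass_in
        base[~peak] *= (1 - spec.peak_share) / (1 - mass_in)
    base /= base.sum()
    return {int(h): float(p) for h, p in zip(hours, base)}


def _day_shape(rng: np.random.Generator) -> np.ndarray:
    """Bimodal 24-hour volume profile (fraction of daily traffic per hour)."""
    hours = np.arange(24, dtype=float)
    shape = (
        0.15
        + np.exp(-0.5 * ((hours - 8.0) / 1.8) ** 2)
        + 0.9 * np.exp(-0.5 * ((hours - 17.5) / 2.0) ** 2)
    )
    shape[:6] *= 0.25  # overnight maintenance closure: little traffic
    shape *= 1 + 0.05 * rng.standard_normal(24)
    shape = np.clip(shape, 0.01, None)
    return shape / shape.sum()


def generate_network(spec: GeneratorSpec) -> tuple[list[Segment], pd.DataFrame]:
    """Draw segments with CPM covariates and hourly traffic profiles.

    Hourly volume follows a bimodal day shape scaled to the segment's ADT;
    speed is anticorrelated with the volume-to-capacity ratio; the approach
    flow tracks the volume with noise and is always kept strictly below
    capacity so every queuing scenario is well-posed.
    """
    rng = np.random.default_rng(spec.seed)
    segments: list[Segment] = []
    traffic_rows = []
    for sid in range(1, spec.n_segments + 1):
        lm = rng.uniform(*spec.lm_range)
        lanes = int(rng.integers(2, 5))
        capacity = lanes * rng.uniform(1800.0, 2100.0)
        seg = Segment(
            segment_id=sid,
            length_km=lm / 1000.0,
            lane_count=lanes,
            capacity=capacity,
            seg_length_m=lm,
            adt=rng.uniform(*spec.adt_range),
            congestion_index=rng.uniform(*spec.ci_range),
            merging_ratio=rng.uniform(*spec.mr_range),
        )
        segments.append(seg)

        shape = _day_shape(rng)
        # pcu/day -> veh/h, capped below capacity
        volumes = np.minimum(seg.adt * shape, 0.92 * capacity)
        for hour in range(24):
            vol = float(volumes[hour])
            vc = vol / capacity
            speed = float(np.clip(80.0 * (1.0 - 0.65 * vc) + 3.0 * rng.standard_normal(), 15.0, 90.0))
            approach = float(
                np.clip(vol * (1 + 0.05 * rng.standard_normal()), 0.0, 0.95 * capacity)
            )
            traffic_rows.append(
                {
                    "segment_id": sid,
                    "hour": hour,
                    "volume": round(vol, 1),
                    "speed": round(speed, 1),
                    "approach_flow": round(approach, 1),
                }
            )
    return segments, pd.DataFrame(traffic_rows)


def generate_crashes(
    segments: Sequence[Segment], spec: GeneratorSpec
) -> list[CrashRecord]:
    """Draw a multi-year crash history for a network.

    Per segment and year the crash count is NB2 around the CPM-truth mean
    times the year's trend factor; each crash gets an hour from the
    peak-calibrated distribution, a uniform date and within-hour start, a
    type from the mixture, and a lognormal duration.
    """
    rng = np.random.default_rng(spec.seed + 1)
    hour_probs = hour_distribution(spec)
    hours = np.array(sorted(hour_probs))
    hour_p = np.array([hour_probs[h] for h in hours])
    mixture = np.asarray(spec.type_mixture)
    mu_log = np.log(spec.duration_median_min)

    records: list[CrashRecord] = []
    theta = spec.nb_dispersion
    for seg in segments:
        base_mu = predict_crash_frequency(seg, spec.cpm_truth)
        for yr in range(spec.years):
            mu = base_mu * (1 + spec.trend_pct_per_year / 100.0) ** yr
            count = int(rng.negative_binomial(theta, theta / (theta + mu)))
            if count == 0:
                continue
            crash_hours = rng.choice(hours, size=count, p=hour_p)
            days = rng.integers(0, 365, size=count)
            minutes = rng.integers(0, 60, size=count)
            seconds = rng.integers(0, 60, size=count)
            types = rng.choice(len(_TYPE_ORDER), size=count, p=mixture)
            durations_min = np.exp(mu_log + spec.duration_sigma * rng.standard_normal(count))
            year_start = pd.Timestamp(year=spec.start_year + yr, month=1, day=1)
            for i in range(count):
                start = year_start + pd.Timedelta(
                    days=int(days[i]), hours=int(crash_hours[i]),
                    minutes=int(minutes[i]), seconds=int(seconds[i]),
                )
                end = start + pd.Timedelta(seconds=float(durations_min[i]) * 60.0)
                records.append(
                    CrashRecord(seg.segment_id, start, end, _TYPE_ORDER[int(types[i])])
                )
    records.sort(key=lambda r: (r.start_time, r.segment_id))
    return records


def generate_dataset(spec: GeneratorSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate a full dataset and write segments/traffic/crashes CSVs plus
    a truth.json with the ground-truth generator parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    segments, traffic = generate_network(spec)
    crashes = generate_crashes(segments, spec)
    paths = {
        "segments": outdir / "segments.csv",
        "traffic": outdir / "traffic.csv",
        "crashes": outdir / "crashes.csv",
        "truth": outdir / "truth.json",
    }
    write_segments(segments, paths["segments"])
    write_traffic(traffic, paths["traffic"])
    write_crashes(crashes, paths["crashes"])
    truth = asdict(spec)
    truth["cpm_truth"] = spec.cpm_truth.as_dict()
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, default=list)
    return paths
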