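"""Domain types, CSV readers/writers and validation for expressway risk screening.

The study unit is the *segment*: the stretch of mainline expressway between
two adjacent ramps. Each segment carries static roadway attributes (length,
lane count, capacity) and the covariates of the crash prediction model
(segment length in metres, average daily traffic, congestion index, merging
ratio). Time-varying state lives in hourly traffic profiles (volume, speed,
approach flow per hour-of-day), and the crash history is a flat table of
records with start/end timestamps and a three-level type: single-vehicle,
two-vehicle or multi-vehicle collision.

All interchange is plain CSV with mandatory documented headers; timestamps
are timezone-naive ISO-8601 local time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "CrashType",
    "Segment",
    "CrashRecord",
    "StudyConfig",
    "DataLoadError",
    "load_segments",
    "load_traffic",
    "load_crashes",
    "write_segments",
    "write_traffic",
    "write_crashes",
    "crash_duration",
]

SEGMENT_COLUMNS = [
    "segment_id", "length_km", "lane_count", "capacity",
    "seg_length_m", "adt", "congestion_index", "merging_ratio",
]
TRAFFIC_COLUMNS = ["segment_id", "hour", "volume", "speed", "approach_flow"]
CRASH_COLUMNS = ["segment_id", "start_time", "end_time", "crash_type"]


class DataLoadError(ValueError):
    """Raised when a CSV row violates the schema; names the offending row."""


class CrashType(str, enum.Enum):
    """Crash classification by the number of vehicles involved."""

    SINGLE = "single"
    TWO = "two"
    MULTI = "multi"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class Segment:
    """A mainline expressway segment between two adjacent ramps."""

    segment_id: int
    length_km: float
    lane_count: int
    capacity: float  # veh/h
    seg_length_m: float  # CPM exposure covariate (m)
    adt: float  # average daily traffic (pcu/day)
    congestion_index: float
    merging_ratio: float

    def __post_init__(self) -> None:
        if self.length_km <= 0:
            raise ValueError(f"segment {self.segment_id}: length_km must be > 0")
        if self.capacity <= 0:
            raise ValueError(f"segment {self.segment_id}: capacity must be > 0")
        if self.lane_count < 1:
            raise ValueError(f"segment {self.segment_id}: lane_count must be >= 1")
        if self.adt <= 0:
            raise ValueError(f"segment {self.segment_id}: adt must be > 0")
        if self.congestion_index < 0 or self.merging_ratio < 0:
            raise ValueError(
                f"segment {self.segment_id}: congestion_index and merging_ratio must be >= 0"
            )
        # length appears twice (km for queuing, m for the CPM); they must agree
        if abs(self.seg_length_m - self.length_km * 1000.0) > 1.0:
            raise ValueError(
                f"segment {self.segment_id}: seg_length_m={self.seg_length_m} "
                f"inconsistent with length_km={self.length_km}"
            )


@dataclass(frozen=True)
class CrashRecord:
    """One crash: where, when it started and ended, and its type."""

    segment_id: int
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    crash_type: CrashType

    def __post_init__(self) -> None:
        if self.end_time < self.start_time:
            raise ValueError(
                f"crash on segment {self.segment_id}: end_time {self.end_time} "
                f"precedes start_time {self.start_time}"
            )


class StudyConfig(BaseModel):
    """Study-level parameters: trend, active hours, economics, sampling.

    ``trend_pct_per_year`` is the signed annual trend percentage entering the
    EB trend multiplier ``1 - ny * (trend/100)``; positive means an assumed
    annual *reduction* under that formula's literal sign convention.
    """

    trend_pct_per_year: float = 8.0
    study_years: int = Field(default=3, ge=1)
    active_hours: list[int] = Field(default_factory=lambda: list(range(6, 24)))
    peak_windows: list[tuple[int, int]] = Field(
        default_factory=lambda: [(7, 10), (16, 19)]
    )
    # fraction of capacity remaining while a crash of each type blocks lanes
    capacity_reduction: dict[CrashType, float] = Field(
        default_factory=lambda: {
            CrashType.SINGLE: 0.58,
            CrashType.TWO: 0.45,
            CrashType.MULTI: 0.32,
        }
    )
    # direct monetary loss per crash of each type (yuan)
    direct_loss: dict[CrashType, float] = Field(
        default_factory=lambda: {
            CrashType.SINGLE: 2000.0,
            CrashType.TWO: 4000.0,
            CrashType.MULTI: 6000.0,
        }
    )
    income_per_year: float = Field(default=80_000.0, gt=0)  # yuan
    work_days_per_year: float = Field(default=250.0, gt=0)
    work_hours_per_day: float = Field(default=8.0, gt=0)
    mc_reps: int = Field(default=10, ge=1)
    seed: int = 0

    @field_validator("active_hours")
    @classmethod
    def _check_hours(cls, v: list[int]) -> list[int]:
        if not v:
            raise ValueError("active_hours must be non-empty")
        if any(h < 0 or h > 23 for h in v):
            raise ValueError("active_hours must lie in 0..23")
        return sorted(set(v))

    @field_validator("capacity_reduction")
    @classmethod
    def _check_k(cls, v: dict[CrashType, float]) -> dict[CrashType, float]:
        for t, k in v.items():
            if not 0 < k <= 1:
                raise ValueError(f"capacity_reduction[{t}]={k} outside (0, 1]")
        return v

    @field_validator("direct_loss")
    @classmethod
    def _check_dl(cls, v: dict[CrashType, float]) -> dict[CrashType, float]:
        for t, dl in v.items():
            if dl < 0:
                raise ValueError(f"direct_loss[{t}]={dl} must be >= 0")
        return v

    @model_validator(mode="after")
    def _check_trend(self) -> "StudyConfig":
        if 1 - self.study_years * self.trend_pct_per_year / 100.0 <= 0:
            raise ValueError(
                "trend multiplier 1 - ny*(alpha/100) is nonpositive; "
                "shorten the study period or revisit the trend percentage"
            )
        return self

    @property
    def value_of_time(self) -> float:
        """Yuan per vehicle-hour of delay: annual income / annual work hours."""
        return self.income_per_year / (self.work_days_per_year * self.work_hours_per_day)

    def peak_hours(self) -> set[int]:
        hours: set[int] = set()
        for lo, hi in self.peak_windows:
            hours.update(range(lo, hi + 1))
        return hours

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)

    def to_yaml(self, path: str | Path) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path: str | Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataLoadError(f"{path}: missing required columns {missing}")


def load_segments(path: str | Path) -> list[Segment]:
    """Read segments.csv into validated :class:`Segment` objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SEGMENT_COLUMNS, path)
    segments = []
    for idx, row in df.iterrows():
        try:
            segments.append(
                Segment(
                    segment_id=int(row["segment_id"]),
                    length_km=float(row["length_km"]),
                    lane_count=int(row["lane_count"]),
                    capacity=float(row["capacity"]),
                    seg_length_m=float(row["seg_length_m"]),
                    adt=float(row["adt"]),
                    congestion_index=float(row["congestion_index"]),
                    merging_ratio=float(row["merging_ratio"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise DataLoadError(f"{path} row {idx}: {exc}") from exc
    ids = [s.segment_id for s in segments]
    if len(set(ids)) != len(ids):
        raise DataLoadError(f"{path}: duplicate segment_id values")
    return segments


def load_traffic(path: str | Path) -> pd.DataFrame:
    """Read traffic.csv: one row per (segment, hour) with volume/speed/approach flow."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRAFFIC_COLUMNS, path)
    bad = df[(df["speed"] <= 0) | (df["volume"] < 0) | (df["approach_flow"] < 0)]
    if not bad.empty:
        raise DataLoadError(
            f"{path}: rows {bad.index.tolist()[:10]} violate speed>0, volume>=0, approach_flow>=0"
        )
    if df.duplicated(["segment_id", "hour"]).any():
        dup = df[df.duplicated(["segment_id", "hour"])].index.tolist()[:10]
        raise DataLoadError(f"{path}: duplicate (segment_id, hour) rows {dup}")
    if ((df["hour"] < 0) | (df["hour"] > 23)).any():
        raise DataLoadError(f"{path}: hour values outside 0..23")
    return df.astype({"segment_id": int, "hour": int}).reset_index(drop=True)


def load_crashes(
    path: str | Path, known_segments: Iterable[int] | None = None
) -> list[CrashRecord]:
    """Read crashes.csv into validated :class:`CrashRecord` objects.

    If ``known_segments`` is given, a crash referencing an unknown segment is
    rejected with a row-level diagnostic.
    """
    df = pd.read_csv(path)
    _require_columns(df, CRASH_COLUMNS, path)
    known = set(known_segments) if known_segments is not None else None
    records = []
    for idx, row in df.iterrows():
        try:
            ctype = CrashType(str(row["crash_type"]))
        except ValueError as exc:
            raise DataLoadError(
                f"{path} row {idx}: unknown crash_type {row['crash_type']!r} "
                f"(expected one of {[t.value for t in CrashType]})"
            ) from exc
        try:
            start = pd.Timestamp(row["start_time"])
            end = pd.Timestamp(row["end_time"])
        except (ValueError, TypeError) as exc:
            raise DataLoadError(f"{path} row {idx}: unparseable timestamp: {exc}") from exc
        sid = int(row["segment_id"])
        if known is not None and sid not in known:
            raise DataLoadError(f"{path} row {idx}: unknown segment_id {sid}")
        try:
            records.append(CrashRecord(sid, start, end, ctype))
        except ValueError as exc:
            raise DataLoadError(f"{path} row {idx}: {exc}") from exc
    return records


def write_segments(segments: Sequence[Segment], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "segment_id": s.segment_id,
                "length_km": s.length_km,
                "lane_count": s.lane_count,
                "capacity": s.capacity,
                "seg_length_m": s.seg_length_m,
                "adt": s.adt,
                "congestion_index": s.congestion_index,
                "merging_ratio": s.merging_ratio,
            }
            for s in segments
        ],
        columns=SEGMENT_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")


def write_traffic(traffic: pd.DataFrame, path: str | Path) -> None:
    traffic[TRAFFIC_COLUMNS].to_csv(path, index=False)


def write_crashes(crashes: Sequence[CrashRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "segment_id": c.segment_id,
                "start_time": c.start_time.isoformat(),
                "end_time": c.end_time.isoformat(),
                "crash_type": c.crash_type.value,
            }
            for c in crashes
        ],
        columns=CRASH_COLUMNS,
    ).to_csv(path, index=False)


def crash_duration(record: CrashRecord, rounding: str = "nearest_minute") -> float:
    """Crash duration in hours.

    ``rounding="nearest_minute"`` (the default) rounds the raw duration to a
    whole number of minutes before converting to hours, matching how incident
    logs report treatment times; ``rounding="none"`` keeps raw seconds.
    """
    seconds = (record.end_time - record.start_time).total_seconds()
    if rounding == "nearest_minute":
        minutes = round(seconds / 60.0)
        return minutes / 60.0
    if rounding == "none":
        return seconds / 3600.0
    raise ValueError(f"unknown rounding mode {rounding!r}")
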