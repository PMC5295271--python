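"""Shared fixtures: small and full-size synthetic networks, crash profiles."""

from __future__ import annotations

import pandas as pd
import pytest

import qrascreen as q


@pytest.fixture(scope="session")
def small_spec() -> q.GeneratorSpec:
    return q.GeneratorSpec(n_segments=12, years=3, seed=11)


@pytest.fixture(scope="session")
def small_network(small_spec):
    segments, traffic = q.generate_network(small_spec)
    crashes = q.generate_crashes(segments, small_spec)
    return segments, traffic, crashes


@pytest.fixture(scope="session")
def default_dataset():
    """The full default network (167 segments, 3 years); generated once."""
    spec = q.GeneratorSpec(seed=42)
    segments, traffic = q.generate_network(spec)
    crashes = q.generate_crashes(segments, spec)
    return spec, segments, traffic, crashes


@pytest.fixture(scope="session")
def shanghai_type_probs() -> dict[q.CrashType, float]:
    """Observed crash-type mixture on the studied network: 12/87/1."""
    return {
        q.CrashType.SINGLE: 0.12,
        q.CrashType.TWO: 0.87,
        q.CrashType.MULTI: 0.01,
    }


@pytest.fixture()
def uniform_profile(shanghai_type_probs) -> q.CrashProfile:
    hours = range(6, 24)
    return q.CrashProfile(
        type_probs=shanghai_type_probs,
        hour_probs={h: 1 / 18 for h in hours},
    )


def make_crash(segment_id=1, start="2011-03-01 08:15:00", minutes=10.0,
               ctype=q.CrashType.TWO) -> q.CrashRecord:
    t0 = pd.Timestamp(start)
    return q.CrashRecord(segment_id, t0, t0 + pd.Timedelta(minutes=minutes), ctype)
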