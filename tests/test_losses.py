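"""Monetized losses, expected loss per crash, risk scores and rankings."""

import numpy as np
import pandas as pd
import pytest

import qrascreen as q
from conftest import make_crash


@pytest.fixture()
def two_segment_fixture():
    """A high-frequency/high-capacity segment A versus a two-lane segment B
    whose approach flow runs close to its low capacity, so each crash on B
    causes far more queuing delay."""
    seg_a = q.Segment(1, 1.5, 4, 8000.0, 1500.0, 60_000, 0.3, 0.1)
    seg_b = q.Segment(2, 1.5, 2, 3600.0, 1500.0, 60_000, 0.3, 0.1)
    rows = []
    for hour in (8, 18):
        rows.append({"segment_id": 1, "hour": hour, "volume": 4000.0,
                     "speed": 70.0, "approach_flow": 4000.0})
        rows.append({"segment_id": 2, "hour": hour, "volume": 3200.0,
                     "speed": 30.0, "approach_flow": 3200.0})
    traffic = pd.DataFrame(rows)
    profile = q.CrashProfile(type_probs={q.CrashType.TWO: 1.0},
                             hour_probs={8: 0.5, 18: 0.5})
    crashes = [make_crash(segment_id=sid, minutes=10.0) for sid in (1, 2)]
    eb = pd.DataFrame(
        {"segment_id": [1, 2], "predicted": [280.0, 140.0],
         "observed_mean": [310.0, 160.0], "weight": [0.5, 0.5],
         "expected": [300.0, 150.0]}
    )
    return [seg_a, seg_b], traffic, crashes, profile, eb


class TestMonetizeDelay:
    def test_value_of_time_conversion(self):
        # 80,000 yuan/yr over 250 d x 8 h = 40 yuan per vehicle-hour
        assert q.monetize_delay(100.0, 80_000, 250, 8) == pytest.approx(4000.0)

    def test_zero_delay_costs_nothing(self):
        assert q.monetize_delay(0.0, 80_000, 250, 8) == 0.0

    def test_linear_in_income(self):
        assert q.monetize_delay(10, 160_000, 250, 8) == pytest.approx(
            2 * q.monetize_delay(10, 80_000, 250, 8)
        )

    def test_nonpositive_work_time_rejected(self):
        with pytest.raises(ValueError):
            q.monetize_delay(1.0, 80_000, 0, 8)


class TestDirectLoss:
    def test_default_table_by_type(self):
        table = q.StudyConfig().direct_loss
        assert q.direct_loss(q.CrashType.SINGLE, table) == 2000.0
        assert q.direct_loss(q.CrashType.TWO, table) == 4000.0
        assert q.direct_loss(q.CrashType.MULTI, table) == 6000.0

    def test_custom_table_overrides(self):
        assert q.direct_loss(q.CrashType.TWO, {q.CrashType.TWO: 9000.0}) == 9000.0

    def test_unknown_type_rejected(self):
        with pytest.raises(KeyError):
            q.direct_loss(q.CrashType.MULTI, {q.CrashType.TWO: 1.0})


class TestMeanDurations:
    def test_per_type_means_with_global_fallback(self):
        crashes = [
            make_crash(ctype=q.CrashType.TWO, minutes=10),
            make_crash(ctype=q.CrashType.TWO, minutes=20),
            make_crash(ctype=q.CrashType.SINGLE, minutes=6),
        ]
        d = q.mean_durations(crashes)
        assert d[q.CrashType.TWO] == pytest.approx(15 / 60)
        assert d[q.CrashType.SINGLE] == pytest.approx(6 / 60)
        assert d[q.CrashType.MULTI] == pytest.approx(12 / 60)  # global mean


class TestExpectedLossPerCrash:
    def test_degenerate_profile_equals_single_cell(self, two_segment_fixture):
        segments, traffic, crashes, _, _ = two_segment_fixture
        profile = q.CrashProfile(type_probs={q.CrashType.TWO: 1.0},
                                 hour_probs={8: 1.0})
        cfg = q.StudyConfig()
        durations = {t: 1 / 6 for t in q.CrashType}
        loss = q.expected_loss_per_crash(segments[0], profile, traffic, cfg, durations)
        # reproduce the single cell by hand
        q0 = q.initial_queue(1.5, 70.0, 4000.0)
        sc = q.QueueScenario(q0, 4000.0, q.reduced_capacity(8000, 0.45), 8000.0, 1 / 6)
        expected = (q.monetize_delay(q.non_recurrent_delay(sc).ncd, 80_000, 250, 8)
                    + 4000.0)
        assert loss == pytest.approx(expected)

    def test_uniform_two_cell_profile_averages(self, two_segment_fixture):
        segments, traffic, crashes, profile, _ = two_segment_fixture
        cfg = q.StudyConfig()
        durations = {t: 1 / 6 for t in q.CrashType}
        loss = q.expected_loss_per_crash(segments[0], profile, traffic, cfg, durations)
        cells = [
            q.expected_loss_per_crash(
                segments[0],
                q.CrashProfile(type_probs={q.CrashType.TWO: 1.0}, hour_probs={h: 1.0}),
                traffic, cfg, durations)
            for h in (8, 18)
        ]
        assert loss == pytest.approx(np.mean(cells))

    def test_missing_traffic_hour_reported(self, two_segment_fixture):
        segments, traffic, crashes, _, _ = two_segment_fixture
        profile = q.CrashProfile(type_probs={q.CrashType.TWO: 1.0},
                                 hour_probs={8: 0.5, 12: 0.5})
        with pytest.raises(ValueError, match="12"):
            q.expected_loss_per_crash(segments[0], profile, traffic,
                                      q.StudyConfig(), {t: 0.1 for t in q.CrashType})

    def test_monte_carlo_close_to_exact(self, two_segment_fixture, shanghai_type_probs):
        segments, traffic, crashes, _, _ = two_segment_fixture
        profile = q.CrashProfile(type_probs=shanghai_type_probs,
                                 hour_probs={8: 0.6, 18: 0.4})
        cfg = q.StudyConfig(mc_reps=10, seed=77)
        durations = {t: 1 / 6 for t in q.CrashType}
        exact = q.expected_loss_per_crash(segments[1], profile, traffic, cfg, durations)
        mc = q.expected_loss_per_crash(segments[1], profile, traffic, cfg, durations,
                                       mode="monte_carlo", n_draws=10_000)
        assert mc == pytest.approx(exact, rel=0.02)

    def test_monte_carlo_unbiased_over_replications(self, two_segment_fixture,
                                                    shanghai_type_probs):
        segments, traffic, crashes, _, _ = two_segment_fixture
        profile = q.CrashProfile(type_probs=shanghai_type_probs,
                                 hour_probs={8: 0.6, 18: 0.4})
        durations = {t: 1 / 6 for t in q.CrashType}
        cfg = q.StudyConfig(mc_reps=1)
        exact = q.expected_loss_per_crash(segments[1], profile, traffic, cfg, durations)
        estimates = [
            q.expected_loss_per_crash(segments[1], profile, traffic, cfg, durations,
                                      mode="monte_carlo", n_draws=2000, seed=1000 + r)
            for r in range(50)
        ]
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - exact) < 3 * se


class TestRiskScore:
    def test_product_form(self):
        assert q.risk_score(10, 5000) == 50_000.0
        assert q.risk_score(0, 5000) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            q.risk_score(-1, 100)


class TestRankHotspots:
    def test_descending_order_and_top_n(self):
        scores = pd.DataFrame({"segment_id": [1, 2, 3], "score": [3.0, 1.0, 2.0]})
        out = q.rank_hotspots(scores, top_n=2)
        assert list(out["segment_id"]) == [1, 3]
        assert list(out["rank"]) == [1, 2]

    def test_ties_break_by_segment_id(self):
        scores = pd.DataFrame({"segment_id": [5, 2, 9], "score": [1.0, 1.0, 1.0]})
        out = q.rank_hotspots(scores)
        assert list(out["segment_id"]) == [2, 5, 9]

    def test_top_n_larger_than_network_returns_all(self):
        scores = pd.DataFrame({"segment_id": [1, 2], "score": [2.0, 1.0]})
        assert len(q.rank_hotspots(scores, top_n=10)) == 2


class TestRiskScreen:
    def test_risk_equals_frequency_times_loss(self, two_segment_fixture):
        segments, traffic, crashes, profile, eb = two_segment_fixture
        table = q.risk_screen(segments, traffic, crashes, eb, profile,
                              q.StudyConfig())
        assert np.allclose(table["risk"],
                           table["expected_crashes"] * table["expected_loss_per_crash"],
                           rtol=1e-6)
        assert np.allclose(table["risk"], table["direct"] + table["indirect"])

    def test_direct_component_independent_of_traffic(self, two_segment_fixture):
        segments, traffic, crashes, profile, eb = two_segment_fixture
        table = q.risk_screen(segments, traffic, crashes, eb, profile,
                              q.StudyConfig())
        exp_dl = sum(profile.type_probs[s] * q.StudyConfig().direct_loss[s]
                     for s in profile.type_probs)
        assert np.allclose(table["direct"], table["expected_crashes"] * exp_dl)

    def test_low_capacity_segment_ranks_higher_under_qra_than_eb(
            self, two_segment_fixture):
        """The frequency-only ranking puts the busy segment first; pricing in
        the per-crash congestion delay promotes the two-lane bottleneck."""
        segments, traffic, crashes, profile, eb = two_segment_fixture
        table = q.risk_screen(segments, traffic, crashes, eb, profile,
                              q.StudyConfig()).set_index("segment_id")
        assert table.loc[2, "rank_eb"] == 2  # fewer expected crashes
        assert table.loc[2, "rank_qra"] == 1  # but larger total risk
        assert table.loc[2, "rank_qra"] < table.loc[2, "rank_eb"]

    def test_eb_ranking_invariant_to_economics_qra_scales_uniformly(
            self, two_segment_fixture):
        segments, traffic, crashes, profile, eb = two_segment_fixture
        cfg1 = q.StudyConfig()
        cfg2 = q.StudyConfig(
            income_per_year=cfg1.income_per_year * 3,
            direct_loss={t: 3 * v for t, v in cfg1.direct_loss.items()},
        )
        t1 = q.risk_screen(segments, traffic, crashes, eb, profile, cfg1)
        t2 = q.risk_screen(segments, traffic, crashes, eb, profile, cfg2)
        assert list(t1["rank_eb"]) == list(t2["rank_eb"])
        assert list(t1["rank_qra"]) == list(t2["rank_qra"])
        assert np.allclose(t2["risk"], 3 * t1["risk"], rtol=1e-9)
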