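import math

import numpy as np
import pandas as pd
import pytest

from hystnet import actr
from hystnet.actr import (
    ActrParams,
    BehavioralRecord,
    Chunk,
    RetrievalFailure,
    activation,
    base_level,
    retrieval_probability,
    retrieval_time,
    run_session,
    summarize_bins,
)
from hystnet.matb import EventSchedule, make_lhl_schedule


class TestBaseLevel:
    def test_single_presentation_age_one(self):
        assert base_level(Chunk("c", [0.0]), 1.0, d=0.7) == pytest.approx(0.0)

    def test_two_presentations_printed_formula(self):
        # ages 1 and 4 s with d = 0.5: ln(1^-0.5 + 4^-0.5) = ln(1.5)
        c = Chunk("c", [0.0, 3.0])
        assert base_level(c, 4.0, d=0.5) == pytest.approx(math.log(1.5), abs=1e-6)

    def test_strictly_decreasing_between_presentations(self):
        c = Chunk("c", [0.0, 1.0])
        values = [base_level(c, t, 0.5) for t in np.linspace(1.5, 50.0, 40)]
        assert np.all(np.diff(values) < 0)

    def test_empty_history_signals_retrieval_failure(self):
        with pytest.raises(RetrievalFailure):
            base_level(Chunk("c", []), 1.0)

    def test_query_before_last_presentation_rejected(self):
        with pytest.raises(ValueError):
            base_level(Chunk("c", [0.0, 5.0]), 5.0)

    def test_permanent_base_offset(self):
        c = Chunk("c", [0.0], permanent_base=2.0)
        assert base_level(c, 1.0, 0.5) == pytest.approx(2.0)


class TestActivation:
    def test_equals_base_level_without_noise_or_context(self):
        c = Chunk("c", [0.0, 3.0])
        p = ActrParams(epsilon_sd=0.0)
        assert activation(c, 4.0, p) == pytest.approx(base_level(c, 4.0, p.d))

    def test_associative_term_is_linear(self):
        c = Chunk("c", [0.0])
        p = ActrParams(epsilon_sd=0.0, Sji={"cue": 0.5})
        a = activation(c, 1.0, p, context={"cue": 1.0})
        assert a == pytest.approx(0.5)

    def test_noise_calibration(self):
        c = Chunk("c", [0.0])
        p = ActrParams(epsilon_sd=0.1)
        rng = np.random.default_rng(0)
        draws = np.array([activation(c, 1.0, p, rng=rng) for _ in range(10_000)])
        assert np.std(draws) == pytest.approx(0.1, rel=0.05)


class TestRetrievalEquations:
    def test_probability_half_at_threshold(self):
        assert retrieval_probability(-2.0, tau=-2.0, s=0.4) == pytest.approx(0.5)

    def test_probability_one_noise_unit_above(self):
        p = retrieval_probability(-1.6, tau=-2.0, s=0.4)
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-9)

    def test_probability_limits_and_monotonicity(self):
        assert retrieval_probability(50.0, 0.0, 1.0) > 0.999999
        grid = np.linspace(-5, 5, 30)
        ps = [retrieval_probability(a, 0.0, 0.5) for a in grid]
        assert np.all(np.diff(ps) > 0)

    def test_probability_invalid_noise(self):
        with pytest.raises(ValueError):
            retrieval_probability(0.0, 0.0, 0.0)

    def test_latency_at_zero_activation_is_f(self):
        assert retrieval_time(0.0, F=0.73) == pytest.approx(0.73)

    def test_latency_printed_example(self):
        assert retrieval_time(math.log(2.0), F=1.0) == pytest.approx(0.5)

    def test_latency_decreasing_in_activation(self):
        assert retrieval_time(-1.0, 1.0) > retrieval_time(0.5, 1.0)


def _empty_schedule(duration=60.0):
    df = pd.DataFrame(columns=["time_s", "subtask", "event_type", "condition"])
    return EventSchedule(df, duration_s=duration)


class TestRunSession:
    def test_empty_schedule_baseline(self):
        p = ActrParams(seed=0)
        rec = run_session(_empty_schedule(120.0), p)
        assert len(rec.responses) == 0
        rms = float(np.sqrt(np.mean(rec.tracking_error**2)))
        baseline = p.track_sigma / math.sqrt(2 * p.track_gain)
        assert rms == pytest.approx(baseline, rel=0.25)

    def test_production_cycle_grid_is_50_ms(self):
        rec = run_session(make_lhl_schedule(0.5, seed=1), ActrParams(seed=1))
        steps = np.diff(rec.tick_times)
        assert np.allclose(steps, 0.050, atol=1e-12)
        # every evaluation timestamp is a multiple of 50 ms
        assert np.allclose(
            np.round(rec.tick_times / 0.050) * 0.050, rec.tick_times, atol=1e-9
        )

    def test_rt_decomposition_lower_bound(self):
        p = ActrParams(seed=2)
        rec = run_session(make_lhl_schedule(2.0, seed=2), p)
        floor = (p.visual_ms + p.motor_ms) / 1000.0
        assert (rec.responses["response_time_s"] >= floor - 1e-9).all()

    def test_declarative_retrievals_never_overlap(self):
        rec = run_session(make_lhl_schedule(2.0, seed=3), ActrParams(seed=3))
        iv = sorted(rec.retrieval_intervals)
        for (s0, e0), (s1, e1) in zip(iv, iv[1:]):
            assert s1 >= e0 - 1e-9

    def test_hysteresis_direction_with_carryover(self):
        # noise off isolates the practice mechanism
        deltas = []
        for seed in range(6):
            sched = make_lhl_schedule(3.0, seed=seed)
            p = ActrParams(seed=seed, epsilon_sd=0.0)
            rec = run_session(sched, p, carryover=True)
            by = rec.responses.groupby("condition")["response_time_s"].mean()
            deltas.append(by["L3"] - by["L1"])
        assert all(d < 0 for d in deltas)

    def test_no_hysteresis_without_carryover(self):
        deltas, sds = [], []
        for seed in range(10):
            sched = make_lhl_schedule(3.0, seed=seed)
            p = ActrParams(seed=seed)
            rec = run_session(sched, p, carryover=False)
            grp = rec.responses.groupby("condition")["response_time_s"]
            by, sd = grp.mean(), grp.std()
            deltas.append(by["L3"] - by["L1"])
            sds.append(0.5 * (sd["L1"] + sd["L3"]))
        assert abs(np.mean(deltas)) < 0.5 * np.mean(sds)

    def test_high_demand_slower_than_first_low_block(self):
        l1, h2 = [], []
        for seed in range(6):
            rec = run_session(
                make_lhl_schedule(3.0, seed=seed), ActrParams(seed=seed), carryover=True
            )
            by = rec.responses.groupby("condition")["response_time_s"].mean()
            l1.append(by["L1"])
            h2.append(by["H2"])
        assert np.mean(h2) >= np.mean(l1)


class TestSummarizeBins:
    def test_twelve_minute_record_has_six_labeled_bins(self):
        rec = run_session(make_lhl_schedule(4.0, seed=4), ActrParams(seed=4))
        bins = summarize_bins(rec, bin_minutes=2.0)
        assert list(bins["bin"]) == ["0–2", "2–4", "4–6", "6–8", "8–10", "10–12"]
        assert list(bins["condition"]) == ["L1", "L1", "H2", "H2", "L3", "L3"]

    def test_constant_tracking_error_gives_rms_equal_to_it(self):
        ticks = np.arange(0, 240.0, 0.05)
        rec = BehavioralRecord(
            responses=pd.DataFrame(
                columns=[
                    "event_time",
                    "response_time_s",
                    "correct",
                    "subtask",
                    "event_type",
                    "condition",
                ]
            ),
            tracking_error=np.full(len(ticks), 7.5),
            tick_times=ticks,
            duration_s=240.0,
            misses=0,
            retrieval_intervals=[],
        )
        bins = summarize_bins(rec)
        assert np.allclose(bins["tracking_rms"], 7.5)
        assert bins["no_correct_responses"].all()

    def test_bin_means_match_hand_computation(self):
        resp = pd.DataFrame(
            {
                "event_time": [10.0, 50.0, 130.0],
                "response_time_s": [1.0, 2.0, 4.0],
                "correct": [True, True, True],
                "subtask": ["system_monitoring"] * 3,
                "event_type": ["light"] * 3,
                "condition": ["L1"] * 3,
            }
        )
        ticks = np.arange(0, 240.0, 0.05)
        rec = BehavioralRecord(
            responses=resp,
            tracking_error=np.zeros(len(ticks)),
            tick_times=ticks,
            duration_s=240.0,
            misses=0,
            retrieval_intervals=[],
        )
        bins = summarize_bins(rec)
        assert bins["correct_rt_mean_s"][0] == pytest.approx(1.5)
        assert bins["correct_rt_mean_s"][1] == pytest.approx(4.0)

    def test_zero_duration_rejected(self):
        rec = run_session(_empty_schedule(60.0), ActrParams(seed=0))
        rec.duration_s = 0.0
        with pytest.raises(ValueError):
            summarize_bins(rec)
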