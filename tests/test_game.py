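"""Target bands, set state machine, scoring, levels, closed-loop sessions."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nirsbf import (RunConfig, SetState, band_for_level, finish_set,
                    make_subject, run_session, score_set, step_set,
                    user_level)


class TestBandForLevel:
    def test_level_one_uses_base_width(self):
        b = band_for_level(1, "CBF", 0.0, base_width=0.5)
        assert b.width == pytest.approx(0.5)

    def test_level_two_narrows_by_decay(self):
        b = band_for_level(2, "CBF", 0.0, base_width=0.5)
        assert b.width == pytest.approx(0.45)

    def test_width_floors_at_high_level(self):
        b = band_for_level(100, "CBF", 0.0, base_width=0.5)
        assert b.width == pytest.approx(0.15)  # 0.3 x base

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            band_for_level(0, "CBF", 0.0)

    def test_decrease_direction_places_band_below_baseline(self):
        b = band_for_level(1, "CBF", 1.0, direction="decrease", offset=0.6)
        assert b.center == pytest.approx(0.4)

    @given(level=st.integers(1, 50))
    def test_width_never_increases_with_level(self, level):
        w1 = band_for_level(level, "CBF", 0.0).width
        w2 = band_for_level(level + 1, "CBF", 0.0).width
        assert w2 <= w1 + 1e-12


def _run_cue_sequence(cues, fs=10.0):
    band = band_for_level(1, "CBF", 0.0, base_width=1.0, offset=0.0)
    state = SetState(fs=fs)
    for k, cue in enumerate(cues):
        step_set(state, k / fs, cue, band)
        if state.achieved:
            break
    return state


class TestStepSet:
    def test_continuous_in_band_achieves_at_15s(self):
        state = _run_cue_sequence([0.0] * 1200)
        assert state.achieved
        assert state.achieved_at_s == pytest.approx(15.0)

    def test_advice_shown_when_band_never_reached_by_10s(self):
        state = _run_cue_sequence([5.0] * 101)
        assert state.advice_shown
        assert not state.achieved

    def test_early_band_entry_suppresses_advice(self):
        cues = [0.0] * 50 + [5.0] * 100  # enters band immediately
        state = _run_cue_sequence(cues)
        assert not state.advice_shown

    def test_single_dropout_resets_continuous_timer(self):
        cues = [0.0] * 140 + [5.0] + [0.0] * 140
        state = _run_cue_sequence(cues)
        assert not state.achieved
        assert state.in_band_total_s == pytest.approx(28.0)
        assert state.in_band_continuous_s == pytest.approx(14.0)

    def test_stepping_finished_set_rejected(self):
        state = _run_cue_sequence([0.0] * 1200)
        with pytest.raises(RuntimeError, match="finished"):
            step_set(state, 15.0, 0.0,
                     band_for_level(1, "CBF", 0.0, offset=0.0))

    def test_timers_never_exceed_elapsed(self):
        rng = np.random.default_rng(0)
        cues = rng.normal(0.0, 1.0, 1200)
        band = band_for_level(1, "CBF", 0.0, base_width=1.0, offset=0.0)
        state = SetState(fs=10.0)
        for k, cue in enumerate(cues):
            if state.achieved:
                break
            step_set(state, k / 10.0, float(cue), band)
            assert (state.in_band_continuous_s <= state.in_band_total_s
                    <= state.elapsed_s <= 120.0)


class TestScoreSet:
    def test_instant_success_scores_exactly_100(self):
        assert score_set(True, 105.0, 15.0) == pytest.approx(100.0)

    def test_last_moment_success(self):
        assert score_set(True, 0.0, 15.0) == pytest.approx(12.5)

    def test_failure_with_sixty_seconds_in_band(self):
        assert score_set(False, 0.0, 60.0) == pytest.approx(25.0)

    def test_failure_with_nothing_in_band(self):
        assert score_set(False, 0.0, 0.0) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            score_set(False, 0.0, -1.0)

    @given(maintain=st.floats(0.0, 119.9))
    def test_failure_scores_stay_below_50(self, maintain):
        assert score_set(False, 0.0, maintain) < 50.0

    @given(remaining=st.floats(0.0, 105.0), maintain=st.floats(15.0, 120.0))
    def test_scores_always_within_bounds(self, remaining, maintain):
        assert 0.0 <= score_set(True, remaining, maintain) <= 100.0


class TestUserLevel:
    def test_hundred_sets_averaging_five_is_level_one(self):
        assert user_level([5.0] * 100) == 1

    def test_fewer_than_hundred_sets_counts_as_zero(self):
        assert user_level([100.0] * 50) == 1

    def test_hundred_sets_averaging_95_caps_decade_mapping(self):
        assert user_level([95.0] * 100) == 10

    def test_level_caps_at_ten(self):
        assert user_level([100.0] * 100) == 10

    def test_only_last_window_counts(self):
        assert user_level([0.0] * 100 + [55.0] * 100) == 6

    @given(st.lists(st.floats(0.0, 100.0), min_size=100, max_size=100),
           st.floats(0.1, 5.0))
    def test_level_monotone_in_average(self, scores, bump):
        bumped = [min(100.0, s + bump) for s in scores]
        assert user_level(bumped) >= user_level(scores)


class TestRunSession:
    def test_session_has_ten_sets(self):
        subj = make_subject({}, seed=7)
        log = run_session(subj, RunConfig(), seed=7)
        assert len(log.set_results) == 10

    def test_unskilled_subject_fails_every_set(self):
        subj = make_subject({"control_skill": 0.0}, seed=7)
        log = run_session(subj, RunConfig(), seed=7)
        assert not any(r.achieved for r in log.set_results)
        assert all(s < 50.0 for s in log.scores)

    def test_skilled_subject_achieves_sets(self):
        subj = make_subject({"control_skill": 0.9}, seed=7)
        log = run_session(subj, RunConfig(), seed=7)
        assert sum(r.achieved for r in log.set_results) >= 5

    def test_same_seed_reproduces_log(self):
        subj = make_subject({}, seed=11)
        a = run_session(subj, RunConfig(), seed=3)
        b = run_session(subj, RunConfig(), seed=3)
        assert a.scores == b.scores
        assert a.user_level_after == b.user_level_after

    def test_heart_rate_mode_runs_and_responds_to_skill(self):
        cfg = RunConfig(signal_kind="HR")
        good = run_session(make_subject({"control_skill": 0.9}, seed=11),
                           cfg, seed=5)
        bad = run_session(make_subject({"control_skill": 0.0}, seed=11),
                          cfg, seed=5)
        assert len(good.set_results) == 10
        assert np.mean(good.scores) > np.mean(bad.scores)

    def test_level_before_comes_from_history(self):
        subj = make_subject({}, seed=7)
        log = run_session(subj, RunConfig(), seed=7,
                          score_history=[95.0] * 100)
        assert log.user_level_before == 10
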