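import math

import numpy as np
import pytest

from audcog.adaptive_tests import (BekesyConfig, GapConfig, HintConfig,
                                   TdtConfig, hint_composite, run_bekesy,
                                   run_gap_staircase, run_hint_condition,
                                   run_tdt, tracks_to_frame)
from audcog.listeners import PsychometricListener, make_gap_listener

from oracles import bekesy_trace, gap_trace, hint_trace, tdt_trace


def det(threshold, **kw):
    return PsychometricListener(threshold, mode="deterministic_step", **kw)


class TestBekesy:
    @pytest.mark.parametrize("threshold", [10.0, 3.0, 27.0, 55.0])
    def test_matches_brute_force_trace(self, threshold):
        track = run_bekesy(det(threshold), BekesyConfig(start_level=40.0))
        levels, heard, est = bekesy_trace(threshold, start=40.0)
        assert track.levels == levels
        assert [t.response for t in track.trials] == [int(h) for h in heard]
        assert track.estimate == est

    def test_step_listener_recovers_threshold_within_small_step(self):
        cfg = BekesyConfig(start_level=40.0)
        track = run_bekesy(det(10.0), cfg)
        assert abs(track.estimate - 10.0) <= cfg.small_step
        assert track.converged

    def test_always_hearing_listener_pins_at_floor(self):
        track = run_bekesy(det(-1e6), BekesyConfig(start_level=40.0))
        assert not track.converged
        assert math.isnan(track.estimate)
        assert min(track.levels) == BekesyConfig().min_level

    def test_same_seed_reproduces_track(self):
        lst = PsychometricListener(15.0, 1.0)
        a = run_bekesy(lst, BekesyConfig(), np.random.default_rng(5))
        b = run_bekesy(lst, BekesyConfig(), np.random.default_rng(5))
        assert a.levels == b.levels and a.estimate == b.estimate

    def test_big_step_used_only_before_first_reversal(self):
        track = run_bekesy(det(10.0), BekesyConfig(start_level=40.0))
        diffs = np.diff(track.levels)
        first_rev = next(i for i, t in enumerate(track.trials) if t.is_reversal)
        assert all(d == -4.0 for d in diffs[:first_rev])
        assert all(abs(d) == 2.0 for d in diffs[first_rev:])


class TestGap:
    @pytest.mark.parametrize("threshold_ms", [6.0, 3.5, 11.0, 17.0])
    def test_matches_brute_force_trace(self, threshold_ms):
        track = run_gap_staircase(
            make_gap_listener(threshold_ms, mode="deterministic_step"),
            GapConfig(),
        )
        gaps, corrects, est = gap_trace(threshold_ms)
        assert track.levels == gaps
        assert [bool(t.response) for t in track.trials] == corrects
        assert track.estimate == est

    def test_step_listener_recovers_threshold_within_min_step(self):
        cfg = GapConfig()
        track = run_gap_staircase(
            make_gap_listener(6.0, mode="deterministic_step"), cfg
        )
        assert abs(track.estimate - 6.0) <= cfg.min_step

    def test_always_correct_listener_flags_non_convergence_at_floor(self):
        track = run_gap_staircase(
            make_gap_listener(0.01, mode="deterministic_step"), GapConfig()
        )
        assert not track.converged
        assert min(track.levels) == GapConfig().min_gap

    def test_steep_stochastic_listener_reproduces_deterministic_trace(self):
        # slope -> infinity limit: p is exactly 0 or 1 off-threshold
        sharp = make_gap_listener(6.3, slope_per_octave=1e9)
        stoch = run_gap_staircase(sharp, GapConfig(), np.random.default_rng(3))
        deter = run_gap_staircase(
            make_gap_listener(6.3, mode="deterministic_step"), GapConfig(),
        )
        assert stoch.levels == deter.levels
        assert stoch.estimate == deter.estimate

    def test_reversals_mark_direction_changes_only(self):
        track = run_gap_staircase(
            make_gap_listener(6.0, mode="deterministic_step"), GapConfig()
        )
        rev_levels = track.reversal_levels
        assert len(rev_levels) == GapConfig().stop_reversals
        assert track.estimate == pytest.approx(
            np.mean(rev_levels[-GapConfig().estimator_reversals:]))

    def test_bias_symmetry_about_start_gap(self):
        # reflecting the threshold about the 20 ms start reflects the
        # expected estimate (Monte-Carlo, stochastic listeners)
        lo, hi = [], []
        for i in range(150):
            lo.append(run_gap_staircase(
                make_gap_listener(14.0, 4.0), GapConfig(),
                np.random.default_rng(30_000 + i)).estimate)
            hi.append(run_gap_staircase(
                make_gap_listener(26.0, 4.0), GapConfig(),
                np.random.default_rng(40_000 + i)).estimate)
        assert abs((np.nanmean(lo) + np.nanmean(hi)) - 2 * 20.0) < 1.5


class TestHint:
    def test_all_correct_closed_form_srt(self):
        track = run_hint_condition(det(-1e6), HintConfig(), "noise_front")
        # levels 0,-4,-8,-12 then -16,-18,...,-46: SRT = mean(-16..-46) = -31
        assert track.levels[:5] == [0.0, -4.0, -8.0, -12.0, -16.0]
        assert all(b < a for a, b in zip(track.levels, track.levels[1:]))
        assert track.estimate == -31.0

    def test_all_incorrect_mirror_image(self):
        track = run_hint_condition(det(1e6), HintConfig(), "noise_front")
        assert all(b > a for a, b in zip(track.levels, track.levels[1:]))
        assert track.estimate == 31.0

    @pytest.mark.parametrize("threshold", [-2.0, 3.0, -7.0])
    def test_matches_brute_force_trace(self, threshold):
        track = run_hint_condition(det(threshold), HintConfig(), "noise_left")
        levels, corrects, est = hint_trace(threshold)
        assert track.levels == levels
        assert track.estimate == est
        assert abs(track.estimate - threshold) <= HintConfig().step_rest

    def test_composite_is_mean_of_three_conditions(self):
        assert hint_composite(-2.0, -4.0, -6.0) == -4.0
        assert hint_composite(-3.0, -3.0, -3.0) == -3.0
        assert hint_composite(-2.5, -3.1, -4.3) == pytest.approx(-3.3)
        assert math.isnan(hint_composite(-2.0, math.nan, -6.0))

    def test_bias_symmetry_about_start_snr(self):
        lo, hi = [], []
        for i in range(150):
            lo.append(run_hint_condition(
                PsychometricListener(-4.0, 1.5), HintConfig(), "noise_front",
                np.random.default_rng(10_000 + i)).estimate)
            hi.append(run_hint_condition(
                PsychometricListener(+4.0, 1.5), HintConfig(), "noise_front",
                np.random.default_rng(20_000 + i)).estimate)
        assert abs(np.mean(lo) + np.mean(hi)) < 0.75

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            run_hint_condition(det(0.0), HintConfig(), "noise_behind")


class TestTdt:
    def test_always_correct_descends_4p5_per_pair(self):
        track = run_tdt(det(-1e6), TdtConfig(), np.random.default_rng(0))
        pair_snrs = [t.level for t in track.trials[::2]]
        assert pair_snrs == [pytest.approx(-4.5 * k) for k in range(18)]
        # positive-phase test SNRs: pairs 4..18; SRT = mean of last 14
        assert track.estimate == pytest.approx(-47.25)

    @pytest.mark.parametrize("threshold", [-6.0, -12.0, 2.0])
    def test_matches_brute_force_trace(self, threshold):
        track = run_tdt(det(threshold), TdtConfig(), np.random.default_rng(1))
        pair_snrs, positive_test, est = tdt_trace(threshold)
        assert [t.level for t in track.trials[::2]] == pair_snrs
        got_pos = [t.level for t in track.trials
                   if t.phase == "positive" and t.in_estimate]
        assert got_pos == positive_test
        assert track.estimate == est

    def test_half_correct_listener_has_no_drift(self):
        # at p_correct = 0.5 the expected per-pair move is 0
        lst = PsychometricListener(0.0, 1.0)  # p = 0.5 at 0 dB start
        finals = [run_tdt(lst, TdtConfig(), np.random.default_rng(i)).estimate
                  for i in range(300)]
        se = np.std(finals) / math.sqrt(len(finals))
        assert abs(np.mean(finals)) < 4 * se + 0.5

    def test_same_seed_identical_including_phase_order(self):
        lst = PsychometricListener(-5.0, 1.0, guess_rate=0.1)
        a = run_tdt(lst, TdtConfig(), np.random.default_rng(9))
        b = run_tdt(lst, TdtConfig(), np.random.default_rng(9))
        assert [(t.level, t.response, t.phase) for t in a.trials] == \
               [(t.level, t.response, t.phase) for t in b.trials]

    def test_each_pair_presented_at_same_snr_with_both_phases(self):
        track = run_tdt(PsychometricListener(-5.0, 1.0),
                        TdtConfig(), np.random.default_rng(2))
        for first, second in zip(track.trials[::2], track.trials[1::2]):
            assert first.level == second.level
            assert {first.phase, second.phase} == {"positive", "negative"}

    def test_srt_window_larger_than_positive_presentations_rejected(self):
        with pytest.raises(ValueError):
            TdtConfig(srt_last_k_positive=16)
        with pytest.raises(ValueError):
            TdtConfig(n_test_presentations=31)


def test_tracks_to_frame_long_format():
    t1 = run_hint_condition(det(-2.0), HintConfig(), "noise_front")
    t2 = run_tdt(det(-6.0), TdtConfig(), np.random.default_rng(0))
    df = tracks_to_frame([("S1", t1), ("S1", t2)])
    assert set(df["test"]) == {"hint", "tdt"}
    assert (df["subject_id"] == "S1").all()
    assert len(df) == len(t1.trials) + len(t2.trials)
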