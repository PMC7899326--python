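"""Per-trial feature definitions and the exclusion cascade."""

import numpy as np
import pandas as pd
import pytest

from gazefatigue.core import BlinkBurst, BlinkEvent, FEATURE_COLUMNS, OculomotorEvent, QCResult, TypingLog
from gazefatigue.features import (
    assemble_feature_table,
    compute_ansr,
    compute_blink_features,
    compute_error_rates,
    compute_eye_height,
    compute_pupil_baseline,
    compute_rte,
    compute_saccade_features,
    compute_typing_speed,
)


def mk_log(events, target="abcde"):
    return TypingLog(target_sentence=target, events=pd.DataFrame(events))


def select_events(chars, t0=0.0, gap=1.0, dwell=0.5):
    return [
        {"t_s": t0 + i * gap, "kind": "select", "key": c, "aoi": "keyboard", "dur_s": dwell}
        for i, c in enumerate(chars)
    ]


class TestTypingSpeed:
    @pytest.mark.parametrize("n_chars,secs,wpm", [(25, 60.0, 5.0), (0, 60.0, 0.0), (50, 120.0, 5.0)])
    def test_hand_arithmetic(self, n_chars, secs, wpm):
        events = select_events("x" * n_chars) if n_chars else [
            {"t_s": 0.0, "kind": "read", "key": "", "aoi": "typed_text", "dur_s": 1.0}
        ]
        assert compute_typing_speed(mk_log(events), secs) == pytest.approx(wpm)

    def test_zero_trial_time_rejected(self):
        with pytest.raises(ValueError):
            compute_typing_speed(mk_log(select_events("ab")), 0.0)


class TestErrorRates:
    def test_corrected_rate_hand_arithmetic(self):
        # 30 character selections, 3 of them followed by backspace
        evs = select_events("abcdefghij" * 3)
        for i in (5, 15, 25):
            evs.insert(i, {"t_s": evs[i]["t_s"] - 0.01, "kind": "backspace",
                           "key": "<-", "aoi": "keyboard", "dur_s": 0.3})
        evs.sort(key=lambda e: e["t_s"])
        corrected, _ = compute_error_rates(mk_log(evs, target="whatever"))
        assert corrected == pytest.approx(10.0)

    def test_perfect_copy_zero_uncorrected(self):
        log = mk_log(select_events("abc de"), target="abc de")
        _, unc = compute_error_rates(log)
        assert unc == 0.0

    def test_equally_weighted_char_and_word_errors(self):
        # final: 20 chars, 2 char errors; 5 words, 1 word error
        target = "aaa bbb ccc ddd eeee"
        final_ = "aaa bbb ccc ddd eexx"
        log = mk_log(select_events(final_), target=target)
        _, unc = compute_error_rates(log)
        assert unc == pytest.approx(50.0 * (2 / 20 + 1 / 5))

    def test_empty_final_string(self):
        log = mk_log([{"t_s": 0.0, "kind": "read", "key": "", "aoi": "typed_text", "dur_s": 0.5}],
                     target="abc")
        corrected, unc = compute_error_rates(log)
        assert unc == 100.0 and corrected == 0.0


class TestRte:
    def test_no_read_events_zero(self):
        assert compute_rte(mk_log(select_events("ab")), 60.0) == 0.0

    def test_hand_arithmetic(self):
        evs = select_events("ab") + [
            {"t_s": 5.0, "kind": "read", "key": "", "aoi": "typed_text", "dur_s": 4.0},
            {"t_s": 20.0, "kind": "read", "key": "", "aoi": "typed_text", "dur_s": 2.0},
        ]
        assert compute_rte(mk_log(evs), 60.0) == pytest.approx(0.1)

    def test_bound_case_one(self):
        evs = [{"t_s": 0.0, "kind": "read", "key": "", "aoi": "typed_text", "dur_s": 60.0}]
        assert compute_rte(mk_log(evs), 60.0) == pytest.approx(1.0)


class TestAnsr:
    def test_no_attend_events_zero(self):
        assert compute_ansr(mk_log(select_events("abcde"))) == 0.0

    def test_hand_arithmetic(self):
        evs = select_events("abcdefghij") + [
            {"t_s": 50.0, "kind": "attend", "key": "z", "aoi": "keyboard", "dur_s": 1.5},
            {"t_s": 55.0, "kind": "attend", "key": "q", "aoi": "keyboard", "dur_s": 0.5},
        ]
        assert compute_ansr(mk_log(evs)) == pytest.approx(0.2)

    def test_attendance_ending_in_selection_contributes_zero(self):
        evs = [
            {"t_s": 0.0, "kind": "attend", "key": "a", "aoi": "keyboard", "dur_s": 1.0},
            {"t_s": 0.8, "kind": "select", "key": "a", "aoi": "keyboard", "dur_s": 0.5},
        ]
        assert compute_ansr(mk_log(evs)) == 0.0

    def test_no_selections_flagged_missing(self):
        evs = [{"t_s": 0.0, "kind": "attend", "key": "a", "aoi": "keyboard", "dur_s": 1.0}]
        assert np.isnan(compute_ansr(mk_log(evs)))


class TestPupilBaseline:
    fs = 90.0

    def test_clean_break_returns_mean(self):
        y = np.full(450, 3.5)
        flags = np.zeros(450, dtype=bool)
        assert compute_pupil_baseline(y, flags, self.fs) == pytest.approx(3.5)

    def test_window_shifts_before_trailing_interpolation(self):
        y = np.concatenate([np.full(400, 3.0), np.full(50, 9.0)])
        flags = np.zeros(450, dtype=bool)
        flags[400:] = True  # last ~0.55 s interpolated
        assert compute_pupil_baseline(y, flags, self.fs) == pytest.approx(3.0)

    def test_fully_interpolated_break_missing(self):
        y = np.full(450, 3.5)
        flags = np.ones(450, dtype=bool)
        assert np.isnan(compute_pupil_baseline(y, flags, self.fs))


class TestBlinkAndSaccadeFeatures:
    def test_blink_feature_arithmetic(self):
        blinks = [BlinkEvent(start=s, end=s + 0.2) for s in (0.0, 2.0, 6.0)]
        bursts = [BlinkBurst(start=0.0, end=2.2, n_blinks=2)]
        freq, dur, interval, ratio = compute_blink_features(blinks, bursts, 60.0)
        assert freq == pytest.approx(0.05)
        assert dur == pytest.approx(0.2)
        assert interval == pytest.approx(3.0)
        assert ratio == pytest.approx(1 / 0.05)

    def test_no_blinks_degenerate(self):
        freq, dur, interval, ratio = compute_blink_features([], [], 60.0)
        assert freq == 0.0
        assert np.isnan(dur) and np.isnan(interval) and np.isnan(ratio)

    def test_saccade_mean_features(self):
        sacs = [
            OculomotorEvent("saccade", 0.0, 0.04, amplitude=2.0, peak_velocity=150.0),
            OculomotorEvent("saccade", 1.0, 1.06, amplitude=4.0, peak_velocity=250.0),
        ]
        amp, dur, pv = compute_saccade_features(sacs)
        assert amp == pytest.approx(3.0)
        assert dur == pytest.approx(0.05)
        assert pv == pytest.approx(200.0)
        amp_sum, _, _ = compute_saccade_features(sacs, agg="sum")
        assert amp_sum == pytest.approx(6.0)

    def test_no_saccades_missing(self):
        amp, dur, pv = compute_saccade_features([])
        assert np.isnan(amp) and np.isnan(dur) and np.isnan(pv)


class TestEyeHeight:
    def test_difference_from_day_reference(self, stream_factory):
        df = stream_factory(100)
        df["eye_y_cm"] = 32.0
        assert compute_eye_height(df, 35.0) == pytest.approx(-3.0)

    def test_missing_channel_gives_nan(self, stream_factory):
        df = stream_factory(50)
        df["eye_y_cm"] = np.nan
        assert np.isnan(compute_eye_height(df, 35.0))


def _trial_frame(n_participants=18, n_days=4):
    rows = []
    rng = np.random.default_rng(0)
    for p in range(n_participants):
        for d in range(1, n_days + 1):
            for tr in range(1, 11):
                row = {
                    "participant": f"P{p:02d}", "day": d,
                    "session": 1 if tr <= 5 else 2, "trial": tr,
                    "difficulty": "easy", "language": "danish",
                    "perceived_effort": int(rng.integers(1, 8)),
                    "fatigue_level": float(rng.integers(1, 7)) if tr in (1, 5, 10) else np.nan,
                }
                row.update({f: float(rng.normal(1, 0.1)) for f in FEATURE_COLUMNS})
                rows.append(row)
    return pd.DataFrame(rows)


class TestAssembly:
    def test_default_design_row_counts(self):
        stats_table, model_table, log = assemble_feature_table(_trial_frame())
        assert len(stats_table) == 720
        assert int(stats_table["trial"].isin([1, 5, 10]).sum()) == 216
        assert len(model_table) == 216
        assert not log

    def test_qc_failed_session_removed_everywhere(self):
        df = _trial_frame()
        qc = [QCResult(("P00", 1, 1), 0.4, False)]
        stats_table, model_table, log = assemble_feature_table(df, qc)
        assert len(stats_table) == 715
        sel = (stats_table["participant"] == "P00") & (stats_table["day"] == 1) & (stats_table["session"] == 1)
        assert not sel.any()
        assert len([l for l in log if l["reason"] == "qc_failed_session"]) == 5

    def test_missing_feature_rows_dropped_and_logged(self):
        df = _trial_frame()
        df.loc[3, "blink_frequency"] = np.nan
        stats_table, _, log = assemble_feature_table(df)
        assert len(stats_table) == 719
        assert any(l["reason"] == "missing_feature" for l in log)

    def test_sparse_fatigue_level_pruned(self):
        df = _trial_frame()
        mask = df["trial"].isin([1, 5, 10])
        df.loc[mask, "fatigue_level"] = 3.0
        idx = df[mask].index[:3]
        df.loc[idx, "fatigue_level"] = 7.0  # only 3 rows at level 7
        _, model_table, log = assemble_feature_table(df)
        assert 7.0 not in set(model_table["fatigue_level"])
        assert sum("sparse_fatigue_level" in l["reason"] for l in log) == 3

    def test_thin_participant_dropped(self):
        df = _trial_frame(n_participants=4)
        mask = (df["participant"] == "P00") & df["trial"].isin([5, 10])
        df.loc[mask, "fatigue_level"] = np.nan  # P00 left with 4 labelled trials
        _, model_table, log = assemble_feature_table(df, min_level_count=0)
        assert "P00" not in set(model_table["participant"])
        assert any(l["reason"] == "participant_too_few_trials" for l in log)

    def test_counts_reconcile(self):
        df = _trial_frame(n_participants=6, n_days=2)
        df.loc[10:14, "rte"] = np.nan
        stats_table, _, log = assemble_feature_table(df)
        dropped = sum(l["reason"] == "missing_feature" for l in log)
        assert len(stats_table) + dropped == len(df)

    def test_empty_result_rejected(self):
        df = _trial_frame(n_participants=1, n_days=1)
        df[FEATURE_COLUMNS] = np.nan
        with pytest.raises(ValueError):
            assemble_feature_table(df)
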