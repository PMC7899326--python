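"""Gaze-stream cleaning rules: invalidation, blinks, interpolation, pupil."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_stream
from oracles import classify_runs_brute, hampel_brute
from gazefatigue.core import SIGNAL_COLUMNS, missing_mask
from gazefatigue.preprocessing import (
    clean_pupil,
    detect_blinks,
    fuse_binocular_pupil,
    hampel_filter,
    interpolate_gaps,
    mark_invalid_samples,
    preprocess_trial,
    session_quality_check,
)
from gazefatigue.core import BlinkEvent


class TestMarkInvalid:
    def test_repeated_rows_blanked(self):
        df = make_stream(20)
        df.loc[5:7, SIGNAL_COLUMNS] = df.loc[5, SIGNAL_COLUMNS].values
        out, n = mark_invalid_samples(df)
        assert n == 3
        assert missing_mask(out)[5:8].all()
        assert not missing_mask(out)[:5].any()

    def test_clean_stream_unchanged(self):
        df = make_stream(15)
        out, n = mark_invalid_samples(df)
        assert n == 0
        pd.testing.assert_frame_equal(out, df)

    def test_all_constant_stream_fully_blanked(self):
        df = make_stream(10)
        df.loc[:, SIGNAL_COLUMNS] = df.loc[0, SIGNAL_COLUMNS].values
        out, n = mark_invalid_samples(df)
        assert n == 10
        assert missing_mask(out).all()

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError):
            mark_invalid_samples(make_stream(5).iloc[:0])


class TestDetectBlinks:
    @pytest.mark.parametrize(
        "runs,expected",
        [
            ([(50, 27)], (1, 0, 0)),   # 0.300 s at 90 Hz -> blink
            ([(50, 4)], (0, 1, 0)),    # 0.044 s -> short gap
            ([(30, 18), (60, 72), (150, 9)], (2, 0, 1)),  # 0.2 / 0.8 / 0.1 s
        ],
    )
    def test_run_classification(self, runs, expected):
        df = make_stream(400, missing=runs)
        blinks, short, losses = detect_blinks(df)
        assert (len(blinks), len(short), len(losses)) == expected

    def test_boundary_durations_count_as_blinks(self):
        # at 40 Hz: 3 samples = 0.075 s, 20 samples = 0.500 s
        df = make_stream(200, fs=40.0, missing=[(20, 3), (100, 20)])
        blinks, short, losses = detect_blinks(df)
        assert len(blinks) == 2 and not short and not losses

    def test_every_missing_run_classified_exactly_once(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            runs = []
            pos = 5
            while pos < 800:
                length = int(rng.integers(1, 60))
                runs.append((pos, length))
                pos += length + int(rng.integers(2, 40))
            runs = [r for r in runs if r[0] + r[1] < 800]
            df = make_stream(800, missing=runs)
            blinks, short, losses = detect_blinks(df)
            assert len(blinks) + len(short) + len(losses) == len(runs)


class TestInterpolateGaps:
    def test_linear_ramp_recovered_exactly(self):
        df = make_stream(100)
        ramp = np.linspace(0.0, 10.0, 100)
        for c in SIGNAL_COLUMNS:
            df[c] = ramp
        df.loc[40:46, SIGNAL_COLUMNS] = np.nan
        df.loc[40:46, "valid"] = 0
        blinks, short, _ = detect_blinks(df)
        out = interpolate_gaps(df, blinks, short)
        assert np.allclose(out["pupil_l"], ramp)
        assert out["interp"].to_numpy()[40:47].all()

    def test_edge_gap_left_unfilled(self):
        df = make_stream(100, missing=[(0, 10)])
        blinks, short, _ = detect_blinks(df)
        out = interpolate_gaps(df, blinks, short)
        assert out["pupil_l"].isna()[:10].all()

    def test_no_gaps_identity(self):
        df = make_stream(50)
        out = interpolate_gaps(df, [], [])
        assert np.allclose(out["pupil_l"], df["pupil_l"])
        assert not out["interp"].any()

    def test_out_of_bounds_event_rejected(self):
        df = make_stream(50)
        with pytest.raises(ValueError):
            interpolate_gaps(df, [BlinkEvent(start=10.0, end=10.2)])


class TestHampel:
    def test_spike_replaced_by_median(self):
        x = np.array([1, 1, 1, 10, 1, 1, 1], dtype=float)
        out, bad = hampel_filter(x)
        assert out[3] == 1.0
        assert list(bad) == [3]

    def test_constant_series_untouched(self):
        x = np.full(50, 2.5)
        out, bad = hampel_filter(x)
        assert np.array_equal(out, x)
        assert len(bad) == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            x = rng.normal(0, 1, int(rng.integers(7, 60)))
            spikes = rng.integers(0, len(x), 3)
            x[spikes] += rng.choice([-1, 1], 3) * 10
            out, _ = hampel_filter(x)
            assert np.allclose(out[2:-2], hampel_brute(x)[2:-2])

    def test_short_series_passthrough_with_warning(self):
        with pytest.warns(UserWarning):
            out, bad = hampel_filter(np.array([1.0, 2.0]))
        assert len(bad) == 0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hampel_filter(np.zeros(10), window=4)


class TestCleanPupil:
    def test_margin_interpolated_around_blink(self):
        fs = 90.0
        df = make_stream(450, fs=fs)
        df["pupil_l"] = 3.5
        df["pupil_r"] = 3.5
        # contaminate pupil strictly inside what will be the margin span
        df.loc[80:119, ["pupil_l", "pupil_r"]] = 5.0
        blink = BlinkEvent(start=1.0, end=1.2)
        out, mask = clean_pupil(df, [blink])
        t = out["t_s"].to_numpy()
        span = (t >= 0.8) & (t < 1.4)
        assert np.allclose(out.loc[span, "pupil_l"], 3.5, atol=1e-6)
        assert mask[span].all()

    def test_overlapping_margins_merged(self):
        df = make_stream(600)
        b1 = BlinkEvent(start=1.0, end=1.2)
        b2 = BlinkEvent(start=1.5, end=1.7)  # margins [0.8,1.4] & [1.3,1.9] overlap
        out, mask = clean_pupil(df, [b1, b2])
        t = out["t_s"].to_numpy()
        assert mask[(t >= 0.8) & (t < 1.9)].all()

    def test_no_blinks_no_outliers_identity(self):
        df = make_stream(200)
        df[["pupil_l", "pupil_r"]] = 3.5  # outlier-free by construction
        out, mask = clean_pupil(df, [])
        assert np.allclose(out["pupil_l"], df["pupil_l"])
        assert not mask.any()

    def test_samples_outside_spans_untouched(self):
        df = make_stream(400)
        base = df["pupil_l"].to_numpy().copy()
        out, mask = clean_pupil(df, [BlinkEvent(start=2.0, end=2.2)])
        t = out["t_s"].to_numpy()
        outside = (t < 1.8 - 1e-9) | (t >= 2.4)
        assert np.allclose(out["pupil_l"].to_numpy()[outside], base[outside])


class TestFusion:
    def test_identical_eyes_returns_input(self):
        rng = np.random.default_rng(1)
        x = 3.5 + rng.normal(0, 0.1, 200)
        fused = fuse_binocular_pupil(x, x)
        assert np.allclose(fused, x)

    def test_weights_follow_inverse_sd(self):
        rng = np.random.default_rng(2)
        n = 300
        left = 3.0 + rng.normal(0, 0.2, n)
        right = 4.0 + rng.normal(0, 0.1, n)
        fused = fuse_binocular_pupil(left, right)
        i = 250
        sl = np.std(left[i - 24 : i + 1], ddof=1)
        sr = np.std(right[i - 24 : i + 1], ddof=1)
        wl, wr = 1 / sl, 1 / sr
        expected = (wl * left[i] + wr * right[i]) / (wl + wr)
        assert fused[i] == pytest.approx(expected, rel=1e-9)

    def test_constant_eye_stays_finite(self):
        left = np.full(100, 3.5)
        right = np.full(100, 3.6)
        fused = fuse_binocular_pupil(left, right)
        assert np.isfinite(fused[30:]).all()

    def test_one_eye_missing_falls_back(self):
        left = np.full(60, 3.0)
        right = np.full(60, 4.0)
        left[30:35] = np.nan
        fused = fuse_binocular_pupil(left, right)
        assert np.allclose(fused[30:35], 4.0)
        both = left.copy()
        both[40] = np.nan
        fused2 = fuse_binocular_pupil(both, np.where(np.arange(60) == 40, np.nan, right))
        assert np.isnan(fused2[40])


class TestSessionQC:
    def test_identical_eyes_pass(self):
        df = make_stream(300)
        df["pupil_r"] = df["pupil_l"]
        res = session_quality_check([df])
        assert res.passed and res.pearson_r == pytest.approx(1.0)

    def test_mirrored_eyes_fail(self):
        df = make_stream(300)
        df["pupil_l"] = 3.5 + np.sin(np.arange(300) / 10)
        df["pupil_r"] = 3.5 - np.sin(np.arange(300) / 10)
        res = session_quality_check([df])
        assert not res.passed and res.pearson_r == pytest.approx(-1.0)

    def test_half_correlated_fails(self):
        rng = np.random.default_rng(3)
        n = 2000
        shared = rng.normal(0, 1.0, n)
        df = make_stream(n)
        df["pupil_l"] = 3.5 + shared + rng.normal(0, 1.0, n)
        df["pupil_r"] = 3.5 + shared + rng.normal(0, 1.0, n)
        res = session_quality_check([df])  # true r = 0.5
        assert not res.passed
        assert res.pearson_r == pytest.approx(0.5, abs=0.1)

    def test_insufficient_pairs_fail_with_reason(self):
        df = make_stream(10)
        df[["pupil_l", "pupil_r"]] = np.nan
        res = session_quality_check([df])
        assert not res.passed and res.reason


class TestBlinkRecoveryProperty:
    def test_injected_blinks_recovered_without_false_positives(self):
        from gazefatigue.design import build_experiment_design
        from gazefatigue.simulate import OculomotorParams, simulate_trial_gaze

        design = build_experiment_design(1, 1, seed=0)
        params = OculomotorParams(trackloss_rate=0.0)
        n_true = n_found = n_extra = 0
        for seed in range(15):
            stream, truth = simulate_trial_gaze(
                design, params, seed=seed, latent=2.0, trial_duration=30.0
            )
            pre = preprocess_trial(stream)
            n_true += len(truth.blinks)
            truth_starts = {round(b.start, 6) for b in truth.blinks}
            for b in pre.blinks:
                if round(b.start, 6) in truth_starts:
                    n_found += 1
                else:
                    n_extra += 1
        assert n_true > 20
        assert n_found / n_true >= 0.95
        assert n_extra == 0
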