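import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import physioevents as pe
from oracles import best_subset_selection, edr_bruteforce


def ramp(amplitude, duration_s, pad_s=20.0, baseline=2.0):
    """2 Hz series: flat pad, linear rise of `amplitude` over `duration_s`, flat pad."""
    npad = int(pad_s * 2)
    nramp = int(duration_s * 2)
    up = baseline + amplitude * np.arange(1, nramp + 1) / nramp
    return np.concatenate([np.full(npad, baseline), up, np.full(npad, baseline + amplitude)])


class TestDetectEdr:
    def test_constant_is_silent(self):
        assert not pe.detect_edr(np.full(100, 2.0)).any()

    def test_canonical_minimum_ramp_fires(self):
        out = pe.detect_edr(ramp(0.05, 10.0), t_edr_s=10.0, a_edr_us=0.05)
        assert out.max() == pytest.approx(0.05, abs=1e-9)

    def test_tailored_threshold_0p24(self):
        assert pe.detect_edr(ramp(0.24, 10.0), 10.0, 0.24).any()
        assert not pe.detect_edr(ramp(0.20, 10.0), 10.0, 0.24).any()

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_random_walk_matches_bruteforce(self, seed):
        x = 2.0 + 0.05 * np.random.default_rng(seed).standard_normal(300).cumsum()
        out = pe.detect_edr(x, 10.0, 0.05)
        np.testing.assert_allclose(out, edr_bruteforce(x, 10.0, 0.05), rtol=0, atol=0)


class TestDetectTempTrend:
    def test_worked_range_of_0p01_fires_at_threshold(self):
        temp = np.full(60, 35.8367)
        temp[20:40] = np.linspace(35.8367, 35.8267, 20)
        out = pe.detect_temp_trend(temp, t_temp_s=10.0, dt_min_c=0.01)
        assert out.max() == pytest.approx(0.0100, abs=1e-12)

    def test_worked_range_of_0p17_over_20s(self):
        temp = np.concatenate([np.full(20, 33.79), np.linspace(33.79, 33.96, 40), np.full(20, 33.96)])
        out = pe.detect_temp_trend(temp, t_temp_s=20.0, dt_min_c=0.01)
        assert out.max() == pytest.approx(0.17, abs=1e-12)

    def test_constant_is_silent(self):
        assert not pe.detect_temp_trend(np.full(100, 33.0)).any()

    def test_sign_change_mode_requires_reversal(self):
        rising = np.linspace(33.0, 33.5, 100)  # monotone: no reversal
        assert pe.detect_temp_trend(rising, 10.0, 0.01).any()
        assert not pe.detect_temp_trend(rising, 10.0, 0.01, require_sign_change=True).any()


def triangle(prominence, baseline=70.0, half_steps=10, pad=40):
    up = baseline + prominence * np.arange(1, half_steps + 1) / half_steps
    down = up[-2::-1]
    return np.concatenate([np.full(pad, baseline), up, down, np.full(pad, baseline)])


class TestDetectHrVar:
    def test_monotone_is_silent(self):
        assert not pe.detect_hr_var(np.linspace(60, 100, 100)).any()

    def test_triangle_prominence_15_fires_at_10(self):
        out = pe.detect_hr_var(triangle(15.0), 10.0)
        assert out.max() == pytest.approx(15.0)

    def test_tailored_threshold_25(self):
        assert not pe.detect_hr_var(triangle(15.0), 25.0).any()
        assert pe.detect_hr_var(triangle(28.0), 25.0).any()

    def test_minima_detected_symmetrically(self):
        out = pe.detect_hr_var(-triangle(15.0) + 140.0, 10.0)
        assert out.max() == pytest.approx(15.0)


class TestScore:
    def test_unit_weight_sum(self):
        f = pe.FeatureSeries(np.array([0.0]), np.array([1.0]), np.array([2.0]), np.array([3.0]))
        assert pe.score(f).s[0] == 6.0

    def test_zero_features_zero_score(self):
        z = np.zeros(5)
        assert not pe.score(pe.FeatureSeries(np.arange(5.0), z, z, z)).s.any()

    def test_tailored_scaling(self):
        f = pe.FeatureSeries(np.array([0.0]), np.array([0.24]), np.array([0.0]), np.array([0.0]))
        s = pe.score(f, a=5.0, b=1.0, c=1.0)
        assert s.s[0] == pytest.approx(1.2)
        assert s.dominant[0] == "eda"

    def test_negative_weight_rejected(self):
        f = pe.FeatureSeries(np.array([0.0]), np.zeros(1), np.zeros(1), np.zeros(1))
        with pytest.raises(pe.ValidationError):
            pe.score(f, a=-1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(min_value=0.0, max_value=10.0, allow_nan=False),
        st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_score_is_linear_in_features(self, alpha, seed):
        r = np.random.default_rng(seed)
        t2 = np.arange(20) * 0.5
        e, d, h = r.random(20), r.random(20), r.random(20)
        base = pe.score(pe.FeatureSeries(t2, e, d, h), 1.0, 2.0, 3.0).s
        scaled = pe.score(pe.FeatureSeries(t2, alpha * e, alpha * d, alpha * h), 1.0, 2.0, 3.0).s
        np.testing.assert_allclose(scaled, alpha * base, atol=1e-9)


def score_series(t2, s):
    return pe.ScoreSeries(t2=t2, s=s, dominant=np.array(["eda"] * len(t2)))


class TestSelectEvents:
    def test_zero_scores_select_nothing(self):
        t2 = np.arange(100) * 0.5
        assert pe.select_events(score_series(t2, np.zeros(100)), np.ones(100)) == []

    def test_equal_maxima_tie_broken_by_time(self):
        t2 = np.arange(200) * 0.5
        s = np.zeros(200)
        s[40] = s[100] = 1.0  # 30 s apart
        events = pe.select_events(score_series(t2, s), np.ones(200), max_events=2)
        assert [e.time_s for e in events] == [20.0, 50.0]

    def test_matches_exhaustive_subset_oracle(self, rng):
        t2 = np.arange(1200) * 0.5
        s = np.zeros(1200)
        peak_idx = rng.choice(np.arange(60, 1140, 60), size=10, replace=False)
        s[peak_idx] = rng.uniform(1.0, 5.0, 10)
        events = pe.select_events(score_series(t2, s), np.ones(1200), max_events=5, min_sep_s=20.0)
        total = sum(e.score for e in events)
        best = best_subset_selection(t2[peak_idx], s[peak_idx], 5, 20.0)
        assert total == pytest.approx(best)

    def test_respects_max_events_budget(self, rng):
        t2 = np.arange(2000) * 0.5
        s = rng.random(2000)
        events = pe.select_events(score_series(t2, s), np.ones(2000), max_events=7)
        assert len(events) <= 7

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_output_sorted_separated_and_quality_gated(self, seed):
        r = np.random.default_rng(seed)
        n = 400
        t2 = np.arange(n) * 0.5
        s = r.random(n)
        sqi = (r.random(n) > 0.2).astype(float)
        events = pe.select_events(score_series(t2, s), sqi, max_events=6, min_sep_s=20.0)
        times = [e.time_s for e in events]
        assert times == sorted(times)
        for a, b in zip(times, times[1:]):
            assert b - a >= 20.0
        for ev in events:
            assert sqi[int(round(ev.time_s / 0.5))] == 1.0


class TestThresholdMonotonicity:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_raising_thresholds_never_fires_more(self, seed):
        r = np.random.default_rng(seed)
        eda = 2.0 + 0.05 * r.standard_normal(200).cumsum()
        temp = 33.0 + 0.01 * r.standard_normal(200).cumsum()
        hr = 70.0 + r.standard_normal(200).cumsum()
        for lo, hi, fn in [
            (0.02, 0.1, lambda th: pe.detect_edr(eda, 10.0, th)),
            (0.005, 0.05, lambda th: pe.detect_temp_trend(temp, 10.0, th)),
            (2.0, 10.0, lambda th: pe.detect_hr_var(hr, th)),
        ]:
            assert np.count_nonzero(fn(hi)) <= np.count_nonzero(fn(lo))


class TestRunDetector:
    def test_flat_recording_yields_no_events(self, small_recording):
        clean = pe.preprocess(small_recording)
        sqi = pe.score_quality(clean.t2, clean.eda, clean.temp)
        # flat channels trip the flatness quality rules, and nothing scores
        assert pe.run_detector(clean, sqi) == []

    def test_single_embedded_edr_found(self):
        cfg = pe.SynthConfig(duration_s=240.0, seed=11, events=[pe.SynthEvent(120.0, "eda", 0.3, 8.0)])
        rec, _ = pe.generate(cfg)
        clean = pe.preprocess(rec)
        sqi = pe.SQISeries(clean.t2, np.ones(len(clean)), np.ones(len(clean)), np.ones(len(clean)))
        events = pe.run_detector(clean, sqi)
        assert len(events) == 1
        assert events[0].dominant_modality == "eda"
        assert abs(events[0].time_s - 120.0) <= 5.0

    def test_feature_in_invalid_region_suppressed(self):
        cfg = pe.SynthConfig(duration_s=240.0, seed=11, events=[pe.SynthEvent(120.0, "eda", 0.3, 8.0)])
        rec, _ = pe.generate(cfg)
        clean = pe.preprocess(rec)
        n = len(clean)
        sqi_all = np.ones(n)
        sqi_all[np.abs(clean.t2 - 120.0) <= 30.0] = 0.0
        sqi = pe.SQISeries(clean.t2, np.ones(n), np.ones(n), sqi_all)
        assert pe.run_detector(clean, sqi) == []
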