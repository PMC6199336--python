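"""Trace processing: sliding-window search, onset detection, trends."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forcematch.exceptions import TraceTooShortError
from forcematch.task import ForceTrace, TaskDesign
from forcematch.traces import (
    classify_response,
    detect_initiation,
    find_stable_window,
    premature_onset,
    stabilization_time,
    within_window_trend,
)


def make_trace(matching_force, sampling_rate=100.0, presentation_s=1.0):
    """Trace with a flat 1 N presentation phase and the given matching
    samples appended."""
    n_pres = int(presentation_s * sampling_rate)
    force = np.concatenate([np.full(n_pres, 1.0), matching_force])
    return ForceTrace(
        force=force,
        sampling_rate=sampling_rate,
        presentation_end=presentation_s,
        matching_end=(len(force) - 1) / sampling_rate,
    )


def brute_force_window(trace, window_s):
    """Independent oracle: enumerate every admissible window explicitly."""
    w = int(round(window_s * trace.sampling_rate))
    i0, i1 = trace.matching_bounds()
    best = None
    for start in range(i0, i1 - w + 1):
        seg = trace.force[start : start + w]
        sd = float(np.asarray(seg).std(ddof=1))
        if best is None or sd < best[0]:
            best = (sd, start, float(np.mean(seg)))
    return best


class TestFindStableWindow:
    def test_constant_trace_earliest_window(self):
        trace = make_trace(np.full(200, 2.0))
        res = find_stable_window(trace, 0.5)
        assert res.within_window_sd == 0.0
        assert res.mean_force == 2.0
        assert res.start_index == trace.matching_bounds()[0]

    def test_oscillation_then_flat_selects_flat_part(self):
        sr = 100.0
        t = np.arange(100) / sr
        first = 1.5 + 0.5 * np.sin(2 * np.pi * 8 * t)
        second = np.full(100, 1.8)
        trace = make_trace(np.concatenate([first, second]))
        res = find_stable_window(trace, 0.5)
        assert res.mean_force == pytest.approx(1.8)
        assert res.start_time >= trace.presentation_end + 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        trace = make_trace(rng.normal(2.0, 0.3, size=200))
        res = find_stable_window(trace, 0.5)
        sd, start, mean = brute_force_window(trace, 0.5)
        assert res.start_index == start
        assert res.within_window_sd == pytest.approx(sd, abs=1e-12)
        assert res.mean_force == pytest.approx(mean, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=-3.0, max_value=3.0),
    )
    def test_translation_invariance(self, seed, shift):
        rng = np.random.default_rng(seed)
        matching = rng.normal(2.0, 0.3, size=200)
        base = find_stable_window(make_trace(matching), 0.5)
        moved = find_stable_window(make_trace(matching + shift), 0.5)
        assert moved.start_index == base.start_index
        assert moved.mean_force == pytest.approx(base.mean_force + shift, abs=1e-9)
        assert moved.within_window_sd == pytest.approx(
            base.within_window_sd, abs=1e-9
        )
        assert moved.trend_slope == pytest.approx(base.trend_slope, abs=1e-9)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.integers(min_value=0, max_value=2**31 - 1),
        st.floats(min_value=0.1, max_value=5.0),
    )
    def test_scale_equivariance(self, seed, c):
        rng = np.random.default_rng(seed)
        matching = rng.normal(2.0, 0.3, size=200)
        base = find_stable_window(make_trace(matching), 0.5)
        scaled = find_stable_window(
            ForceTrace(
                force=np.concatenate([np.full(100, 1.0), matching]) * c,
                sampling_rate=100.0,
                presentation_end=1.0,
                matching_end=(100 + 200 - 1) / 100.0,
            ),
            0.5,
        )
        assert scaled.start_index == base.start_index
        assert scaled.mean_force == pytest.approx(c * base.mean_force, rel=1e-9)
        assert scaled.within_window_sd == pytest.approx(
            c * base.within_window_sd, rel=1e-9
        )

    def test_window_minimality(self, rng):
        trace = make_trace(rng.normal(2.0, 0.3, size=200))
        res = find_stable_window(trace, 0.5)
        w = res.n_samples
        i0, i1 = trace.matching_bounds()
        for start in range(i0, i1 - w + 1):
            sd = trace.force[start : start + w].std(ddof=1)
            assert sd >= res.within_window_sd - 1e-12
            if sd == res.within_window_sd:
                assert start >= res.start_index

    def test_earliest_start_restriction(self, rng):
        # quiet early segment would win an unrestricted search
        quiet = np.zeros(80)
        noisy = rng.normal(2.0, 0.2, size=150)
        trace = make_trace(np.concatenate([quiet, noisy]))
        unrestricted = find_stable_window(trace, 0.5)
        restricted = find_stable_window(
            trace, 0.5, earliest_start=trace.presentation_end + 0.8
        )
        assert unrestricted.mean_force == pytest.approx(0.0, abs=0.2)
        assert restricted.start_time >= trace.presentation_end + 0.8
        assert restricted.mean_force == pytest.approx(2.0, abs=0.2)

    def test_too_short_raises(self):
        trace = make_trace(np.ones(20))
        with pytest.raises(TraceTooShortError):
            find_stable_window(trace, 0.5)


class TestInitiation:
    def test_step_input(self):
        matching = np.concatenate([np.zeros(30), np.full(170, 2.0)])
        trace = make_trace(matching)
        assert detect_initiation(trace, 2.0) == pytest.approx(0.3)

    def test_all_zero_returns_absent(self):
        trace = make_trace(np.zeros(200))
        assert detect_initiation(trace, 2.0) is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ramp = np.clip((np.arange(200) - 50) / 60.0, 0, 1) * 2.0
        matching = ramp + rng.normal(0, 0.02, size=200)
        trace = make_trace(matching)
        got = detect_initiation(trace, 2.0, sustain_duration=0.05)
        # oracle: scan every sample for a 5-sample sustained crossing
        thr = 0.05 * 2.0
        above = matching > thr
        expected = None
        for i in range(len(above) - 4):
            if above[i : i + 5].all():
                expected = i / 100.0
                break
        assert got == pytest.approx(expected)


class TestClassifyResponse:
    def test_premature_onset_during_presentation(self, design):
        sr = design.sampling_rate
        n = int(round(design.matching_end * sr)) + 1
        t = np.arange(n) / sr
        # press starts at 2.0 s, before the 2.5 s go cue
        press = np.where(t >= 2.0, 2.0, 0.0)
        motor = np.where(t < design.presentation_end, 2.0, 0.0)
        trace = ForceTrace(press + motor, sr, design.presentation_end, design.matching_end)
        assert premature_onset(trace, 2.0) == pytest.approx(2.0, abs=0.01)
        assert classify_response(trace, 2.0, 0.0, design) == "premature"

    def test_late_initiation(self, design):
        trace = make_trace(np.zeros(400), sampling_rate=100.0)
        assert classify_response(trace, 2.0, 1.2, design) == "late"
        assert classify_response(trace, 2.0, None, design) == "late"

    def test_valid_initiation(self, design):
        matching = np.concatenate([np.zeros(40), np.full(360, 2.0)])
        trace = make_trace(matching, sampling_rate=100.0)
        assert classify_response(trace, 2.0, 0.4, design) == "valid"


class TestTrendAndStabilization:
    def test_constant_window_zero_slope(self):
        trace = make_trace(np.full(200, 2.0))
        res = find_stable_window(trace, 0.5)
        assert within_window_trend(trace, res) == pytest.approx(0.0, abs=1e-12)

    def test_linear_window_exact_slope(self):
        # rises 0.1 N over the 0.5 s window -> slope 0.2 N/s
        matching = 1.0 + 0.2 * np.arange(200) / 100.0
        trace = make_trace(matching)
        res = find_stable_window(trace, 0.5)
        assert res.trend_slope == pytest.approx(0.2, rel=1e-9)

    def test_noisy_window_matches_normal_equations(self, rng):
        matching = rng.normal(2.0, 0.1, size=200)
        trace = make_trace(matching)
        res = find_stable_window(trace, 0.5)
        sl = slice(res.start_index, res.start_index + res.n_samples)
        tt = np.arange(res.start_index, res.start_index + res.n_samples) / 100.0
        ff = trace.force[sl]
        n = len(tt)
        slope = (n * (tt * ff).sum() - tt.sum() * ff.sum()) / (
            n * (tt**2).sum() - tt.sum() ** 2
        )
        assert res.trend_slope == pytest.approx(slope, rel=1e-9)

    def test_stabilization_time_references(self):
        trace = make_trace(np.full(300, 2.0))
        res = find_stable_window(trace, 0.5)
        t_start = stabilization_time(res, trace.presentation_end)
        assert t_start == pytest.approx(res.start_time - 1.0)
        t_mid = stabilization_time(res, trace.presentation_end, reference="center")
        assert t_mid == pytest.approx(t_start + 0.25)
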