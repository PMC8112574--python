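"""Velocity-threshold detection cascade: blink handling, smoothing, speed,
candidate detection, filters, raw restoration, and end-to-end recovery."""

from dataclasses import replace

import numpy as np
import pytest

from saccland.detection import (DetectionParams, compute_speed, detect_saccades,
                                filter_saccades, interpolate_blinks,
                                restore_raw, run_detection,
                                saccade_passes_filters, smooth_trace)
from saccland.simulate import (SimulatorParams, sample_user_profile,
                               synth_session, velocity_profile)
from saccland.trace import GazeTrace, Saccade


def _make_trace(x, y=None, valid=None):
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    valid = np.ones(len(x), dtype=bool) if valid is None else np.asarray(valid, bool)
    return GazeTrace(t=np.arange(len(x)), x=x, y=y, valid=valid)


class TestBlinkInterpolation:
    def test_fully_valid_trace_unchanged(self):
        trace = _make_trace(np.linspace(0, 1, 60))
        out = interpolate_blinks(trace)
        np.testing.assert_array_equal(out.x, trace.x)

    def test_gap_in_stationary_fixation_filled_flat(self):
        x = np.full(100, 3.0)
        y = np.full(100, 3.0)
        valid = np.ones(100, bool)
        x[40:60] = np.nan
        y[40:60] = np.nan
        valid[40:60] = False
        out = interpolate_blinks(_make_trace(x, y, valid))
        assert out.valid.all()
        assert np.allclose(out.x[40:60], 3.0, atol=1e-6)
        assert np.allclose(out.y[40:60], 3.0, atol=1e-6)

    def test_high_speed_flanks_absorbed(self):
        # fixation at 0, 5 samples rushing at 100 deg/s into the gap, gap,
        # 5 samples rushing out, fixation at 8 deg
        x = np.concatenate([
            np.zeros(50),
            np.arange(1, 6) * 0.1,            # 100 deg/s artefact
            np.full(25, np.nan),
            8.0 - np.arange(4, -1, -1) * 0.1,  # 100 deg/s artefact
            np.full(50, 8.0),
        ])
        valid = ~np.isnan(x)
        out = interpolate_blinks(_make_trace(x, valid=valid))
        assert out.valid.all()
        # the absorbed flanks were re-interpolated: the spline bridges 0 -> 8
        # smoothly instead of reproducing the 0.1-0.5 artefact ramp
        assert np.isclose(out.x[49], 0.0, atol=1e-9)   # last calm sample kept
        assert not np.allclose(out.x[50:55], np.arange(1, 6) * 0.1, atol=1e-3)
        assert np.isclose(out.x[85], 8.0, atol=1e-9)   # first calm sample kept

    def test_boundary_gap_dropped_with_shorter_trace(self):
        x = np.concatenate([np.full(10, np.nan), np.zeros(40)])
        valid = ~np.isnan(x)
        out = interpolate_blinks(_make_trace(x, valid=valid))
        assert len(out) == 40
        assert out.t[0] == 10


class TestSmoothing:
    def test_cubic_polynomial_reproduced(self):
        tt = np.arange(100) * 0.03
        x = 2 * tt**3 - tt**2 + 5
        out = smooth_trace(_make_trace(x, y=x[::-1].copy()))
        assert np.allclose(out.x[7:-7], x[7:-7], atol=1e-8)

    def test_constant_trace_unchanged(self):
        out = smooth_trace(_make_trace(np.full(50, 2.5)))
        assert np.allclose(out.x, 2.5, atol=1e-12)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(5)
        line = np.linspace(0, 5, 400)
        noisy = line + rng.normal(0, 0.2, 400)
        out = smooth_trace(_make_trace(noisy))
        assert np.var(out.x - line) < np.var(noisy - line)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            smooth_trace(_make_trace(np.zeros(10)))


class TestSpeed:
    def test_stationary_trace_zero_speed(self):
        assert np.allclose(compute_speed(_make_trace(np.full(20, 1.0))), 0.0)

    def test_constant_horizontal_velocity(self):
        x = np.arange(20) * 0.05
        assert np.allclose(compute_speed(_make_trace(x)), 50.0)

    def test_three_four_five_diagonal(self):
        x = np.arange(20) * 0.03
        y = np.arange(20) * 0.04
        assert np.allclose(compute_speed(_make_trace(x, y)), 50.0)


def _synthetic_saccade_trace(amplitude=8.0, duration=40, fix_ms=200):
    """Noiseless fixation-saccade-fixation trace built from the canonical
    speed profile, plus the onset index of the simulated saccade."""
    v = velocity_profile(amplitude, duration)
    disp = np.concatenate([[0.0], np.cumsum(v) / 1000.0])
    x = np.concatenate([np.full(fix_ms, -4.0), -4.0 + disp,
                        np.full(fix_ms, -4.0 + amplitude)])
    return _make_trace(x), fix_ms


class TestDetection:
    def test_stationary_trace_no_candidates(self):
        assert detect_saccades(_make_trace(np.zeros(300))) == []

    def test_single_saccade_found_near_true_onset(self):
        trace, onset = _synthetic_saccade_trace()
        cands = detect_saccades(smooth_trace(trace))
        assert len(cands) == 1
        assert abs(cands[0].onset_ms - onset) <= 3

    def test_short_burst_fails_sustain_requirement(self):
        # 6 ms at 50 deg/s: suprathreshold but shorter than the 10 ms sustain
        x = np.concatenate([np.zeros(100), np.cumsum(np.full(6, 0.05)),
                            np.full(100, 0.3)])
        assert detect_saccades(_make_trace(x)) == []


class TestFilters:
    def test_small_amplitude_rejected(self):
        trace, _ = _synthetic_saccade_trace(amplitude=0.8, duration=20)
        v = velocity_profile(0.8, 20, params=SimulatorParams(amp_min=0.5))
        disp = np.concatenate([[0.0], np.cumsum(v) / 1000.0])
        s = Saccade(trajectory=np.column_stack([disp, np.zeros_like(disp)]))
        assert filter_saccades([s]) == []

    def test_low_first_quartile_velocity_rejected(self):
        # slow creep (30 deg/s) for half the movement then a fast finish:
        # quartile speed is 0.1 x peak, the pursuit-like signature
        v = np.concatenate([np.full(20, 30.0), np.full(19, 300.0), [100.0]])
        disp = np.concatenate([[0.0], np.cumsum(v) / 1000.0])
        s = Saccade(trajectory=np.column_stack([disp, np.zeros_like(disp)]))
        assert s.amplitude_deg > 1 and s.duration_ms > 15
        assert filter_saccades([s]) == []

    def test_gaussian_profile_saccade_accepted(self):
        v = velocity_profile(8.0, 40)
        disp = np.concatenate([[0.0], np.cumsum(v) / 1000.0])
        s = Saccade(trajectory=np.column_stack([disp, np.zeros_like(disp)]))
        assert saccade_passes_filters(s)
        # the profile is Gaussian (possibly widened by the peak-velocity cap):
        # recover its width from two interior samples and check the
        # quartile-to-peak ratio against the closed form
        c = round(40 / 2)
        sigma = np.sqrt(-0.5 * (15 - c) ** 2 / np.log(v[15] / v[c]))
        q = v[round(40 / 4)] / v.max()
        assert q == pytest.approx(np.exp(-0.5 * ((10 - c) / sigma) ** 2), rel=1e-6)
        assert q > 0.15

    def test_high_initial_speed_rejected(self):
        # constant 200 deg/s from the first sample: no quiet onset
        disp = np.arange(41) * 0.2
        s = Saccade(trajectory=np.column_stack([disp, np.zeros_like(disp)]))
        assert not saccade_passes_filters(s)


class TestRestoreRaw:
    def test_identity_when_raw_equals_smoothed(self):
        trace, _ = _synthetic_saccade_trace()
        cands = detect_saccades(smooth_trace(trace))
        restored = restore_raw(cands, trace)
        # raw here IS the source trace; landing must match it exactly
        i1 = cands[0].onset_ms + cands[0].duration_ms
        assert restored[0].landing[0] == trace.x[i1]

    def test_constant_offset_shifts_landing_exactly(self):
        trace, _ = _synthetic_saccade_trace()
        smoothed = smooth_trace(trace)
        cands = detect_saccades(smoothed)
        raw = _make_trace(smoothed.x + 0.1, smoothed.y)
        restored = restore_raw(cands, raw)
        sm_landing = cands[0].landing[0]
        assert restored[0].landing[0] - sm_landing == pytest.approx(0.1, abs=1e-9)

    def test_index_mismatch_raises(self):
        trace, _ = _synthetic_saccade_trace()
        cands = detect_saccades(smooth_trace(trace))
        short_raw = _make_trace(trace.x[:50])
        with pytest.raises(RuntimeError):
            restore_raw(cands, short_raw)


@pytest.fixture(scope="module")
def noiseless_corpus():
    params = replace(SimulatorParams(), noise_sigma=0.0, amp_min=2.0,
                     amp_max=20.0, fixation_dur_range=(250.0, 400.0),
                     blink_rate=0.0)
    rng = np.random.default_rng(11)
    profile = sample_user_profile(params, rng, "u0")
    trace, truth = synth_session(500, profile, params, rng)
    return trace, truth


class TestEndToEnd:
    def test_recall_and_amplitude_error(self, noiseless_corpus):
        trace, truth = noiseless_corpus
        detected = run_detection(trace)
        det_onsets = np.array([s.onset_ms for s in truth])
        found = np.array([s.onset_ms for s in detected])
        matched, amp_err = 0, []
        for s in truth:
            j = int(np.argmin(np.abs(found - s.onset_ms)))
            if abs(found[j] - s.onset_ms) <= 10:
                matched += 1
                amp_err.append(abs(detected[j].amplitude_deg - s.amplitude_deg))
        assert matched / len(truth) >= 0.95
        assert np.median(amp_err) <= 0.5

    def test_no_temporal_overlap_and_filters_hold(self, noiseless_corpus):
        trace, _ = noiseless_corpus
        detected = run_detection(trace)
        spans = sorted((s.onset_ms, s.onset_ms + s.duration_ms) for s in detected)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 < b0
        for s in detected[:100]:
            assert 1.0 < s.amplitude_deg < 40.0
            assert s.duration_ms > 15

    def test_detection_survives_blinks(self):
        params = replace(SimulatorParams(), blink_rate=60.0)
        rng = np.random.default_rng(21)
        profile = sample_user_profile(params, rng, "u1")
        trace, truth = synth_session(40, profile, params, rng, with_blinks=True)
        assert not trace.valid.all()  # blinks actually injected
        detected = run_detection(trace)
        assert len(detected) >= 0.7 * len(truth)
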