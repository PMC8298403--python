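"""Filter contracts (pass-band fidelity, stop-band rejection, zero phase,
linearity) and contraction-segment extraction against simulator ground truth."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgesture import (
    FilterSpec,
    SimConfig,
    bandpass,
    extract_task_segments,
    notch,
    preprocess_signals,
    rectify_smooth,
    simulate_session,
)
from emgesture.preprocess import InputTooShortError, OnsetConfig

FS = 2000.0


def sine(freq, dur=4.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


def rms(x):
    return np.sqrt(np.mean(np.asarray(x) ** 2))


def interior(x, fs=FS, trim_s=0.5):
    n = int(trim_s * fs)
    return np.atleast_2d(x)[:, n:-n]


class TestBandpass:
    def test_dc_suppressed_below_one_percent(self):
        x = np.ones((1, 8000))
        y = bandpass(x, FS)
        assert np.abs(interior(y)).max() < 0.01

    @pytest.mark.parametrize("design", ["fir_hamming", "butterworth"])
    def test_100hz_preserved(self, design):
        spec = FilterSpec(bandpass_design=design)
        y = bandpass(sine(100.0), FS, spec)
        assert rms(interior(y)) == pytest.approx(rms(interior(sine(100.0))), rel=0.05)

    def test_500hz_rejected(self):
        y = bandpass(sine(500.0), FS)
        assert rms(interior(y)) < 0.10 * rms(sine(500.0))

    def test_too_short_input_raises(self):
        with pytest.raises(InputTooShortError):
            bandpass(np.zeros((1, 100)), FS)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((1, 8000)), FS, FilterSpec(bandpass_low_hz=500, bandpass_high_hz=400))


class TestNotch:
    def test_50hz_rejected_20db(self):
        y = notch(sine(50.0), FS)
        assert rms(interior(y)) < 0.1 * rms(sine(50.0))  # >= 20 dB

    def test_100hz_preserved(self):
        y = notch(sine(100.0), FS)
        assert rms(interior(y)) == pytest.approx(rms(interior(sine(100.0))), rel=0.05)

    def test_60hz_attenuation_below_3db(self):
        y = notch(sine(60.0), FS)
        assert rms(interior(y)) > 10 ** (-3 / 20) * rms(interior(sine(60.0)))

    def test_zero_in_zero_out(self):
        assert np.abs(notch(np.zeros((2, 8000)), FS)).max() == 0.0


@settings(max_examples=20, deadline=None, derandomize=True)
@given(
    a=st.floats(-5, 5, allow_nan=False),
    b=st.floats(-5, 5, allow_nan=False),
    seed=st.integers(0, 100),
)
def test_filters_are_linear(a, b, seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((1, 6000))
    y = rng.standard_normal((1, 6000))
    for f in (lambda s: bandpass(s, FS), lambda s: notch(s, FS)):
        lhs = f(a * x + b * y)
        rhs = a * f(x) + b * f(y)
        assert np.abs(lhs - rhs).max() < 1e-8 * max(1.0, abs(a) + abs(b))


@pytest.mark.parametrize("design", ["fir_hamming", "butterworth"])
def test_filters_are_zero_phase(design):
    """Cross-correlation peak between a band-limited input and its filtered
    output sits at zero lag."""
    rng = np.random.default_rng(1)
    x = rng.standard_normal(8000)
    x = bandpass(x, FS)[0]  # band-limit first so the comparison is in-band
    y = notch(bandpass(x, FS, FilterSpec(bandpass_design=design)), FS)[0]
    xc = np.correlate(interior(x)[0], interior(y)[0], mode="full")
    lag = int(np.argmax(xc)) - (len(interior(x)[0]) - 1)
    assert lag == 0


class TestRectifySmooth:
    def test_constant_maps_to_abs(self):
        env = rectify_smooth(np.full((1, 1000), -3.0), FS)
        assert np.allclose(env, 3.0)

    def test_sinusoid_envelope_is_two_over_pi(self):
        # 50 Hz carrier (40 samples/period), 0.5 s window >> period:
        # interior -> mean of |sin| = 2/pi
        env = rectify_smooth(sine(50.0, dur=2.0), FS, window_s=0.5)
        inner = env[0, 1500:-1500]
        assert np.allclose(inner, 2 / np.pi, atol=0.01)

    def test_window_shorter_than_sample_rejected(self):
        with pytest.raises(ValueError):
            rectify_smooth(np.zeros((1, 100)), 10.0, window_s=0.01)

    def test_output_shape_matches_input(self):
        x = np.random.default_rng(0).standard_normal((8, 5000))
        assert rectify_smooth(x, FS).shape == x.shape


@pytest.fixture(scope="module")
def zero_jitter_session():
    profiles = {
        kind: [
            type(p)(p.movement_code, p.spatial_gains, onset_jitter_sd_s=0.0)
            for p in SimConfig().profiles[kind]
        ]
        for kind in ("flexion", "extension")
    }
    cfg = SimConfig(n_participants=1, seed=5, profiles=profiles)
    return simulate_session(1, "flexion", cfg, seed=5)


class TestSegmentExtraction:
    def test_zero_jitter_segments_start_at_cue_plus_guard(self, zero_jitter_session):
        s = zero_jitter_session
        fs = s.sampling_rate_hz
        filt = preprocess_signals(s.signals, fs)
        cfg = OnsetConfig()
        segs = extract_task_segments(s, filt, cfg)
        task_trials = [t for t in s.trials if not t.is_control]
        for seg, tr in zip(segs, task_trials):
            expected_start = tr.cue_on_s + cfg.guard_s
            start_idx = None
            # locate the segment in the filtered signal by exact float match
            lo = max(0, int((tr.cue_on_s - 1.5) * fs))
            hi = int(tr.cue_off_s * fs)
            for cand in lo + np.nonzero(filt[0, lo:hi] == seg.data[0, 0])[0]:
                if np.array_equal(filt[:, cand : cand + 50], seg.data[:, :50]):
                    start_idx = int(cand)
                    break
            assert start_idx is not None
            # detection may fire up to ~envelope-window early; never late
            assert abs(start_idx / fs - expected_start) < 0.15

    def test_segment_count_and_length(self, small_session, small_session_filtered):
        segs = extract_task_segments(small_session, small_session_filtered)
        assert len(segs) == 30  # 6 task movements x 5 repetitions
        for seg in segs:
            assert seg.data.shape == (8, 6000)  # 3 s at 2 kHz

    def test_detected_onsets_track_ground_truth(self, small_session, small_session_filtered):
        """Detected onsets within 150 ms of the simulator's true onsets."""
        from emgesture.preprocess import detect_onset

        s = small_session
        fs = s.sampling_rate_hz
        cfg = OnsetConfig()
        env = rectify_smooth(small_session_filtered, fs, cfg.envelope_window_s).sum(axis=0)
        true = {(m, r): on for m, r, on, off in s.metadata["true_onsets"]}
        errors = []
        trials = s.trials
        for idx, tr in enumerate(trials):
            if tr.is_control:
                continue
            on = int(tr.cue_on_s * fs)
            off = int(tr.cue_off_s * fs)
            next_on = (
                int(trials[idx + 1].cue_on_s * fs) if idx + 1 < len(trials) else env.size
            )
            rest = env[off + 3000 : max(off + 3001, next_on - 3000)]
            onset = detect_onset(
                env, fs, (max(0, on - 2000), off), (rest.mean(), rest.std()), cfg
            )
            assert onset is not None
            errors.append(onset / fs - true[(tr.movement_code, tr.repetition_index)])
        errors = np.asarray(errors)
        assert np.quantile(np.abs(errors), 0.9) < 0.15

    def test_fallback_never_drops_repetitions(self, small_session):
        """Even with an unusable envelope threshold every repetition yields
        one segment (cue-anchored fallback)."""
        s = small_session
        filt = preprocess_signals(s.signals, s.sampling_rate_hz)
        cfg = OnsetConfig(threshold_sd=1e9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            segs = extract_task_segments(s, filt, cfg)
        assert len(segs) == 30

    def test_shape_mismatch_rejected(self, small_session):
        with pytest.raises(ValueError):
            extract_task_segments(small_session, small_session.signals[:, :100])
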