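"""Signal conditioning and contraction-segment extraction.

Raw forearm sEMG is band-pass filtered to the 10-380 Hz EMG band, power-line
interference is removed with a 49-51 Hz band-stop, and one 3 s segment per
movement repetition is extracted from the period where the contraction was
actually exerted.  Because reaction times shift the true contraction onset
relative to the audio cue, onsets are re-detected from the rectified,
smoothed envelope rather than taken from the cue annotations.

All filters are applied with zero phase so detected onsets and extracted
segments stay aligned with the raw recording.  The FIR band-pass is a
Hamming-windowed sinc whose symmetric impulse response is applied in a
single pass with exact group-delay compensation (linear phase => integer
delay); the IIR paths use forward-backward filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as sps

from .io import RecordingSession, TaskSegment


class InputTooShortError(ValueError):
    """Signal shorter than the filter can safely handle."""


@dataclass
class FilterSpec:
    """Band-pass + notch configuration.

    Defaults mirror a standard sEMG conditioning chain: 10-380 Hz pass band
    and a 4th-order Butterworth band-stop at 49-51 Hz for 50 Hz mains.  The
    FIR pass band uses 401 taps (0.2 s at 2 kHz), long enough to realise a
    10 Hz low edge with a Hamming window.
    """

    bandpass_low_hz: float = 10.0
    bandpass_high_hz: float = 380.0
    notch_band_hz: tuple[float, float] = (49.0, 51.0)
    notch_order: int = 4
    bandpass_design: Literal["fir_hamming", "butterworth"] = "fir_hamming"
    fir_order_taps: int = 401
    butter_order: int = 4

    def validate(self, fs: float) -> None:
        if not 0 < self.bandpass_low_hz < self.bandpass_high_hz < fs / 2:
            raise ValueError(
                f"band edges {self.bandpass_low_hz}-{self.bandpass_high_hz} Hz "
                f"invalid for fs={fs}"
            )
        lo, hi = self.notch_band_hz
        if not self.bandpass_low_hz <= lo < hi <= self.bandpass_high_hz:
            raise ValueError("notch band must lie inside the pass band")
        if self.fir_order_taps % 2 == 0:
            raise ValueError("fir_order_taps must be odd (symmetric linear phase)")


def _fir_taps(spec: FilterSpec, fs: float) -> np.ndarray:
    return sps.firwin(
        spec.fir_order_taps,
        [spec.bandpass_low_hz, spec.bandpass_high_hz],
        window="hamming",
        pass_zero=False,
        fs=fs,
    )


def _check_length(x: np.ndarray, flen: int, what: str) -> None:
    if x.shape[-1] < 3 * flen:
        raise InputTooShortError(
            f"{what}: signal of {x.shape[-1]} samples shorter than 3 x filter "
            f"length ({3 * flen})"
        )


def bandpass(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase 10-380 Hz band-pass; output has the input's shape."""
    spec = spec or FilterSpec()
    spec.validate(fs)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if spec.bandpass_design == "fir_hamming":
        taps = _fir_taps(spec, fs)
        _check_length(x, len(taps), "bandpass")
        delay = len(taps) // 2
        # symmetric FIR: one fft convolution + integer delay removal is
        # exactly zero-phase and much faster than filtfilt on long cohorts
        ext = np.pad(x, [(0, 0), (delay, delay)], mode="reflect")
        y = sps.fftconvolve(ext, taps[None, :], mode="same")[:, delay:-delay]
    else:
        sos = sps.butter(
            spec.butter_order,
            [spec.bandpass_low_hz, spec.bandpass_high_hz],
            btype="bandpass",
            fs=fs,
            output="sos",
        )
        _check_length(x, 3 * spec.butter_order, "bandpass")
        y = sps.sosfiltfilt(sos, x, axis=-1)
    return y


def notch(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-stop (49-51 Hz by default)."""
    spec = spec or FilterSpec()
    spec.validate(fs)
    x = np.atleast_2d(np.asarray(x, dtype=float))
    sos = sps.butter(
        spec.notch_order, spec.notch_band_hz, btype="bandstop", fs=fs, output="sos"
    )
    _check_length(x, 3 * spec.notch_order, "notch")
    return sps.sosfiltfilt(sos, x, axis=-1)


def preprocess_signals(
    x: np.ndarray, fs: float, spec: FilterSpec | None = None
) -> np.ndarray:
    """Band-pass then notch (both zero-phase, order immaterial for LTI)."""
    return notch(bandpass(x, fs, spec), fs, spec)


def rectify_smooth(x: np.ndarray, fs: float, window_s: float = 0.1) -> np.ndarray:
    """Envelope: moving average of ``|x|`` over a centred window.

    The 100 ms default window removes the EMG carrier while tracking
    activation bursts; edges use shrinking windows so the output keeps the
    input's length.
    """
    n_win = int(round(window_s * fs))
    if n_win < 1:
        raise ValueError(f"window_s={window_s} shorter than one sample at fs={fs}")
    x = np.atleast_2d(np.asarray(x, dtype=float))
    rect = np.abs(x)
    csum = np.cumsum(np.pad(rect, [(0, 0), (1, 0)]), axis=-1)
    n = rect.shape[-1]
    half_l = (n_win - 1) // 2
    half_r = n_win // 2
    starts = np.clip(np.arange(n) - half_l, 0, n)
    stops = np.clip(np.arange(n) + half_r + 1, 0, n)
    return (csum[:, stops] - csum[:, starts]) / (stops - starts)


@dataclass
class OnsetConfig:
    """Envelope-threshold contraction detection.

    Onset = first sample within ``[cue_on - pre_search_s, cue_off]`` where
    the cross-channel summed envelope stays above
    ``rest_mean + threshold_sd * rest_sd`` for at least ``sustain_s``; the
    feature segment starts ``guard_s`` after the onset.
    """

    threshold_sd: float = 3.0
    sustain_s: float = 0.2
    guard_s: float = 0.25
    pre_search_s: float = 1.0
    slack_s: float = 1.0
    envelope_window_s: float = 0.1


def detect_onset(
    envelope: np.ndarray,
    fs: float,
    search: tuple[int, int],
    rest_stats: tuple[float, float],
    config: OnsetConfig,
) -> int | None:
    """First sustained supra-threshold sample index, or ``None``."""
    lo, hi = search
    rest_mean, rest_sd = rest_stats
    thr = rest_mean + config.threshold_sd * rest_sd
    above = envelope[lo:hi] > thr
    n_sustain = max(1, int(round(config.sustain_s * fs)))
    if above.size < n_sustain:
        return None
    # run of >= n_sustain consecutive True values
    run = np.convolve(above.astype(int), np.ones(n_sustain, dtype=int), "valid")
    hits = np.nonzero(run == n_sustain)[0]
    return int(lo + hits[0]) if hits.size else None


def extract_task_segments(
    session: RecordingSession,
    filtered: np.ndarray,
    onset_config: OnsetConfig | None = None,
    segment_s: float = 3.0,
) -> list[TaskSegment]:
    """One 3 s contraction segment per non-control repetition.

    Never drops a repetition: if no sustained onset is found, or the
    detected onset leaves less than 3 s before ``cue_off + slack``, the
    segment falls back to the cue-anchored position with a warning.
    """
    cfg = onset_config or OnsetConfig()
    fs = session.sampling_rate_hz
    filtered = np.atleast_2d(np.asarray(filtered, dtype=float))
    if filtered.shape != session.signals.shape:
        raise ValueError(
            f"filtered shape {filtered.shape} != session shape {session.signals.shape}"
        )
    env = rectify_smooth(filtered, fs, cfg.envelope_window_s).sum(axis=0)
    n_total = filtered.shape[1]
    n_seg = int(round(segment_s * fs))
    n_guard = int(round(cfg.guard_s * fs))

    segments: list[TaskSegment] = []
    trials = session.trials
    for idx, tr in enumerate(trials):
        if tr.is_control:
            continue
        on = int(round(tr.cue_on_s * fs))
        off = int(round(tr.cue_off_s * fs))
        # rest baseline: the tail of this trial's rest phase, kept clear of
        # jitter-shifted contractions on BOTH sides (this trial's offset and
        # the next trial's early onset), falling back to the pre-cue second
        next_on = (
            int(round(trials[idx + 1].cue_on_s * fs)) if idx + 1 < len(trials) else n_total
        )
        rest_lo = min(off + int(round(1.5 * fs)), n_total - 1)
        rest_hi = max(rest_lo + 1, next_on - int(round(1.5 * fs)))
        rest = env[rest_lo:rest_hi]
        if rest.size < int(0.5 * fs):
            rest = env[max(0, on - int(fs)) : max(1, on)]
        rest_stats = (float(rest.mean()), float(rest.std()))

        lo = max(0, on - int(round(cfg.pre_search_s * fs)))
        onset = detect_onset(env, fs, (lo, off), rest_stats, cfg)
        start = None if onset is None else onset + n_guard
        latest = off + int(round(cfg.slack_s * fs)) - n_seg
        if start is None or start > latest or start + n_seg > n_total:
            warnings.warn(
                f"{tr.movement_code} rep {tr.repetition_index}: onset detection "
                "failed or left <3 s; falling back to cue-anchored segment",
                stacklevel=2,
            )
            start = min(on + n_guard, n_total - n_seg)
        segments.append(
            TaskSegment(
                participant_id=session.participant_id,
                movement_code=tr.movement_code,
                repetition_index=tr.repetition_index,
                sampling_rate_hz=fs,
                data=filtered[:, start : start + n_seg],
            )
        )
    return segments
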