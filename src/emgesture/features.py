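"""Time- and frequency-domain sEMG feature bank.

Eleven features per channel per 1 s analysis window: nine time-domain
(MAV, MAX, MIN, RANGE, RMS, VAR, STD, ZC, WFL) and two spectral (MNF, MDF)
computed from a Welch periodogram restricted to the 20-300 Hz EMG band.
A 3 s contraction segment yields three non-overlapping windows, so a
segment contributes three 88-dimensional feature vectors (11 features x 8
channels).

Definitions
-----------
MAV  = (1/N) sum |x_i|                       mean absolute value
RMS  = sqrt((1/N) sum x_i^2)
VAR  = (1/(N-1)) sum (x_i - mean)^2          sample variance; STD = sqrt(VAR)
ZC   = #{i : x_i * x_{i+1} < 0}              strict sign changes, no deadband
WFL  = sum |x_{i+1} - x_i|                   waveform length
MNF  = sum f_i PSD_i / sum PSD_i             spectral centroid
MDF  = smallest f where cumulative PSD reaches half the total power
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import (
    FEATURE_COLUMNS,
    FEATURE_NAMES_11,
    LABEL_COLUMNS,
    N_CHANNELS,
    FeatureMatrix,
    TaskSegment,
)

TIME_FEATURES = ("MAV", "MAX", "MIN", "RANGE", "RMS", "VAR", "STD", "ZC", "WFL")


class UndefinedSpectrumError(ValueError):
    """PSD carries no power: spectral features are undefined."""


@dataclass
class WindowSpec:
    """Feature-window and PSD-estimation configuration.

    ``fft_length`` of 2048 with a 1 s window at 2 kHz gives a bin spacing
    of 2000/2048 ~ 0.9766 Hz.  ``psd_band_hz`` restricts MNF/MDF to the
    surface-EMG energy band.
    """

    window_s: float = 1.0
    overlap: float = 0.0
    psd_window_s: float = 1.0
    psd_overlap: float = 0.5
    fft_length: int = 2048
    psd_band_hz: tuple[float, float] = (20.0, 300.0)
    snr_band_hz: tuple[float, float] = (15.0, 250.0)

    def validate(self, fs: float) -> None:
        n_win = self.window_s * fs
        if abs(n_win - round(n_win)) > 1e-9:
            raise ValueError(f"window_s x fs must be integral, got {n_win}")
        if self.fft_length < round(self.psd_window_s * fs):
            raise ValueError("fft_length must be >= PSD window length")


def time_features(window: np.ndarray) -> dict[str, float]:
    """Nine time-domain features of one single-channel window."""
    x = np.asarray(window, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"need >= 2 samples, got {x.size}")
    diffs = np.diff(x)
    return {
        "MAV": float(np.mean(np.abs(x))),
        "MAX": float(np.max(x)),
        "MIN": float(np.min(x)),
        "RANGE": float(np.max(x) - np.min(x)),
        "RMS": float(np.sqrt(np.mean(x**2))),
        "VAR": float(np.var(x, ddof=1)),
        "STD": float(np.std(x, ddof=1)),
        "ZC": float(np.count_nonzero(x[:-1] * x[1:] < 0)),
        "WFL": float(np.sum(np.abs(diffs))),
    }


def welch_psd(
    window: np.ndarray,
    fs: float,
    spec: WindowSpec | None = None,
    band: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD (Hamming taper, 50% overlap, zero-padded FFT), band-clipped.

    Returns ``(frequencies, psd)`` restricted to ``band`` (default the
    spec's 20-300 Hz EMG band).
    """
    spec = spec or WindowSpec()
    spec.validate(fs)
    x = np.asarray(window, dtype=float).ravel()
    nperseg = int(round(spec.psd_window_s * fs))
    if x.size < nperseg:
        raise ValueError(
            f"window of {x.size} samples shorter than PSD window ({nperseg})"
        )
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=int(round(spec.psd_overlap * nperseg)),
        nfft=spec.fft_length,
        detrend=False,
    )
    lo, hi = band if band is not None else spec.psd_band_hz
    keep = (freqs >= lo) & (freqs <= hi)
    return freqs[keep], psd[keep]


def freq_features(frequencies: np.ndarray, psd: np.ndarray) -> tuple[float, float]:
    """Mean frequency (spectral centroid) and median frequency of a PSD."""
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(psd, dtype=float)
    if np.any(p < 0):
        raise ValueError("PSD must be non-negative")
    total = p.sum()
    if total <= 0:
        raise UndefinedSpectrumError("all-zero PSD: MNF/MDF undefined")
    mnf = float(np.sum(f * p) / total)
    # MDF: smallest bin where the cumulative spectrum first reaches half the
    # total power (discrete-bin convention for the equal-power split)
    cum = np.cumsum(p)
    mdf = float(f[np.searchsorted(cum, total / 2.0)])
    return mnf, mdf


def band_power(
    frequencies: np.ndarray,
    psd: np.ndarray,
    band: tuple[float, float] = (15.0, 250.0),
) -> float:
    """Trapezoidal integral of the PSD over ``band`` (average signal power)."""
    f = np.asarray(frequencies, dtype=float)
    p = np.asarray(psd, dtype=float)
    lo, hi = band
    keep = (f >= lo) & (f <= hi)
    if keep.sum() < 2:
        raise ValueError(f"band {band} Hz has <2 bins within {f[0]:g}-{f[-1]:g} Hz")
    return float(np.trapezoid(p[keep], f[keep]))


def snr(task_power: float, rest_power: float) -> float:
    """Signal-to-noise ratio ``10 log10((P_signal - P_noise)/P_noise)`` in dB.

    Returns ``-inf`` with a warning when the task power does not exceed the
    rest (noise) power.
    """
    if rest_power <= 0:
        raise ValueError(f"rest power must be positive, got {rest_power}")
    if task_power <= rest_power:
        warnings.warn(
            "task power <= rest power: SNR undefined, returning -inf", stacklevel=2
        )
        return float("-inf")
    return float(10.0 * np.log10((task_power - rest_power) / rest_power))


def build_feature_matrix(
    segments: list[TaskSegment], spec: WindowSpec | None = None
) -> FeatureMatrix:
    """11 features x 8 channels per 1 s window; 3 windows per 3 s segment.

    Rows are ordered by (participant, movement, repetition, window).
    Windows whose spectrum carries no power (degenerate all-zero data) are
    rejected with a warning rather than emitting NaNs.
    """
    spec = spec or WindowSpec()
    rows: list[dict] = []
    for seg in segments:
        fs = seg.sampling_rate_hz
        spec.validate(fs)
        n_win = int(round(spec.window_s * fs))
        n_windows = seg.data.shape[1] // n_win
        if n_windows != 3:
            raise ValueError(
                f"segment must hold exactly 3 windows of {spec.window_s} s, "
                f"got {n_windows}"
            )
        for w in range(3):
            sl = seg.data[:, w * n_win : (w + 1) * n_win]
            row: dict = {
                "participant_id": seg.participant_id,
                "movement_code": seg.movement_code,
                "repetition_index": seg.repetition_index,
                "window_index": w + 1,
            }
            try:
                for ch in range(N_CHANNELS):
                    tf = time_features(sl[ch])
                    freqs, psd = welch_psd(sl[ch], fs, spec)
                    mnf, mdf = freq_features(freqs, psd)
                    for name in TIME_FEATURES:
                        row[f"{name}_ch{ch + 1}"] = tf[name]
                    row[f"MNF_ch{ch + 1}"] = mnf
                    row[f"MDF_ch{ch + 1}"] = mdf
            except UndefinedSpectrumError:
                warnings.warn(
                    f"{seg.movement_code} rep {seg.repetition_index} window "
                    f"{w + 1}: zero spectrum, row rejected",
                    stacklevel=2,
                )
                continue
            rows.append(row)
    df = pd.DataFrame(rows, columns=list(LABEL_COLUMNS) + list(FEATURE_COLUMNS))
    df = df.sort_values(list(LABEL_COLUMNS), kind="stable").reset_index(drop=True)
    return FeatureMatrix(df)


def segment_snr(
    session_signals: np.ndarray,
    fs: float,
    task_interval: tuple[float, float],
    rest_interval: tuple[float, float],
    spec: WindowSpec | None = None,
) -> float:
    """Per-repetition SNR from 15-250 Hz band power of task vs rest."""
    spec = spec or WindowSpec()
    x = np.atleast_2d(session_signals)

    def _power(interval: tuple[float, float]) -> float:
        lo, hi = (int(round(t * fs)) for t in interval)
        chunk = x[:, lo:hi]
        powers = []
        for ch in range(chunk.shape[0]):
            f, p = welch_psd(chunk[ch], fs, spec, band=(0.0, fs / 2))
            powers.append(band_power(f, p, spec.snr_band_hz))
        return float(np.mean(powers))

    return snr(_power(task_interval), _power(rest_interval))
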