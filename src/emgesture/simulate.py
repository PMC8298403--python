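"""Synthetic multi-channel sEMG cohort generator.

Emulates a cued finger-movement protocol: participants wear an 8-channel
bipolar electrode matrix on the forearm and perform 6 individual finger
movements plus 2 control hand movements, 5 repetitions each, 5 s task /
5 s rest, in two sessions (flexion and extension).  The generator provides
ground truth for every downstream stage: movement-specific spatial
activation patterns, between-participant amplitude spread, cue-to-
contraction jitter, and the standard nuisance components of surface EMG
(broadband noise floor, 50 Hz power-line interference, low-frequency
drift).

Signal model
------------
Surface EMG is modelled as zero-mean Gaussian noise spectrally shaped to
the 20-300 Hz band (band-pass-filtered white noise — the standard
phenomenological surrogate for interference EMG).  During a contraction,
channel ``c`` is amplitude-modulated by ``spatial_gain[c] x
participant_gain x amplitude_mv``; a raised-cosine ramp (100 ms) smooths
the on/off transitions.  On top of the modulated EMG sit an EMG-band noise
floor, a common-phase 50 Hz sinusoid, and per-channel low-frequency drift.

Each 10 s trial block starts with 1 s of rest, then the cue at t = 1 s;
the actual contraction onset is the cue time plus a Gaussian reaction-time
jitter, and annotations deliberately carry only the *nominal* cue times,
so segment extraction must re-detect onsets just as with real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import RecordingSession, TrialAnnotation

CONTROL_CODES = (7, 8)
THUMB_CODES = (5, 6)


class SimulationError(RuntimeError):
    """Drawn trial parameters cannot be realised (e.g. jitter too large)."""


@dataclass
class MovementProfile:
    """Movement-specific relative channel activation amplitudes."""

    movement_code: str
    spatial_gains: np.ndarray  # 8 non-negative reals, max-normalised to 1
    onset_jitter_sd_s: float = 0.3

    def __post_init__(self) -> None:
        g = np.asarray(self.spatial_gains, dtype=float)
        if g.shape != (8,) or np.any(g < 0):
            raise ValueError("spatial_gains must be 8 non-negative reals")
        if g.max() > 0:
            g = g / g.max()
        self.spatial_gains = g
        if self.onset_jitter_sd_s < 0:
            raise ValueError("onset_jitter_sd_s must be non-negative")


def default_profiles(session_kind: str = "flexion") -> list[MovementProfile]:
    """Six finger-movement profiles plus two control hand movements.

    Task profiles are smooth unimodal gain bumps centred on distinct
    channels so each movement has a distinguishable spatial fingerprint;
    the two thumb movements (codes 5 and 6) share heavily overlapping
    profiles, so their spatial patterns are nearly rank-identical.  Control
    hand movements activate all channels broadly.
    """
    prefix = "F" if session_kind == "flexion" else "E"
    channels = np.arange(8, dtype=float)
    centers = {1: 0.0, 2: 1.6, 3: 3.2, 4: 4.8, 5: 6.9, 6: 7.3}
    width = 1.1
    profiles = []
    for code, c in centers.items():
        gains = np.exp(-((channels - c) ** 2) / (2 * width**2))
        # floor + per-channel tilt keeps all 8 channels at distinct,
        # noise-robust gain levels (no rank ties from a flat tail)
        gains = gains + 0.15 + 0.2 * channels / 8
        profiles.append(MovementProfile(f"{prefix}{code}", gains))
    for code in CONTROL_CODES:
        gains = 0.7 + 0.3 * np.cos(channels / 3 + code)
        profiles.append(MovementProfile(f"{prefix}{code}", gains))
    return profiles


@dataclass
class SimConfig:
    """Cohort-level simulation settings (defaults mirror the study protocol)."""

    n_participants: int = 12
    n_repetitions: int = 5
    task_duration_s: float = 5.0
    rest_duration_s: float = 5.0
    pre_rest_s: float = 1.0  # rest carved out before the cue in each block
    sampling_rate_hz: float = 2000.0
    emg_band_hz: tuple[float, float] = (20.0, 300.0)
    amplitude_mv: float = 1.0  # contraction EMG RMS at gain 1
    noise_floor_mv: float = 0.3  # broadband noise RMS (task SNR ~ 10 dB)
    powerline_amp_mv: float = 0.2  # 50 Hz sinusoid amplitude
    drift_amp_mv: float = 0.15  # low-frequency artifact RMS
    participant_gain_sd: float = 0.2  # LogNormal sigma of per-subject gain
    seed: int = 0
    profiles: dict[str, list[MovementProfile]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.task_duration_s, self.rest_duration_s, self.sampling_rate_hz) <= 0:
            raise ValueError("durations and sampling rate must be positive")
        lo, hi = self.emg_band_hz
        if not 0 < lo < hi < self.sampling_rate_hz / 2:
            raise ValueError(f"emg_band {self.emg_band_hz} outside (0, fs/2)")
        if not 0 <= self.pre_rest_s < self.rest_duration_s:
            raise ValueError("pre_rest_s must be within the rest duration")
        if not self.profiles:
            self.profiles = {
                kind: default_profiles(kind) for kind in ("flexion", "extension")
            }

    @property
    def trial_duration_s(self) -> float:
        return self.task_duration_s + self.rest_duration_s

    def session_profiles(self, session_kind: str) -> list[MovementProfile]:
        profs = self.profiles[session_kind]
        n_task = sum(
            1 for p in profs if int(p.movement_code[1:]) not in CONTROL_CODES
        )
        n_ctrl = len(profs) - n_task
        if (n_task, n_ctrl) != (6, 2):
            raise ValueError(
                f"{session_kind} needs 6 task + 2 control profiles, "
                f"got {n_task} + {n_ctrl}"
            )
        return profs


def _shaped_noise(rng: np.random.Generator, shape, fs, band) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` Hz."""
    white = rng.standard_normal(shape)
    taps = sps.firwin(201, band, window="hamming", pass_zero=False, fs=fs)
    out = sps.fftconvolve(white, taps[None, :], mode="same")
    rms = np.sqrt(np.mean(out**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return out / rms


def _drift(rng: np.random.Generator, shape, fs) -> np.ndarray:
    """Unit-RMS low-frequency (<10 Hz) artifact."""
    white = rng.standard_normal(shape)
    sos = sps.butter(2, 10.0, btype="lowpass", fs=fs, output="sos")
    out = sps.sosfilt(sos, white, axis=-1)
    rms = np.sqrt(np.mean(out**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return out / rms


def simulate_trial(
    profile: MovementProfile,
    config: SimConfig,
    participant_gain: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, tuple[float, float]]:
    """One 10 s trial block; returns the signal and the realised contraction.

    The cue falls at ``pre_rest_s`` into the block; the contraction starts
    at cue + jitter and lasts ``task_duration_s``.  The returned interval is
    the ground-truth (onset_s, offset_s) relative to block start.
    """
    fs = config.sampling_rate_hz
    n = int(round(config.trial_duration_s * fs))
    cue_on = config.pre_rest_s
    # reaction-time jitter: Gaussian truncated at +-3 sigma (a draw beyond
    # that is not a plausible reaction time and would let rare tail draws
    # push the contraction out of its trial block)
    sd = profile.onset_jitter_sd_s
    jitter = float(np.clip(rng.normal(0.0, sd), -3.0 * sd, 3.0 * sd))
    onset = cue_on + jitter
    offset = onset + config.task_duration_s
    if onset < 0 or offset > config.trial_duration_s:
        raise SimulationError(
            f"contraction [{onset:.2f}, {offset:.2f}] s outside the "
            f"{config.trial_duration_s:g} s trial window (jitter {jitter:.2f} s; "
            "onset_jitter_sd_s too large for the trial layout)"
        )

    t = np.arange(n) / fs
    # contraction envelope with 100 ms raised-cosine ramps
    ramp = 0.1
    env = np.clip((t - onset) / ramp, 0, 1) * np.clip((offset - t) / ramp, 0, 1)
    env = 0.5 - 0.5 * np.cos(np.pi * np.clip(env, 0, 1))

    gains = profile.spatial_gains * participant_gain * config.amplitude_mv
    emg = _shaped_noise(rng, (8, n), fs, config.emg_band_hz)
    x = emg * (gains[:, None] * env[None, :])
    if config.noise_floor_mv > 0:
        x += config.noise_floor_mv * _shaped_noise(rng, (8, n), fs, config.emg_band_hz)
    if config.powerline_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x += config.powerline_amp_mv * np.sin(2 * np.pi * 50.0 * t + phase)[None, :]
    if config.drift_amp_mv > 0:
        x += config.drift_amp_mv * _drift(rng, (8, n), fs)
    return x, (onset, offset)


def simulate_session(
    participant_id: int,
    session_kind: str,
    config: SimConfig,
    seed: int | np.random.SeedSequence | None = None,
    participant_gain: float | None = None,
) -> RecordingSession:
    """One session: 8 movements x 5 repetitions of 10 s trial blocks.

    Annotations carry the *nominal* cue times; the ground-truth contraction
    intervals are stored in ``metadata['true_onsets']`` for validation.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    if participant_gain is None:
        participant_gain = 1.0
    profs = config.session_profiles(session_kind)
    fs = config.sampling_rate_hz
    n_trial = int(round(config.trial_duration_s * fs))

    blocks, trials, true_onsets = [], [], []
    t0 = 0.0
    for prof in profs:
        code_num = int(prof.movement_code[1:])
        for rep in range(1, config.n_repetitions + 1):
            sig, (on, off) = simulate_trial(prof, config, participant_gain, rng)
            blocks.append(sig)
            trials.append(
                TrialAnnotation(
                    movement_code=prof.movement_code,
                    repetition_index=rep,
                    cue_on_s=t0 + config.pre_rest_s,
                    cue_off_s=t0 + config.pre_rest_s + config.task_duration_s,
                    is_control=code_num in CONTROL_CODES,
                )
            )
            true_onsets.append((prof.movement_code, rep, t0 + on, t0 + off))
            t0 += n_trial / fs
    return RecordingSession(
        participant_id=participant_id,
        session_kind=session_kind,  # type: ignore[arg-type]
        sampling_rate_hz=fs,
        signals=np.concatenate(blocks, axis=1),
        trials=trials,
        metadata={"true_onsets": true_onsets, "participant_gain": participant_gain},
    )


def participant_gains(config: SimConfig) -> np.ndarray:
    """Per-participant amplitude multipliers, LogNormal(0, participant_gain_sd)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    return np.exp(rng.normal(0.0, config.participant_gain_sd, config.n_participants))


def iter_cohort(
    config: SimConfig, session_kinds: tuple[str, ...] = ("flexion", "extension")
):
    """Yield cohort sessions one at a time (memory-friendly for pipelines).

    Each participant's amplitude multiplier is drawn once and reused across
    their sessions; everything is deterministic given ``config.seed``.
    """
    gains = participant_gains(config)
    for pid in range(1, config.n_participants + 1):
        for k_idx, kind in enumerate(session_kinds):
            ss = np.random.SeedSequence([int(config.seed), pid, k_idx])
            yield simulate_session(
                pid, kind, config, seed=ss, participant_gain=gains[pid - 1]
            )


def simulate_cohort(
    config: SimConfig, session_kinds: tuple[str, ...] = ("flexion", "extension")
) -> list[RecordingSession]:
    """Full cohort as a list; see :func:`iter_cohort` for streaming."""
    return list(iter_cohort(config, session_kinds))


def low_noise_config(config: SimConfig | None = None, factor: float = 0.1) -> SimConfig:
    """A copy of ``config`` with all nuisance amplitudes scaled by ``factor``."""
    cfg = config or SimConfig()
    return replace(
        cfg,
        noise_floor_mv=cfg.noise_floor_mv * factor,
        powerline_amp_mv=cfg.powerline_amp_mv * factor,
        drift_amp_mv=cfg.drift_amp_mv * factor,
        profiles=cfg.profiles,
    )
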