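"""Core data containers and session/feature-matrix I/O.

The analysis operates on multi-channel surface-EMG recordings organised as
sessions: one participant wearing an 8-bipolar-channel electrode matrix over
either the forearm flexor or extensor muscles, performing cued finger
movements in repetitions.  This module houses the in-memory containers that
every other stage consumes and their serialisation to EDF(+) and delimited
text.

Conventions
-----------
* Signals are stored in millivolts, channels x samples, float64.
* Time is seconds from recording start; sample indices are 0-based;
  intervals are half-open ``[on, off)``.
* Movement codes are ``F1``..``F8`` (flexion session) or ``E1``..``E8``
  (extension session); codes 7 and 8 are the two control hand movements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import _edf

N_CHANNELS = 8

#: canonical feature order: feature-major, channel-minor (``RMS_ch1..RMS_ch8``
#: are contiguous), 11 features x 8 channels = 88 columns.
FEATURE_NAMES_11 = (
    "MAV", "MAX", "MIN", "RANGE", "RMS", "VAR", "STD", "ZC", "WFL", "MNF", "MDF",
)
FEATURE_COLUMNS = tuple(
    f"{feat}_ch{ch}" for feat in FEATURE_NAMES_11 for ch in range(1, N_CHANNELS + 1)
)
LABEL_COLUMNS = ("participant_id", "movement_code", "repetition_index", "window_index")

_MOVEMENT_RE = re.compile(r"^[FE][1-8]$")


class FormatError(ValueError):
    """File content does not match the expected on-disk layout."""


class AnnotationError(ValueError):
    """Trial annotations are missing, ill-ordered, or out of range."""


@dataclass
class TrialAnnotation:
    """One cued movement repetition.

    ``cue_on_s``/``cue_off_s`` are the *nominal* audio-cue times; the actual
    contraction may be shifted by the participant's reaction time, which is
    why segment extraction re-detects the onset.
    """

    movement_code: str
    repetition_index: int
    cue_on_s: float
    cue_off_s: float
    is_control: bool = False

    def __post_init__(self) -> None:
        if not _MOVEMENT_RE.match(self.movement_code):
            raise AnnotationError(
                f"movement code {self.movement_code!r} is not F1..F8 / E1..E8"
            )
        if not 1 <= int(self.repetition_index) <= 5:
            raise AnnotationError(
                f"repetition_index {self.repetition_index} outside 1..5"
            )
        if not self.cue_off_s > self.cue_on_s:
            raise AnnotationError(
                f"cue_off_s ({self.cue_off_s}) must exceed cue_on_s ({self.cue_on_s})"
            )


@dataclass
class RecordingSession:
    """One participant x one session kind: raw signal plus trial annotations."""

    participant_id: int
    session_kind: Literal["flexion", "extension"]
    sampling_rate_hz: float
    signals: np.ndarray  # (8, n_samples) millivolts
    trials: list[TrialAnnotation]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def validate(self) -> None:
        if self.session_kind not in ("flexion", "extension"):
            raise ValueError(f"unknown session_kind {self.session_kind!r}")
        if self.sampling_rate_hz <= 0:
            raise FormatError(
                f"sampling rate must be positive, got {self.sampling_rate_hz}"
            )
        if self.signals.ndim != 2 or self.signals.shape[0] != N_CHANNELS:
            n = self.signals.shape[0] if self.signals.ndim == 2 else self.signals.ndim
            raise FormatError(f"expected {N_CHANNELS} channels, got {n}")
        dur = self.duration_s
        last_off = -np.inf
        for tr in self.trials:
            if not (0 <= tr.cue_on_s < dur):
                raise AnnotationError(
                    f"cue_on_s {tr.cue_on_s} outside recording [0, {dur:g})"
                )
            if tr.cue_on_s < last_off:
                raise AnnotationError("trial annotations overlap or are unordered")
            last_off = tr.cue_off_s

    def task_trials(self) -> list[TrialAnnotation]:
        """The six individual finger movements (controls excluded)."""
        return [t for t in self.trials if not t.is_control]


@dataclass
class TaskSegment:
    """One 3 s contraction extract: the unit of feature extraction."""

    participant_id: int
    movement_code: str
    repetition_index: int
    sampling_rate_hz: float
    data: np.ndarray  # (8, round(3 s * fs))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise FormatError(f"segment must be {N_CHANNELS} x n, got {self.data.shape}")
        expected = round(3.0 * self.sampling_rate_hz)
        if abs(self.data.shape[1] - expected) > 1:
            raise ValueError(
                f"segment duration must be 3 s ({expected} samples at "
                f"{self.sampling_rate_hz} Hz), got {self.data.shape[1]}"
            )


class FeatureMatrix:
    """Stacked 88-dimensional feature vectors with full label provenance.

    Thin wrapper over a :class:`pandas.DataFrame` whose columns are the four
    label columns followed by the 88 feature columns (11 features x 8
    channels, feature-major order).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in (*LABEL_COLUMNS, *FEATURE_COLUMNS) if c not in df.columns]
        if missing:
            raise FormatError(f"feature matrix missing columns: {missing[:5]} ...")
        extra = [c for c in df.columns if c not in (*LABEL_COLUMNS, *FEATURE_COLUMNS)]
        if extra:
            raise FormatError(f"unexpected feature-matrix columns: {extra[:5]}")
        df = df[list(LABEL_COLUMNS) + list(FEATURE_COLUMNS)].reset_index(drop=True)
        if len(df) and df[list(FEATURE_COLUMNS)].isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if len(df) and not df["window_index"].isin([1, 2, 3]).all():
            raise ValueError("window_index must be in {1, 2, 3}")
        self.df = df

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:  # label equality + numeric closeness
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return self.df.equals(other.df)

    @property
    def values(self) -> np.ndarray:
        return self.df[list(FEATURE_COLUMNS)].to_numpy(dtype=float)

    @property
    def labels(self) -> pd.DataFrame:
        return self.df[list(LABEL_COLUMNS)]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return FEATURE_COLUMNS

    def select(self, **conditions) -> "FeatureMatrix":
        """Rows matching every ``column=value`` (or ``column=list``) condition."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in conditions.items():
            vals = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
            mask &= self.df[col].isin(list(vals))
        return FeatureMatrix(self.df[mask])


# ---------------------------------------------------------------------------
# session I/O
# ---------------------------------------------------------------------------

def _annotation_frame(trials: list[TrialAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "movement_code": [t.movement_code for t in trials],
            "repetition": [t.repetition_index for t in trials],
            "cue_on_s": [t.cue_on_s for t in trials],
            "cue_off_s": [t.cue_off_s for t in trials],
            "is_control": [int(t.is_control) for t in trials],
        }
    )


def _trials_from_frame(df: pd.DataFrame) -> list[TrialAnnotation]:
    required = {"movement_code", "repetition", "cue_on_s", "cue_off_s", "is_control"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"annotation table missing columns {sorted(required - set(df.columns))}"
        )
    return [
        TrialAnnotation(
            movement_code=str(r.movement_code),
            repetition_index=int(r.repetition),
            cue_on_s=float(r.cue_on_s),
            cue_off_s=float(r.cue_off_s),
            is_control=bool(int(r.is_control)),
        )
        for r in df.itertuples(index=False)
    ]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + "_annotations.csv")


def write_session(
    session: RecordingSession,
    path: str | Path,
    format: Literal["edf", "delimited"] = "edf",
) -> Path:
    """Serialise a session; returns the written signal-file path.

    EDF output carries cue annotations on an ``EDF Annotations`` channel
    (description ``"<code> rep <k>[ ctrl]"``); delimited output is one sample
    per row, one column per channel, with a sidecar annotation CSV.
    """
    session.validate()
    path = Path(path)
    if format == "edf":
        descs = [
            (t.cue_on_s, t.cue_off_s - t.cue_on_s,
             f"{t.movement_code} rep {t.repetition_index}" + (" ctrl" if t.is_control else ""))
            for t in session.trials
        ]
        _edf.write_edf(
            path,
            session.signals,
            session.sampling_rate_hz,
            annotations=descs,
            physical_dim="mV",
            recording_id=f"participant={session.participant_id} kind={session.session_kind}",
        )
    elif format == "delimited":
        sig = pd.DataFrame(
            session.signals.T, columns=[f"ch{i}" for i in range(1, N_CHANNELS + 1)]
        )
        with open(path, "w", newline="") as fh:
            fh.write(
                f"# participant_id={session.participant_id} "
                f"session_kind={session.session_kind} "
                f"sampling_rate_hz={session.sampling_rate_hz:.6g}\n"
            )
            sig.to_csv(fh, index=False, float_format="%.9g")
        _annotation_frame(session.trials).to_csv(_sidecar_path(path), index=False)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


_EDF_DESC_RE = re.compile(r"^([FE][1-8]) rep ([1-5])( ctrl)?$")


def read_session(
    path: str | Path, format: Literal["edf", "delimited"] = "edf"
) -> RecordingSession:
    """Read a session written by :func:`write_session` (or compatible files)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        signals, fs, annots, rec_id = _edf.read_edf(path)
        if signals.shape[0] != N_CHANNELS:
            raise FormatError(
                f"expected {N_CHANNELS} signal channels, got {signals.shape[0]}"
            )
        trials = []
        for onset, duration, desc in annots:
            m = _EDF_DESC_RE.match(desc)
            if not m:
                raise AnnotationError(f"unparseable trial annotation {desc!r}")
            trials.append(
                TrialAnnotation(
                    movement_code=m.group(1),
                    repetition_index=int(m.group(2)),
                    cue_on_s=onset,
                    cue_off_s=onset + duration,
                    is_control=m.group(3) is not None,
                )
            )
        meta = dict(re.findall(r"(\w+)=(\S+)", rec_id or ""))
        participant = int(meta.get("participant_id", meta.get("participant", 0)))
        kind = meta.get("kind", meta.get("session_kind", "flexion"))
    elif format == "delimited":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise FormatError("delimited session must start with a '#' header line")
            meta = dict(re.findall(r"(\w+)=(\S+)", first))
            sig = pd.read_csv(fh)
        if sig.shape[1] != N_CHANNELS:
            raise FormatError(
                f"expected {N_CHANNELS} signal columns, got {sig.shape[1]}"
            )
        signals = sig.to_numpy(dtype=float).T
        fs = float(meta["sampling_rate_hz"])
        participant = int(meta.get("participant_id", 0))
        kind = meta.get("session_kind", "flexion")
        side = _sidecar_path(path)
        if not side.exists():
            raise AnnotationError(f"missing annotation sidecar {side}")
        trials = _trials_from_frame(pd.read_csv(side))
    else:
        raise ValueError(f"unknown format {format!r}")
    return RecordingSession(
        participant_id=participant,
        session_kind=kind,  # type: ignore[arg-type]
        sampling_rate_hz=fs,
        signals=signals,
        trials=trials,
    )


# ---------------------------------------------------------------------------
# feature-matrix I/O
# ---------------------------------------------------------------------------

def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    fm.df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    n_feat = len([c for c in df.columns if c not in LABEL_COLUMNS])
    if n_feat != len(FEATURE_COLUMNS):
        raise FormatError(
            f"expected {len(FEATURE_COLUMNS)} feature columns, found {n_feat}"
        )
    if df.empty:
        df = df.astype(
            {"participant_id": int, "repetition_index": int, "window_index": int},
            errors="ignore",
        )
    return FeatureMatrix(df)
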