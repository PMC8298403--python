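"""Minimal EDF+ (European Data Format) reader/writer.

Implements the subset of EDF+C needed for continuous multi-channel
recordings with cue annotations: ASCII fixed-width headers, int16
little-endian data records, and one ``EDF Annotations`` signal carrying
time-stamped annotation lists (TALs).  Signals are scaled per channel from
their physical range onto the full 16-bit digital range, so round-trip
error is bounded by ``(phys_max - phys_min) / 65535``.

The true sample count is stored in the reserved header field
(``EDF+C NS=<n>``) so that a last record padded to a whole number of
record durations can be trimmed on read; third-party readers ignore the
extra token.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numeric fields rather than truncating digits blindly
        if isinstance(value, float):
            s = f"{value:.{max(width - 8, 1)}g}"
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _num(field: bytes) -> float:
    return float(field.decode("ascii").strip() or "nan")


def write_edf(
    path: str | Path,
    signals: np.ndarray,
    fs: float,
    annotations: list[tuple[float, float, str]] | None = None,
    physical_dim: str = "mV",
    recording_id: str = "",
    patient_id: str = "X X X X",
) -> Path:
    """Write ``signals`` (channels x samples, physical units) as EDF+C."""
    path = Path(path)
    signals = np.asarray(signals, dtype=float)
    n_ch, n_samples = signals.shape
    record_dur = 1.0
    spr = int(round(fs * record_dur))  # samples per record per channel
    if spr != fs * record_dur:
        raise ValueError(f"sampling rate {fs} must yield integer samples per 1 s record")
    n_records = max(1, math.ceil(n_samples / spr))

    # per-channel physical range -> full digital range
    pmins = signals.min(axis=1) if n_samples else np.zeros(n_ch)
    pmaxs = signals.max(axis=1) if n_samples else np.ones(n_ch)
    flat = pmaxs - pmins <= 0
    pmaxs[flat] = pmins[flat] + 1.0
    scale = (_DIG_MAX - _DIG_MIN) / (pmaxs - pmins)

    # annotation signal: TALs for record time-keeping plus all cue TALs in
    # record 0 (cohort annotation payloads are small)
    tals: list[bytes] = []
    for rec in range(n_records):
        tal = f"+{rec * record_dur:g}\x14\x14\x00".encode("ascii")
        if rec == 0 and annotations:
            for onset, duration, desc in annotations:
                tal += (
                    f"+{onset:.6g}\x15{duration:.6g}\x14{desc}\x14\x00".encode("ascii")
                )
        tals.append(tal)
    ann_bytes = max(len(t) for t in tals)
    ann_spr = math.ceil(ann_bytes / 2)

    ns = n_ch + 1
    header_bytes = 256 * (1 + ns)
    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii(patient_id, 80))
        fh.write(_ascii(recording_id, 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(header_bytes, 8))
        fh.write(_ascii(f"EDF+C NS={n_samples}", 44))
        fh.write(_ascii(n_records, 8))
        fh.write(_ascii(f"{record_dur:g}", 8))
        fh.write(_ascii(ns, 4))

        labels = [f"EMG ch{i + 1}" for i in range(n_ch)] + ["EDF Annotations"]
        for lab in labels:
            fh.write(_ascii(lab, 16))
        for _ in range(ns):
            fh.write(_ascii("", 80))  # transducer
        for i in range(ns):
            fh.write(_ascii(physical_dim if i < n_ch else "", 8))
        for i in range(ns):
            fh.write(_ascii(f"{pmins[i]:.6g}" if i < n_ch else -1, 8))
        for i in range(ns):
            fh.write(_ascii(f"{pmaxs[i]:.6g}" if i < n_ch else 1, 8))
        for _ in range(ns):
            fh.write(_ascii(_DIG_MIN, 8))
        for _ in range(ns):
            fh.write(_ascii(_DIG_MAX, 8))
        for _ in range(ns):
            fh.write(_ascii("", 80))  # prefiltering
        for i in range(ns):
            fh.write(_ascii(spr if i < n_ch else ann_spr, 8))
        for _ in range(ns):
            fh.write(_ascii("", 32))

        # header phys min/max were formatted with %.6g: recompute the scale
        # the reader will see so the round-trip error stays at quantisation
        # level rather than header-rounding level
        pmins_h = np.array([float(f"{v:.6g}") for v in pmins])
        pmaxs_h = np.array([float(f"{v:.6g}") for v in pmaxs])
        scale = (_DIG_MAX - _DIG_MIN) / (pmaxs_h - pmins_h)

        padded = np.zeros((n_ch, n_records * spr))
        padded[:, :n_samples] = signals
        padded[:, n_samples:] = pmins_h[:, None]  # pad decodes to phys min
        dig = np.rint((padded - pmins_h[:, None]) * scale[:, None] + _DIG_MIN)
        dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

        for rec in range(n_records):
            fh.write(dig[:, rec * spr : (rec + 1) * spr].tobytes())
            tal = tals[rec]
            fh.write(tal + b"\x00" * (2 * ann_spr - len(tal)))
    return path


def _parse_tals(raw: bytes) -> list[tuple[float, float, str]]:
    out = []
    for tal in raw.split(b"\x00"):
        if not tal:
            continue
        parts = tal.split(b"\x14")
        head = parts[0].decode("ascii", errors="replace")
        if "\x15" in head:
            onset_s, dur_s = head.split("\x15")
            onset, dur = float(onset_s), float(dur_s)
        else:
            onset, dur = float(head), 0.0
        for desc in parts[1:]:
            if desc:
                out.append((onset, dur, desc.decode("utf-8", errors="replace")))
    return out


def read_edf(path: str | Path):
    """Read an EDF/EDF+C file.

    Returns ``(signals, fs, annotations, recording_id)`` with signals in
    physical units (channels x samples) and annotations as
    ``(onset_s, duration_s, description)`` tuples.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        recording_id = hdr[88:168].decode("ascii", errors="replace").strip()
        reserved = hdr[192:236].decode("ascii", errors="replace")
        n_records = int(_num(hdr[236:244]))
        record_dur = _num(hdr[244:252])
        ns = int(_num(hdr[252:256]))

        sig_hdr = fh.read(256 * ns)
        fields = {}
        off = 0
        for name, width in [
            ("label", 16), ("transducer", 80), ("dim", 8), ("pmin", 8),
            ("pmax", 8), ("dmin", 8), ("dmax", 8), ("prefilter", 80),
            ("spr", 8), ("reserved", 32),
        ]:
            fields[name] = [
                sig_hdr[off + i * width : off + (i + 1) * width] for i in range(ns)
            ]
            off += ns * width

        labels = [f.decode("ascii", errors="replace").strip() for f in fields["label"]]
        sprs = [int(_num(f)) for f in fields["spr"]]
        pmins = [_num(f) for f in fields["pmin"]]
        pmaxs = [_num(f) for f in fields["pmax"]]
        dmins = [_num(f) for f in fields["dmin"]]
        dmaxs = [_num(f) for f in fields["dmax"]]

        ann_idx = [i for i, lab in enumerate(labels) if lab == "EDF Annotations"]
        data_idx = [i for i in range(ns) if i not in ann_idx]

        rec_len = sum(sprs)
        raw = np.frombuffer(fh.read(2 * rec_len * n_records), dtype="<i2")
        if raw.size < rec_len * n_records:
            raise ValueError(f"{path}: truncated EDF data section")
        raw = raw.reshape(n_records, rec_len)

    offsets = np.cumsum([0] + sprs)
    signals = []
    for i in data_idx:
        dig = raw[:, offsets[i] : offsets[i + 1]].reshape(-1).astype(float)
        gain = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        signals.append(pmins[i] + (dig - dmins[i]) * gain)
    signals = np.vstack(signals) if signals else np.empty((0, 0))

    annotations: list[tuple[float, float, str]] = []
    for i in ann_idx:
        ann_raw = raw[:, offsets[i] : offsets[i + 1]].astype("<i2").tobytes()
        annotations.extend(
            (o, d, desc) for o, d, desc in _parse_tals(ann_raw) if desc
        )

    m = [tok for tok in reserved.split() if tok.startswith("NS=")]
    if m:
        n_true = int(m[0][3:])
        signals = signals[:, :n_true]

    fs = sprs[data_idx[0]] / record_dur if data_idx else 0.0
    annotations.sort(key=lambda t: t[0])
    return signals, fs, annotations, recording_id
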