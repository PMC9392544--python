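"""Minimal EDF (European Data Format) writer and reader.

Implements just enough of the EDF standard for round-tripping continuous
multichannel recordings: an ASCII header (256 bytes + 256 per signal) and
little-endian int16 data records. Physical values are microvolts; each data
record spans one second, so recordings must contain an integer number of
seconds. Signals are scaled channel-wise to the full 16-bit digital range,
so quantization error is bounded by one digital step.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .recording import EEGRecording, MontageSpec

__all__ = ["write_edf", "read_edf", "quantization_step"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        # shorten numerics to fit the fixed-width ASCII field
        if isinstance(value, float):
            s = f"{value:.{max(width - 8, 1)}e}"
        s = s[:width]
    return s.ljust(width).encode("ascii")


def quantization_step(phys_min: float, phys_max: float) -> float:
    """Physical value of one digital unit for a channel's scaling."""
    return (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)


def write_edf(recording: EEGRecording, path) -> None:
    """Write a recording to an EDF file.

    The recording is truncated to a whole number of 1-second data records.
    Per-channel physical ranges are set symmetrically to the observed
    absolute maximum (rounded up), which fixes the quantization step at
    ``2 * ceil(max|x|) / 65535`` microvolts.
    """
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    fs = int(round(fs))
    n_records = recording.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = recording.data[:, : n_records * fs]
    nc = recording.n_channels

    phys_max = np.ceil(np.maximum(np.abs(data).max(axis=1), 1.0))
    phys_min = -phys_max
    scale = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    start = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header = b"".join([
        _field(0, 8),
        _field(f"{recording.subject_id or 'X'} sex=X", 80),
        _field(f"session={recording.session} condition={recording.condition}", 80),
        _field(start.strftime("%d.%m.%y"), 8),
        _field(start.strftime("%H.%M.%S"), 8),
        _field(256 * (nc + 1), 8),
        _field("", 44),
        _field(n_records, 8),
        _field(1, 8),
        _field(nc, 4),
    ])
    labels = recording.montage.channel_names
    header += b"".join(_field(f"EEG {c}", 16) for c in labels)
    header += b"".join(_field("AgAgCl electrode", 80) for _ in labels)
    header += b"".join(_field("uV", 8) for _ in labels)
    header += b"".join(_field(int(v), 8) for v in phys_min)
    header += b"".join(_field(int(v), 8) for v in phys_max)
    header += b"".join(_field(_DIG_MIN, 8) for _ in labels)
    header += b"".join(_field(_DIG_MAX, 8) for _ in labels)
    header += b"".join(_field("", 80) for _ in labels)
    header += b"".join(_field(fs, 8) for _ in labels)
    header += b"".join(_field("", 32) for _ in labels)

    # data records: one second each, signals concatenated within a record
    records = digital.reshape(nc, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(records).tobytes())


def read_edf(path) -> EEGRecording:
    """Read an EDF file written by :func:`write_edf` back into a recording."""
    raw = Path(path).read_bytes()
    n_records = int(raw[236:244].decode("ascii"))
    nc = int(raw[252:256].decode("ascii"))
    off = 256

    def fields(width: int) -> list[str]:
        nonlocal off
        out = [raw[off + i * width: off + (i + 1) * width].decode("ascii").strip()
               for i in range(nc)]
        off += nc * width
        return out

    labels = [lab.removeprefix("EEG ") for lab in fields(16)]
    fields(80)  # transducer
    fields(8)   # physical dimension
    phys_min = np.array([float(v) for v in fields(8)])
    phys_max = np.array([float(v) for v in fields(8)])
    dig_min = np.array([float(v) for v in fields(8)])
    dig_max = np.array([float(v) for v in fields(8)])
    fields(80)  # prefiltering
    spr = [int(v) for v in fields(8)]
    fields(32)
    fs = spr[0]

    sidecar = raw[88:168].decode("ascii")
    session = "post" if "session=post" in sidecar else "pre"
    condition = "eyes_open" if "condition=eyes_open" in sidecar else "eyes_closed"
    subject_id = raw[8:88].decode("ascii").split()[0]

    body = np.frombuffer(raw[256 * (nc + 1):], dtype="<i2")
    body = body[: n_records * nc * fs].reshape(n_records, nc, fs)
    digital = body.transpose(1, 0, 2).reshape(nc, n_records * fs).astype(np.float64)
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * scale[:, None] + phys_min[:, None]

    return EEGRecording(
        data=data, sampling_rate=float(fs),
        montage=MontageSpec(channel_names=tuple(labels)),
        subject_id="" if subject_id == "X" else subject_id,
        session=session, condition=condition,
    )
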