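"""Minimal EDF (European Data Format) reader/writer.

Supports the plain continuous-EDF subset needed for fixtures and data
exchange: a fixed 256-byte header, one 256-byte header block per signal and
little-endian 16-bit data records.  Signals are quantised to the 16-bit
digital range over their physical min/max, which is the format's native
precision.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .recording import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width and isinstance(value, float):
        # keep as many significant digits as fit the fixed-width field
        for digits in range(width, 0, -1):
            text = f"{value:.{digits}g}"
            if len(text) <= width:
                break
    return text[:width].ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a single-record EDF file."""
    path = Path(path)
    n_sig = rec.n_channels
    n_samp = rec.n_samples

    phys_min = rec.samples.min(axis=1)
    phys_max = rec.samples.max(axis=1)
    # constant channels get a unit range so the gain is well defined
    flat = phys_max - phys_min <= 0
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    # the header stores these in 8 ASCII chars; quantise against the stored
    # (rounded) values so writer and reader agree exactly
    phys_min = np.array([float(_field(float(v), 8)) for v in phys_min])
    phys_max = np.array([float(_field(float(v), 8)) for v in phys_max])
    phys_max = np.where(phys_max - phys_min <= 0, phys_min + 1.0, phys_max)

    gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((rec.samples - phys_min[:, None]) / gain[:, None]
                       + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    record_duration = n_samp / rec.fs
    header = b"".join([
        _field(0, 8),                          # version
        _field(rec.subject_id or "X", 80),     # patient id
        _field(rec.meta.get("recording_id", "X"), 80),
        _field("01.01.00", 8),                 # start date
        _field("00.00.00", 8),                 # start time
        _field(256 * (1 + n_sig), 8),          # header bytes
        _field("", 44),                        # reserved
        _field(1, 8),                          # number of data records
        _field(record_duration, 8),
        _field(n_sig, 4),
    ])
    sig_headers = b"".join([
        b"".join(_field(lab, 16) for lab in rec.channel_labels),
        b"".join(_field("EEG", 80) for _ in range(n_sig)),       # transducer
        b"".join(_field("uV", 8) for _ in range(n_sig)),         # dimension
        b"".join(_field(float(v), 8) for v in phys_min),
        b"".join(_field(float(v), 8) for v in phys_max),
        b"".join(_field(_DIG_MIN, 8) for _ in range(n_sig)),
        b"".join(_field(_DIG_MAX, 8) for _ in range(n_sig)),
        b"".join(_field("", 80) for _ in range(n_sig)),          # prefilter
        b"".join(_field(n_samp, 8) for _ in range(n_sig)),
        b"".join(_field("", 32) for _ in range(n_sig)),          # reserved
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_headers)
        fh.write(digital.tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read a continuous EDF file into a :class:`Recording`."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < 256:
        raise OSError(f"{path}: truncated or empty EDF file")

    def ascii_at(offset: int, width: int) -> str:
        return raw[offset:offset + width].decode("ascii", "replace").strip()

    try:
        n_records = int(ascii_at(236, 8))
        record_duration = float(ascii_at(244, 8))
        n_sig = int(ascii_at(252, 4))
    except ValueError as exc:
        raise OSError(f"{path}: malformed EDF header") from exc
    if n_sig < 1:
        raise OSError(f"{path}: no signals")

    base = 256

    def sig_fields(block: int, width: int) -> list[str]:
        start = base + block
        return [raw[start + i * width:start + (i + 1) * width]
                .decode("ascii", "replace").strip() for i in range(n_sig)]

    labels = sig_fields(0, 16)
    if any(not lab for lab in labels):
        raise ValueError(f"{path}: missing channel labels")
    off = n_sig * 16 + n_sig * 80 + n_sig * 8
    phys_min = np.array([float(v) for v in sig_fields(off, 8)])
    phys_max = np.array([float(v) for v in sig_fields(off + n_sig * 8, 8)])
    dig_min = np.array([float(v) for v in sig_fields(off + n_sig * 16, 8)])
    dig_max = np.array([float(v) for v in sig_fields(off + n_sig * 24, 8)])
    # prefilter text (80 bytes/signal) sits between dig_max and the
    # samples-per-record counts
    n_per_rec = np.array(
        [int(v) for v in sig_fields(off + n_sig * 32 + n_sig * 80, 8)]
    )

    data_start = 256 * (1 + n_sig)
    rec_len = int(n_per_rec.sum())
    body = np.frombuffer(raw, dtype="<i2", offset=data_start)
    if n_records < 0:  # unknown count: infer from file size
        n_records = body.size // rec_len
    if body.size < n_records * rec_len:
        raise OSError(f"{path}: data shorter than header declares")

    chans = [[] for _ in range(n_sig)]
    pos = 0
    for _ in range(n_records):
        for i in range(n_sig):
            chans[i].append(body[pos:pos + n_per_rec[i]])
            pos += n_per_rec[i]
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    samples = np.stack([
        np.concatenate(chans[i]) * gain[i] + (phys_min[i] - dig_min[i] * gain[i])
        for i in range(n_sig)
    ])
    fs = n_per_rec[0] / record_duration
    return Recording(samples=samples, fs=fs, channel_labels=labels,
                     subject_id=ascii_at(8, 80))
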