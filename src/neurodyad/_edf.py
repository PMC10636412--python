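"""Minimal EDF (European Data Format) 16-bit reader/writer.

Supports the subset this package produces: equal sampling rate on all
signals, one-second data records, little-endian int16 samples scaled by
per-signal physical min/max.  The true sample count is stashed in the
header's reserved field (``nsamples=N``) so round-trips preserve length
even when the last record is zero-padded; other EDF readers simply see
the padding.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # numeric fields: retry with tighter formatting
        if isinstance(value, float):
            s = np.format_float_positional(value, precision=width - 2, unique=False).rstrip(".")
        if len(s) > width:
            raise ValueError(f"field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    data: np.ndarray,
    sample_rate: float,
    labels: list[str],
    physical_dim: str = "uV",
    recording_id: str = "",
) -> None:
    data = np.asarray(data, dtype=np.float64)
    n_channels, n_samples = data.shape
    spr = int(round(sample_rate))  # samples per 1-s record
    if abs(spr - sample_rate) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate (1-s records)")
    n_records = int(np.ceil(n_samples / spr)) if n_samples else 0

    phys_min = np.floor(data.min(axis=1)) if n_samples else np.zeros(n_channels)
    phys_max = np.ceil(data.max(axis=1)) if n_samples else np.ones(n_channels)
    # avoid zero span on flat channels
    span = phys_max - phys_min
    phys_max = np.where(span == 0, phys_min + 1, phys_max)

    header_bytes = 256 + 256 * n_channels
    with open(path, "wb") as fh:
        fh.write(_field(0, 8))
        fh.write(_field("X", 80))
        fh.write(_field(f"{recording_id} nsamples={n_samples}".strip(), 80))
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(header_bytes, 8))
        fh.write(_field("", 44))
        fh.write(_field(n_records, 8))
        fh.write(_field(1, 8))
        fh.write(_field(n_channels, 4))
        for lab in labels:
            fh.write(_field(lab, 16))
        for _ in labels:
            fh.write(_field("", 80))
        for _ in labels:
            fh.write(_field(physical_dim, 8))
        for v in phys_min:
            fh.write(_field(v, 8))
        for v in phys_max:
            fh.write(_field(v, 8))
        for _ in labels:
            fh.write(_field(_DIG_MIN, 8))
        for _ in labels:
            fh.write(_field(_DIG_MAX, 8))
        for _ in labels:
            fh.write(_field("", 80))
        for _ in labels:
            fh.write(_field(spr, 8))
        for _ in labels:
            fh.write(_field("", 32))

        gain = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
        padded = np.zeros((n_channels, n_records * spr))
        padded[:, :n_samples] = data
        digital = np.rint(
            (padded - phys_min[:, None]) / gain[:, None] + _DIG_MIN
        ).clip(_DIG_MIN, _DIG_MAX).astype("<i2")
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path):
    """Return (data uV-unscaled, sample_rate, labels, physical_dims, recording_id)."""
    raw = Path(path).read_bytes()

    def ascii_at(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii").strip()

    recording_id = ascii_at(88, 80)
    n_records = int(ascii_at(236, 8))
    record_dur = float(ascii_at(244, 8))
    n_channels = int(ascii_at(252, 4))

    labels = _signal_block(raw, n_channels, 0, 16)
    dims = _signal_block(raw, n_channels, 96, 8)
    phys_min = np.array([float(v) for v in _signal_block(raw, n_channels, 104, 8)])
    phys_max = np.array([float(v) for v in _signal_block(raw, n_channels, 112, 8)])
    dig_min = np.array([float(v) for v in _signal_block(raw, n_channels, 120, 8)])
    dig_max = np.array([float(v) for v in _signal_block(raw, n_channels, 128, 8)])
    spr = np.array([int(v) for v in _signal_block(raw, n_channels, 216, 8)])
    if len(set(spr)) > 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    spr0 = int(spr[0])
    sample_rate = spr0 / record_dur

    header_bytes = 256 + 256 * n_channels
    digital = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    data = digital.reshape(n_records, n_channels, spr0).transpose(1, 0, 2).reshape(n_channels, -1)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    physical = (data.astype(np.float64) - dig_min[:, None]) * gain[:, None] + phys_min[:, None]

    for token in recording_id.split():
        if token.startswith("nsamples="):
            physical = physical[:, : int(token[9:])]
    return physical, sample_rate, labels, dims, recording_id


def _signal_block(raw: bytes, n_channels: int, block_offset: int, width: int) -> list[str]:
    # block_offset is the cumulative byte offset of this field block per the
    # EDF header layout (16,80,8,8,8,8,8,80,8,32 bytes per signal, grouped)
    base = 256 + block_offset * n_channels
    return [
        raw[base + i * width : base + (i + 1) * width].decode("ascii").strip()
        for i in range(n_channels)
    ]
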