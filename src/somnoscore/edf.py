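"""Minimal EDF writer for uniform-rate multichannel signals in uV.

Writes plain EDF (fixed-width ASCII header, little-endian int16 data
records).  Enough of the format for round-tripping simulator output
through standard readers; continuous recordings only, no annotations.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    signals: np.ndarray | Sequence[np.ndarray],
    rate: float,
    channel_labels: Sequence[str],
    physical_range_uv: tuple[float, float] = (-1000.0, 1000.0),
    record_duration_s: float = 1.0,
    patient_id: str = "X",
    recording_id: str = "synthetic PSG",
) -> None:
    """Write (n_channels, n_samples) uV signals as 16-bit EDF.

    Samples outside ``physical_range_uv`` are saturated at the range
    limits; quantisation error is one digital step,
    ``(phys_max - phys_min) / 65535``.
    """
    x = np.asarray(signals, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("signals must be (n_channels, n_samples)")
    nch, nsamp = x.shape
    if len(channel_labels) != nch:
        raise ValueError("one label per channel required")
    spr = rate * record_duration_s
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("rate * record_duration must be an integer sample count")
    spr = int(round(spr))
    if nsamp % spr != 0:
        raise ValueError(
            f"signal length {nsamp} is not a whole number of {record_duration_s}s records"
        )
    n_records = nsamp // spr
    pmin, pmax = physical_range_uv
    if not pmax > pmin:
        raise ValueError("physical range must be increasing")

    gain = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    dig = np.round((np.clip(x, pmin, pmax) - pmin) / gain).astype(np.int64) + _DIG_MIN
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    header_bytes = 256 * (1 + nch)
    head = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(header_bytes, 8),
            _field("", 44),
            _field(n_records, 8),
            _field(_fmt_num(record_duration_s), 8),
            _field(nch, 4),
        ]
    )
    sig_head = b"".join(
        [
            b"".join(_field(lbl, 16) for lbl in channel_labels),
            b"".join(_field("", 80) for _ in range(nch)),
            b"".join(_field("uV", 8) for _ in range(nch)),
            b"".join(_field(_fmt_num(pmin), 8) for _ in range(nch)),
            b"".join(_field(_fmt_num(pmax), 8) for _ in range(nch)),
            b"".join(_field(_DIG_MIN, 8) for _ in range(nch)),
            b"".join(_field(_DIG_MAX, 8) for _ in range(nch)),
            b"".join(_field("", 80) for _ in range(nch)),
            b"".join(_field(spr, 8) for _ in range(nch)),
            b"".join(_field("", 32) for _ in range(nch)),
        ]
    )

    records = dig.reshape(nch, n_records, spr).transpose(1, 0, 2)
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig_head)
        fh.write(records.tobytes())


def quantization_step_uv(physical_range_uv: tuple[float, float] = (-1000.0, 1000.0)) -> float:
    pmin, pmax = physical_range_uv
    return (pmax - pmin) / (_DIG_MAX - _DIG_MIN)


def _fmt_num(v: float) -> str:
    s = f"{v:.8g}"
    if len(s) > 8:
        s = f"{v:.6g}"
    return s.rstrip(".") if s.endswith(".") else s
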