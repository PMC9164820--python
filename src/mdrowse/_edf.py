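"""Minimal EDF (European Data Format) writer.

Writes plain 16-bit EDF with one signal per channel, physical dimension
microvolts, and either 1-second data records (when the sampling rate is an
integer and the length is a whole number of seconds) or a single data record
covering the whole signal. Reading is left to MNE, which parses EDF natively;
this module exists only because no installed package exports EDF.
"""

from __future__ import annotations

import datetime
from pathlib import Path

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ascii chars")
    return s.ljust(width).encode("ascii")


def _fit8(v: float, direction: int) -> str:
    """Format ``v`` in <= 8 ascii chars, rounded outward in ``direction`` (+-1)."""
    eps = max(abs(v), 1.0) * 1e-7
    for _ in range(25):
        w = v + direction * eps
        for p in range(8, 0, -1):
            s = f"{w:.{p}g}"
            if len(s) <= 8:
                break
        f = float(s)
        if (direction < 0 and f <= v) or (direction > 0 and f >= v):
            return s
        eps *= 10.0
    raise ValueError(f"cannot represent {v} in 8 chars")


def quantization_step(phys_min: float, phys_max: float) -> float:
    """Amplitude resolution of a 16-bit EDF signal with the given physical range."""
    return (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)


def write_edf(
    path: str | Path,
    data_uv: np.ndarray,
    rate: float,
    labels: list[str],
    *,
    patient_id: str = "X",
    recording_id: str = "synthetic",
) -> None:
    """Write ``data_uv`` (channels x samples, microvolts) as a 16-bit EDF file.

    The physical range of each signal is its own [min, max], so the round-trip
    error is at most one quantization step per sample.
    """
    data = np.asarray(data_uv, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be channels x samples")
    n_ch, n_samp = data.shape
    if len(labels) != n_ch:
        raise ValueError("label count must match channel count")

    rate_i = int(round(rate))
    if abs(rate - rate_i) < 1e-9 and n_samp % rate_i == 0:
        spr = rate_i                       # samples per record
        n_rec = n_samp // rate_i
        rec_dur = "1"
    else:
        spr = n_samp
        n_rec = 1
        rec_dur = f"{n_samp / rate:.6g}"
        if len(rec_dur) > 8:
            raise ValueError("record duration does not fit the EDF header")

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin = np.where(flat, pmin - 0.5, pmin)
    pmax = np.where(flat, pmax + 0.5, pmax)
    # The header stores min/max as <=8 ascii chars; round outward to a value
    # that fits and scale with the *stored* values so readers agree exactly.
    pmin_s = [_fit8(v, -1) for v in pmin]
    pmax_s = [_fit8(v, +1) for v in pmax]
    pmin = np.array([float(s) for s in pmin_s])
    pmax = np.array([float(s) for s in pmax_s])

    gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.rint((data - pmin[:, None]) * gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    now = datetime.datetime(2000, 1, 1)
    header_bytes = 256 + 256 * n_ch
    parts = [
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(header_bytes), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field(rec_dur, 8),
        _field(str(n_ch), 4),
    ]
    for lab in labels:
        parts.append(_field(lab, 16))
    for _ in labels:
        parts.append(_field("", 80))                      # transducer
    for _ in labels:
        parts.append(_field("uV", 8))                     # physical dimension
    for s in pmin_s:
        parts.append(_field(s, 8))
    for s in pmax_s:
        parts.append(_field(s, 8))
    parts.append(_field(str(_DIG_MIN), 8) * n_ch)
    parts.append(_field(str(_DIG_MAX), 8) * n_ch)
    for _ in labels:
        parts.append(_field("", 80))                      # prefiltering
    parts.append(_field(str(spr), 8) * n_ch)
    parts.append(_field("", 32) * n_ch)

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        for r in range(n_rec):
            chunk = digital[:, r * spr:(r + 1) * spr]     # one record: signals in sequence
            fh.write(chunk.tobytes())


def read_physical_dimensions(path: str | Path) -> list[str]:
    """Return the per-signal physical-dimension strings from an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_ch = int(head[252:256].decode("ascii").strip())
        fh.seek(256 + n_ch * (16 + 80))
        dims = fh.read(n_ch * 8).decode("ascii", errors="replace")
    return [dims[i * 8:(i + 1) * 8].strip() for i in range(n_ch)]


def read_physical_range(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Return (physical_min, physical_max) arrays from an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_ch = int(head[252:256].decode("ascii").strip())
        fh.seek(256 + n_ch * (16 + 80 + 8))
        raw = fh.read(n_ch * 16).decode("ascii")
    pmin = np.array([float(raw[i * 8:(i + 1) * 8]) for i in range(n_ch)])
    pmax = np.array([float(raw[n_ch * 8 + i * 8:n_ch * 8 + (i + 1) * 8]) for i in range(n_ch)])
    return pmin, pmax
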