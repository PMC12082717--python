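"""Minimal EDF (European Data Format) 16-bit writer and header reader.

Reading full records goes through MNE elsewhere in the package; this module
only (a) serializes recordings to spec-conformant EDF so synthetic data can
round-trip through the same clinical container, and (b) peeks at the signal
header table to recover per-channel physical maxima (the transducer ceiling
used by the noisy-record rule), which high-level readers do not expose.

EDF layout: a 256-byte ASCII main header, 256 ASCII bytes per signal of
channel metadata, then data records of little-endian int16 samples scaled
linearly between the digital and physical ranges.  One data record per
second is written, the common clinical convention.
"""
from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .errors import FormatError, ParameterError
from .recording import Recording

_DIG_MAX = 32767
_DIG_MIN = -32768


def _ascii(value, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        raise ParameterError(f"EDF header field {text!r} exceeds {width} ascii bytes")
    return text.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int = 8) -> str:
    """Format a float into EDF's fixed-width ascii numeric fields."""
    for fmt in (f"{x:.6g}", f"{x:.4g}", f"{x:.3g}", f"{x:.2g}"):
        if len(fmt) <= width:
            return fmt
    raise ParameterError(f"cannot format {x} in {width} chars")


def write_edf(path: str | Path, rec: Recording, *, patient_id: str | None = None,
              recording_id: str | None = None,
              start: _dt.datetime | None = None) -> None:
    """Write a :class:`Recording` to ``path`` as 16-bit EDF.

    The sampling rate must be a whole number of samples per second (records
    are one second long); trailing samples short of a full second are
    dropped.  Per-channel physical ranges are symmetric at the channel's
    transducer maximum so the noisy-record rule survives a round trip.
    """
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ParameterError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1 s record
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ParameterError("recording shorter than one EDF data record (1 s)")
    start = start or _dt.datetime(2000, 1, 1, 0, 0, 0)
    ns = rec.n_channels

    phys_max = np.maximum(rec.transducer_max, 1.0)
    phys_min = -phys_max

    header = b"".join([
        _ascii("0", 8),
        _ascii(patient_id or rec.meta.get("patient_id", "X"), 80),
        _ascii(recording_id or rec.meta.get("record_id", "X"), 80),
        _ascii(start.strftime("%d.%m.%y"), 8),
        _ascii(start.strftime("%H.%M.%S"), 8),
        _ascii(256 * (ns + 1), 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii("1", 8),
        _ascii(ns, 4),
    ])

    def field(values, width):
        return b"".join(_ascii(v, width) for v in values)

    header += field(rec.channel_labels, 16)
    header += field(["synthetic" if rec.meta.get("synthetic") else "AgAgCl"] * ns, 80)
    header += field(["uV"] * ns, 8)
    header += field([_fmt_float(v) for v in phys_min], 8)
    header += field([_fmt_float(v) for v in phys_max], 8)
    header += field([_DIG_MIN] * ns, 8)
    header += field([_DIG_MAX] * ns, 8)
    header += field(["HP:0.5Hz LP:75Hz" if rec.meta.get("filtered") else ""] * ns, 80)
    header += field([spr] * ns, 8)
    header += field([""] * ns, 32)

    # physical -> digital, clipping out-of-range samples at the rails
    pmin = np.array([float(_fmt_float(v)) for v in phys_min])[:, None]
    pmax = np.array([float(_fmt_float(v)) for v in phys_max])[:, None]
    gain = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    dig = np.rint((rec.signal[:, : n_rec * spr] - pmin) * gain + _DIG_MIN)
    dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")

    # interleave: per record, all samples of signal 0, then signal 1, ...
    blocks = dig.reshape(ns, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(blocks).tobytes())


def peek_header(path: str | Path) -> dict:
    """Parse the EDF header table without loading any signal data.

    Returns a dict with ``labels``, ``physical_max``, ``physical_min``,
    ``sampling_rate`` (per channel), ``n_records`` and ``record_duration_s``.
    """
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            main = fh.read(256)
            if len(main) < 256:
                raise FormatError(f"{path}: truncated EDF main header")
            try:
                n_rec = int(main[236:244].decode("ascii").strip())
                rec_dur = float(main[244:252].decode("ascii").strip())
                ns = int(main[252:256].decode("ascii").strip())
            except (UnicodeDecodeError, ValueError) as exc:
                raise FormatError(f"{path}: malformed EDF main header") from exc
            table = fh.read(256 * ns)
    except OSError as exc:
        raise FormatError(f"{path}: cannot read EDF header ({exc})") from exc
    if len(table) < 256 * ns or ns <= 0:
        raise FormatError(f"{path}: truncated EDF signal header table")

    def column(offset, width):
        start = offset * ns
        return [table[start + i * width: start + (i + 1) * width].decode(
            "ascii", "replace").strip() for i in range(ns)]

    labels = column(0, 16)
    try:
        phys_min = [float(v) for v in column(16 + 80 + 8, 8)]
        phys_max = [float(v) for v in column(16 + 80 + 8 + 8, 8)]
        spr = [int(v) for v in column(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8)]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF signal header table") from exc
    if rec_dur <= 0 or any(s <= 0 for s in spr):
        raise FormatError(f"{path}: non-positive record duration or sample count")
    return {
        "labels": labels,
        "physical_min": phys_min,
        "physical_max": phys_max,
        "sampling_rate": [s / rec_dur for s in spr],
        "n_records": n_rec,
        "record_duration_s": rec_dur,
    }


def quantization_step(transducer_max: float) -> float:
    """Amplitude resolution (µV per digital unit) of a written channel."""
    pmax = max(float(transducer_max), 1.0)
    return 2 * pmax / (_DIG_MAX - _DIG_MIN)
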