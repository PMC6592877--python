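"""European Data Format (EDF) reader/writer.

EDF is one of the two official EEG-BIDS recording formats.  A file is a
256-byte fixed header, 256 bytes of header per signal, then data records of
16-bit little-endian two's-complement integers, multiplexed record-by-record.
Each signal carries an affine digital→physical calibration

    p = physical_min + (d - digital_min) * (physical_max - physical_min)
                                          / (digital_max - digital_min)

so the worst-case round-trip error of a written value is one quantization
step, (physical_max - physical_min) / (digital_max - digital_min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import Recording
from .errors import FormatError, InvariantError, PrecisionError

DIGITAL_MIN = -32768
DIGITAL_MAX = 32767

#: Fixed start stamp written when the caller supplies none (dd.mm.yy hh.mm.ss).
DEFAULT_START_DATE = "01.01.85"
DEFAULT_START_TIME = "00.00.00"


@dataclass
class EDFSignalHeader:
    """Per-signal calibration and layout block (256 ASCII bytes in the file)."""

    label: str
    physical_dimension: str
    physical_min: float
    physical_max: float
    digital_min: int
    digital_max: int
    samples_per_record: int
    transducer: str = ""
    prefiltering: str = ""

    def __post_init__(self) -> None:
        if not self.physical_max > self.physical_min:
            raise InvariantError("physical_max must exceed physical_min")
        if not self.digital_max > self.digital_min:
            raise InvariantError("digital_max must exceed digital_min")
        if not (DIGITAL_MIN <= self.digital_min < self.digital_max <= DIGITAL_MAX):
            raise InvariantError("digital range must lie within int16")

    @property
    def quantization_step(self) -> float:
        return (self.physical_max - self.physical_min) / (
            self.digital_max - self.digital_min
        )


@dataclass
class EDFFixedHeader:
    """The 256-byte file-level header."""

    n_signals: int
    n_records: int
    record_duration: float
    patient_id: str = "X X X X"
    recording_id: str = "Startdate X X X X"
    start_date: str = DEFAULT_START_DATE
    start_time: str = DEFAULT_START_TIME
    version: str = "0"
    signals: list[EDFSignalHeader] = field(default_factory=list)

    @property
    def header_bytes(self) -> int:
        return 256 * (self.n_signals + 1)


def digital_to_physical(d: int | np.ndarray, h: EDFSignalHeader):
    """Affine map from stored integers to physical units."""
    return h.physical_min + (np.asarray(d, dtype=np.float64) - h.digital_min) * (
        h.physical_max - h.physical_min
    ) / (h.digital_max - h.digital_min)


def physical_to_digital(p: float | np.ndarray, h: EDFSignalHeader) -> np.ndarray:
    """Inverse map, rounded to nearest and clamped to the digital range."""
    d = np.rint(
        (np.asarray(p, dtype=np.float64) - h.physical_min)
        * (h.digital_max - h.digital_min)
        / (h.physical_max - h.physical_min)
        + h.digital_min
    )
    return np.clip(d, h.digital_min, h.digital_max).astype(np.int16)


def _field(value: str, width: int) -> bytes:
    """Space-padded fixed-width ASCII field; overlong values are an error."""
    s = str(value)
    if len(s) > width:
        raise FormatError(f"header field {s!r} exceeds {width} ASCII bytes")
    encoded = s.encode("ascii", errors="strict")
    return encoded + b" " * (width - len(encoded))


def _num(value: float, width: int) -> bytes:
    """Shortest ASCII numeral for a numeric header field.

    The chosen string must parse back to exactly ``value`` — calibration
    written to the header has already been snapped to an 8-char
    representation by :func:`_snap_range`, so this never loses precision.
    """
    if float(value) == int(value):
        s = str(int(value))
    else:
        s = repr(float(value))
        if len(s) > width:
            for p in range(width - 1, 0, -1):
                s = f"{value:.{p}g}"
                if len(s) <= width:
                    break
    if float(s) != float(value):
        raise PrecisionError(
            f"value {value!r} not exactly representable in {width} ASCII chars"
        )
    return _field(s, width)


def _snap_range(m: float, width: int = 8) -> float:
    """Largest-magnitude bound ``>= m`` whose negation prints in ``width`` chars.

    EDF stores physical_min/max as 8-character ASCII; quantization must use
    the value the header will actually carry, and the snapped bound must not
    undercut the data extrema (which would clip samples).
    """
    candidate = m
    for _ in range(20):
        s = repr(candidate)
        if len(s) <= width - 1 and float(s) >= m:
            return float(s)
        for p in range(width - 2, 0, -1):
            s = f"{candidate:.{p}g}"
            if len(s) <= width - 1 and float(s) >= m:
                return float(s)
        candidate *= 1.05
    raise PrecisionError(f"cannot represent physical bound {m} in {width} chars")


def _choose_record_duration(sfreq: float, requested: float | None) -> float:
    """Default 1 s; for non-integer rates the smallest k ≤ 10 making
    sfreq*k integral."""
    if requested is not None:
        if abs(sfreq * requested - round(sfreq * requested)) > 1e-9:
            raise InvariantError(
                f"sampling_frequency {sfreq} x record_duration {requested} "
                "is not an integer sample count"
            )
        return requested
    for k in range(1, 11):
        if abs(sfreq * k - round(sfreq * k)) < 1e-9:
            return float(k)
    raise InvariantError(
        f"no record duration <= 10 s makes {sfreq} Hz an integer per record"
    )


def _physical_range(x: np.ndarray) -> tuple[float, float]:
    """Symmetric per-channel range with 1% margin; 1 unit when all-zero."""
    m = float(np.max(np.abs(x))) if x.size else 0.0
    if m == 0.0 or not math.isfinite(m):
        m = 1.0
    else:
        m = _snap_range(m * 1.01)
    return -m, m


def write_edf(
    r: Recording,
    path: str | Path,
    record_duration: float | None = None,
    start_date: str = DEFAULT_START_DATE,
    start_time: str = DEFAULT_START_TIME,
) -> EDFFixedHeader:
    """Write a continuous EDF file; returns the header actually written.

    The physical range of each signal is chosen from its data extrema
    (symmetric, 1% margin, never zero-width).  A final partial record is
    padded with each channel's last sample and counted in ``n_records``.
    """
    path = Path(path)
    dur = _choose_record_duration(r.sampling_frequency, record_duration)
    spr = int(round(r.sampling_frequency * dur))
    n_records = math.ceil(r.n_samples / spr) if r.n_samples else 0

    signals: list[EDFSignalHeader] = []
    for name, unit, x in zip(r.channel_names, r.channel_units, r.samples):
        pmin, pmax = _physical_range(x)
        if not np.all(np.isfinite(x)):
            raise PrecisionError(f"channel {name!r} contains non-finite samples")
        # uV is the conventional ASCII spelling of microvolts in EDF headers
        dim = "uV" if unit in ("µV", "uV", "μV") else unit
        signals.append(
            EDFSignalHeader(
                label=name,
                physical_dimension=dim,
                physical_min=pmin,
                physical_max=pmax,
                digital_min=DIGITAL_MIN,
                digital_max=DIGITAL_MAX,
                samples_per_record=spr,
            )
        )
    header = EDFFixedHeader(
        n_signals=r.n_channels,
        n_records=n_records,
        record_duration=dur,
        start_date=start_date,
        start_time=start_time,
        signals=signals,
    )

    digital = np.empty((r.n_channels, n_records * spr), dtype=np.int16)
    for i, (sig, x) in enumerate(zip(signals, r.samples)):
        padded = np.concatenate(
            [x, np.full(n_records * spr - x.size, x[-1] if x.size else 0.0)]
        )
        digital[i] = physical_to_digital(padded, sig)

    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        fh.write(_encode_headers(header))
        # record-multiplexed payload: all of signal 1's record, then signal 2's...
        records = digital.reshape(r.n_channels, n_records, spr)
        payload = records.transpose(1, 0, 2)
        fh.write(payload.astype("<i2").tobytes())
    return header


def _encode_headers(h: EDFFixedHeader) -> bytes:
    parts = [
        _field(h.version, 8),
        _field(h.patient_id, 80),
        _field(h.recording_id, 80),
        _field(h.start_date, 8),
        _field(h.start_time, 8),
        _num(h.header_bytes, 8),
        _field("", 44),  # reserved
        _num(h.n_records, 8),
        _num(h.record_duration, 8),
        _num(h.n_signals, 4),
    ]
    sig = h.signals
    parts += [_field(s.label, 16) for s in sig]
    parts += [_field(s.transducer, 80) for s in sig]
    parts += [_field(s.physical_dimension, 8) for s in sig]
    parts += [_num(s.physical_min, 8) for s in sig]
    parts += [_num(s.physical_max, 8) for s in sig]
    parts += [_num(s.digital_min, 8) for s in sig]
    parts += [_num(s.digital_max, 8) for s in sig]
    parts += [_field(s.prefiltering, 80) for s in sig]
    parts += [_num(s.samples_per_record, 8) for s in sig]
    parts += [_field("", 32) for _ in sig]  # reserved
    blob = b"".join(parts)
    assert len(blob) == h.header_bytes
    return blob


def _take(buf: bytes, offset: int, width: int) -> tuple[str, int]:
    return buf[offset : offset + width].decode("ascii").rstrip(), offset + width


def _take_num(buf: bytes, offset: int, width: int, what: str) -> tuple[float, int]:
    s, offset = _take(buf, offset, width)
    try:
        return float(s), offset
    except ValueError as exc:
        raise FormatError(f"non-numeric header field {what}: {s!r}") from exc


def read_header(path: str | Path) -> EDFFixedHeader:
    """Parse and cross-check the ASCII headers only."""
    path = Path(path)
    with open(path, "rb") as fh:
        fixed = fh.read(256)
        if len(fixed) < 256:
            raise FormatError(f"{path}: truncated fixed header")
        version, off = _take(fixed, 0, 8)
        if version != "0":
            raise FormatError(f"{path}: EDF version field is {version!r}, not '0'")
        patient, off = _take(fixed, off, 80)
        recording, off = _take(fixed, off, 80)
        start_date, off = _take(fixed, off, 8)
        start_time, off = _take(fixed, off, 8)
        header_bytes, off = _take_num(fixed, off, 8, "header_bytes")
        _, off = _take(fixed, off, 44)
        n_records, off = _take_num(fixed, off, 8, "n_records")
        record_duration, off = _take_num(fixed, off, 8, "record_duration")
        n_signals, off = _take_num(fixed, off, 4, "n_signals")
        ns = int(n_signals)
        if int(header_bytes) != 256 * (ns + 1):
            raise FormatError(
                f"{path}: header_bytes {int(header_bytes)} inconsistent with "
                f"{ns} signals (expected {256 * (ns + 1)})"
            )
        sigblock = fh.read(256 * ns)
        if len(sigblock) < 256 * ns:
            raise FormatError(f"{path}: truncated signal header block")

    # the signal header is column-major: all labels, then all transducers, ...
    offsets = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    cols: list[list[str]] = []
    pos = 0
    for width in offsets:
        cols.append(
            [
                sigblock[pos + i * width : pos + (i + 1) * width].decode("ascii").rstrip()
                for i in range(ns)
            ]
        )
        pos += ns * width
    labels, transducers, dims, pmins, pmaxs, dmins, dmaxs, prefs, sprs, _ = cols

    signals = []
    for i in range(ns):
        try:
            signals.append(
                EDFSignalHeader(
                    label=labels[i],
                    transducer=transducers[i],
                    physical_dimension=dims[i],
                    physical_min=float(pmins[i]),
                    physical_max=float(pmaxs[i]),
                    digital_min=int(float(dmins[i])),
                    digital_max=int(float(dmaxs[i])),
                    prefiltering=prefs[i],
                    samples_per_record=int(float(sprs[i])),
                )
            )
        except ValueError as exc:
            raise FormatError(
                f"{path}: non-numeric calibration field for signal {i}"
            ) from exc
    return EDFFixedHeader(
        n_signals=ns,
        n_records=int(n_records),
        record_duration=record_duration,
        patient_id=patient,
        recording_id=recording,
        start_date=start_date,
        start_time=start_time,
        signals=signals,
    )


def read_edf(path: str | Path) -> Recording:
    """Read a continuous EDF file into a physical-valued :class:`Recording`."""
    path = Path(path)
    header = read_header(path)
    ns = header.n_signals
    sprs = [s.samples_per_record for s in header.signals]
    if len(set(sprs)) > 1:
        raise FormatError(
            f"{path}: per-signal sampling rates differ ({set(sprs)}); unsupported"
        )
    spr = sprs[0] if sprs else 0
    expected = header.n_records * ns * spr * 2
    payload = path.read_bytes()[header.header_bytes :]
    if len(payload) < expected:
        raise FormatError(
            f"{path}: truncated at byte {header.header_bytes + len(payload)}, "
            f"expected {header.header_bytes + expected} bytes"
        )
    raw = np.frombuffer(payload[:expected], dtype="<i2")
    records = raw.reshape(header.n_records, ns, spr)
    digital = records.transpose(1, 0, 2).reshape(ns, header.n_records * spr)

    samples = np.empty(digital.shape, dtype=np.float64)
    for i, sig in enumerate(header.signals):
        d = digital[i]
        out_of_range = (d < sig.digital_min) | (d > sig.digital_max)
        if out_of_range.any():
            d = np.clip(d, sig.digital_min, sig.digital_max)
        samples[i] = digital_to_physical(d, sig)

    sfreq = spr / header.record_duration if header.record_duration else 0.0
    units = [
        "µV" if s.physical_dimension == "uV" else (s.physical_dimension or "n/a")
        for s in header.signals
    ]
    return Recording(
        channel_names=[s.label for s in header.signals],
        sampling_frequency=sfreq,
        samples=samples,
        channel_units=units,
    )
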