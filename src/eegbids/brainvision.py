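"""BrainVision Core Data Format reader/writer.

A recording is a triplet of sibling files: an INI-style header (``.vhdr``)
describing layout and calibration, an INI-style marker file (``.vmrk``)
holding events at 1-based sample positions, and a raw little-endian binary
payload (``.eeg``).  Only the continuous BINARY/MULTIPLEXED layout is
supported, in either of two sample encodings:

* ``IEEE_FLOAT_32`` (default) — physical values stored verbatim as float32;
* ``INT_16`` — integers scaled by a per-channel resolution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import Recording
from .errors import FormatError, InvariantError, RangeError

BINARY_FORMATS = {"INT_16": np.dtype("<i2"), "IEEE_FLOAT_32": np.dtype("<f4")}

_VHDR_MAGIC = "Brain Vision Data Exchange Header File Version 1.0"
_VMRK_MAGIC = "Brain Vision Data Exchange Marker File, Version 1.0"


@dataclass
class ChannelInfo:
    name: str
    reference: str
    resolution: float
    unit: str


@dataclass
class VhdrDocument:
    """Parsed .vhdr content relevant to decoding the payload."""

    data_file: str
    marker_file: str
    binary_format: str
    sampling_interval_us: float
    channels: list[ChannelInfo] = field(default_factory=list)

    @property
    def sampling_frequency(self) -> float:
        return 1e6 / self.sampling_interval_us

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class Marker:
    """One .vmrk entry; position is 1-based in samples, channel 0 = all."""

    mtype: str
    description: str
    position: int
    points: int = 1
    channel: int = 0


def parse_ini(text: str) -> dict[str, dict[str, str]]:
    """Parse the INI dialect used by .vhdr/.vmrk files.

    Comment lines start with ``;``; duplicate keys within a section keep the
    last occurrence.  A key-value line before any section header is an error.
    """
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
            continue
        if "=" in line:
            if current is None:
                raise FormatError(
                    f"line {lineno}: key-value pair before any [section] header"
                )
            key, _, value = line.partition("=")
            current[key.strip()] = value.strip()
        # free-text lines (the magic first line, comment blocks) are
        # tolerated and ignored wherever they appear
    return sections


def _read_text(path: Path) -> str:
    data = path.read_bytes()
    try:
        return data.decode("utf-8")
    except UnicodeDecodeError:
        return data.decode("latin-1")


def _sanitize(value: str) -> str:
    """Escape characters that would corrupt the INI line structure."""
    return value.replace(",", "\\1").replace("\n", " ").replace("\r", " ")


def write_brainvision(
    r: Recording,
    basepath: str | Path,
    binary_format: str = "IEEE_FLOAT_32",
) -> tuple[Path, Path, Path]:
    """Write the .vhdr/.vmrk/.eeg triplet; returns the three paths.

    Samples are multiplexed (channel-interleaved).  In ``INT_16`` mode each
    channel stores ``round(x / resolution)`` with resolution
    ``max|x| / 32767`` (1 if the channel is all zero); ``IEEE_FLOAT_32``
    stores physical values with resolution 1.  Events become ``Stimulus``
    markers at 1-based position ``round(onset * sfreq) + 1``.
    """
    if binary_format not in BINARY_FORMATS:
        raise InvariantError(f"unsupported BinaryFormat {binary_format!r}")
    base = Path(basepath)
    if base.suffix:
        raise InvariantError(f"basepath {base} must not carry an extension")
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    base.parent.mkdir(parents=True, exist_ok=True)

    if binary_format == "INT_16":
        resolutions = []
        scaled = np.empty(r.samples.shape, dtype=np.int16)
        for i, x in enumerate(r.samples):
            m = float(np.max(np.abs(x))) if x.size else 0.0
            res = m / 32767.0 if m > 0 else 1.0
            q = np.rint(x / res)
            if np.any(np.abs(q) > 32767):
                raise RangeError(
                    f"channel {r.channel_names[i]!r} overflows INT_16 at "
                    f"resolution {res}"
                )
            resolutions.append(res)
            scaled[i] = q.astype(np.int16)
        payload = scaled.T.astype("<i2").tobytes()
    else:
        resolutions = [1.0] * r.n_channels
        payload = r.samples.T.astype("<f4").tobytes()
    eeg.write_bytes(payload)

    sampling_interval = 1e6 / r.sampling_frequency
    si = (
        str(int(round(sampling_interval)))
        if abs(sampling_interval - round(sampling_interval)) < 1e-9
        else repr(sampling_interval)
    )
    lines = [
        _VHDR_MAGIC,
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={r.n_channels}",
        f"SamplingInterval={si}",
        "",
        "[Binary Infos]",
        f"BinaryFormat={binary_format}",
        "",
        "[Channel Infos]",
    ]
    for i, (name, unit, res) in enumerate(
        zip(r.channel_names, r.channel_units, resolutions), start=1
    ):
        res_s = str(int(res)) if float(res) == int(res) else repr(res)
        lines.append(f"Ch{i}={_sanitize(name)},,{res_s},{unit}")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        _VMRK_MAGIC,
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0",
    ]
    for j, (onset, dur, desc) in enumerate(r.events, start=2):
        pos = int(round(onset * r.sampling_frequency)) + 1
        points = int(round(dur * r.sampling_frequency))
        mlines.append(
            f"Mk{j}=Stimulus,{_sanitize(desc)},{pos},{max(points, 1)},0"
        )
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")
    return vhdr, vmrk, eeg


def _parse_vhdr(path: Path) -> VhdrDocument:
    sections = parse_ini(_read_text(path))
    common = sections.get("Common Infos", {})
    binary = sections.get("Binary Infos", {})
    chans = sections.get("Channel Infos", {})
    if common.get("DataFormat", "BINARY") != "BINARY":
        raise FormatError(
            f"{path}: DataFormat {common.get('DataFormat')!r} unsupported "
            "(only BINARY)"
        )
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise FormatError(
            f"{path}: DataOrientation {common.get('DataOrientation')!r} "
            "unsupported (only MULTIPLEXED)"
        )
    bfmt = binary.get("BinaryFormat", "")
    if bfmt not in BINARY_FORMATS:
        raise FormatError(f"{path}: unsupported BinaryFormat {bfmt!r}")
    try:
        n_channels = int(common["NumberOfChannels"])
        interval = float(common["SamplingInterval"])
        data_file = common["DataFile"]
        marker_file = common.get("MarkerFile", "")
    except KeyError as exc:
        raise FormatError(f"{path}: missing Common Infos key {exc}") from exc

    channels: list[ChannelInfo] = []
    for i in range(1, n_channels + 1):
        entry = chans.get(f"Ch{i}")
        if entry is None:
            raise FormatError(
                f"{path}: NumberOfChannels={n_channels} but Ch{i} missing"
            )
        parts = entry.split(",")
        name = parts[0].replace("\\1", ",")
        ref = parts[1] if len(parts) > 1 else ""
        res = float(parts[2]) if len(parts) > 2 and parts[2] else 1.0
        unit = parts[3] if len(parts) > 3 and parts[3] else "µV"
        channels.append(ChannelInfo(name, ref, res, unit))
    if len(chans) != n_channels:
        raise FormatError(
            f"{path}: channel count mismatch (header says {n_channels}, "
            f"{len(chans)} Ch<i> entries)"
        )
    return VhdrDocument(
        data_file=data_file,
        marker_file=marker_file,
        binary_format=bfmt,
        sampling_interval_us=interval,
        channels=channels,
    )


def _parse_vmrk(path: Path) -> list[Marker]:
    sections = parse_ini(_read_text(path))
    markers: list[Marker] = []
    infos = sections.get("Marker Infos", {})
    for key in sorted(infos, key=lambda k: int(re.sub(r"\D", "", k) or 0)):
        if not key.startswith("Mk"):
            continue
        parts = infos[key].split(",")
        if len(parts) < 3:
            raise FormatError(f"{path}: malformed marker {key}={infos[key]!r}")
        markers.append(
            Marker(
                mtype=parts[0],
                description=parts[1].replace("\\1", ","),
                position=int(parts[2]),
                points=int(parts[3]) if len(parts) > 3 and parts[3] else 1,
                channel=int(parts[4]) if len(parts) > 4 and parts[4] else 0,
            )
        )
    return markers


def read_header(vhdr_path: str | Path) -> VhdrDocument:
    """Parse the .vhdr header only (used by the validator)."""
    return _parse_vhdr(Path(vhdr_path))


def read_brainvision(vhdr_path: str | Path) -> Recording:
    """Read a triplet starting from its .vhdr into a :class:`Recording`."""
    vhdr_path = Path(vhdr_path)
    doc = _parse_vhdr(vhdr_path)
    eeg_path = vhdr_path.parent / doc.data_file
    if not eeg_path.is_file():
        raise FormatError(f"{vhdr_path}: DataFile {eeg_path} not found")
    dtype = BINARY_FORMATS[doc.binary_format]
    raw = np.frombuffer(eeg_path.read_bytes(), dtype=dtype)
    nc = doc.n_channels
    if raw.size % nc:
        raise FormatError(
            f"{eeg_path}: payload of {raw.size} values not divisible by "
            f"{nc} channels"
        )
    frames = raw.reshape(-1, nc).T  # multiplexed: frame-major on disk
    if doc.binary_format == "INT_16":
        res = np.array([c.resolution for c in doc.channels])[:, None]
        samples = frames.astype(np.float64) * res
    else:
        samples = frames.astype(np.float64)

    sfreq = doc.sampling_frequency
    events: list[tuple[float, float, str]] = []
    if doc.marker_file:
        vmrk_path = vhdr_path.parent / doc.marker_file
        if not vmrk_path.is_file():
            raise FormatError(f"{vhdr_path}: MarkerFile {vmrk_path} not found")
        for mk in _parse_vmrk(vmrk_path):
            if mk.mtype == "New Segment":
                continue
            onset = (mk.position - 1) / sfreq
            duration = mk.points / sfreq if mk.points > 1 else 0.0
            events.append((onset, duration, mk.description))

    return Recording(
        channel_names=[c.name for c in doc.channels],
        sampling_frequency=sfreq,
        samples=samples,
        channel_units=[c.unit for c in doc.channels],
        events=events,
    )
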