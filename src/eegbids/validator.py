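"""Rule-based EEG-BIDS dataset validator.

Walks a dataset tree and applies a fixed catalog of checks for missing
files and underspecified metadata, emitting machine-readable issues.
Severities follow the standard's modal verbs: requirements ("must") are
errors, recommendations ("should"/"can") are warnings.  Malformed content
inside the tree yields issues, never exceptions, and the tree is never
modified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

from . import brainvision, edf, sidecars
from .core import (
    BIDSPath,
    DatasetIndex,
    EEG_DATA_EXTENSIONS,
    IndexEntry,
    index_dataset,
)
from .errors import EEGBIDSError

#: code -> (severity, one-line description)
RULE_CATALOG: dict[str, tuple[str, str]] = {
    "R1": ("error", "dataset_description.json missing at dataset root"),
    "R2": ("error", "EEG data file without a matching channels.tsv"),
    "R3": ("error", "electrodes.tsv without coordsystem.json or vice versa"),
    "R4": ("warning", "task recording with no events.tsv"),
    "R5": ("error", "eeg suffix with an extension outside the allowed set"),
    "R6": ("warning", "unofficial data format (.set/.fdt or .bdf)"),
    "R7": ("error", "channels.tsv row count differs from data header"),
    "R8": ("warning", "channel names/order differ between channels.tsv and data header"),
    "R9": ("warning", "EEG channel without a row in electrodes.tsv"),
    "R10": ("error", "resolved eeg.json metadata underspecified or inconsistent"),
    "R11": ("error", "events.tsv malformed (column order, negative or late onset)"),
    "R12": ("error", "filename does not parse under the BIDS grammar"),
    "R13": ("error", "channels.tsv status outside {good, bad}"),
    "R14": ("warning", "events stim_file not found under stimuli/"),
}

#: Extensions that *start* a recording (the .vmrk/.eeg siblings are carriers).
PRIMARY_DATA_EXTENSIONS = frozenset({".edf", ".vhdr", ".set", ".bdf"})
UNOFFICIAL_EXTENSIONS = frozenset({".set", ".fdt", ".bdf"})


@dataclass(frozen=True)
class Issue:
    code: str
    severity: str
    path: str
    message: str

    def as_dict(self) -> dict[str, str]:
        return {
            "code": self.code,
            "severity": self.severity,
            "path": self.path,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def n_errors(self) -> int:
        return sum(1 for i in self.issues if i.severity == "error")

    @property
    def n_warnings(self) -> int:
        return sum(1 for i in self.issues if i.severity == "warning")

    @property
    def ok(self) -> bool:
        return self.n_errors == 0

    def codes(self) -> set[str]:
        return {i.code for i in self.issues}

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "errors": self.n_errors,
                "warnings": self.n_warnings,
                "issues": [i.as_dict() for i in self.issues],
            },
            indent=2,
        )

    def to_text(self) -> str:
        lines = [
            f"{i.severity.upper():7s} {i.code:4s} {i.path}: {i.message}"
            for i in self.issues
        ]
        lines.append(
            f"Summary: {self.n_errors} error(s), {self.n_warnings} warning(s) "
            f"-> {'OK' if self.ok else 'INVALID'}"
        )
        return "\n".join(lines)


class _Checker:
    """One validation pass over an indexed tree."""

    def __init__(self, index: DatasetIndex):
        self.index = index
        self.root = index.root
        self.issues: list[Issue] = []

    def add(self, code: str, path: str, message: str) -> None:
        severity = RULE_CATALOG[code][0]
        self.issues.append(Issue(code, severity, path, message))

    # -- helpers ---------------------------------------------------------

    def _entries(self) -> list[IndexEntry]:
        return list(self.index.all_entries())

    def _data_files(self) -> list[IndexEntry]:
        """Primary EEG recordings (one entry per recording)."""
        out = []
        for e in self._entries():
            p = e.parsed
            if (
                isinstance(p, BIDSPath)
                and p.suffix == "eeg"
                and p.extension in PRIMARY_DATA_EXTENSIONS
            ):
                out.append(e)
        return out

    def _sibling(self, data: BIDSPath, suffix: str, ext: str) -> IndexEntry | None:
        """A sibling sidecar sharing the data file's entity set."""
        for e in self._entries():
            p = e.parsed
            if (
                isinstance(p, BIDSPath)
                and p.suffix == suffix
                and p.extension == ext
                and dict(p.entities) == dict(data.entities)
            ):
                return e
        return None

    def _read_data_header(
        self, entry: IndexEntry
    ) -> tuple[list[str], float] | None:
        """(channel names, sampling frequency) from an EDF/vhdr header."""
        p = entry.parsed
        assert isinstance(p, BIDSPath)
        try:
            if p.extension == ".edf":
                h = edf.read_header(self.root / entry.relpath)
                if not h.signals:
                    return [], 0.0
                sfreq = h.signals[0].samples_per_record / h.record_duration
                return [s.label for s in h.signals], sfreq
            if p.extension == ".vhdr":
                doc = brainvision.read_header(self.root / entry.relpath)
                return [c.name for c in doc.channels], doc.sampling_frequency
        except (EEGBIDSError, OSError, ValueError) as exc:
            self.add("R5", entry.relpath, f"unreadable data header: {exc}")
        return None

    # -- rules -----------------------------------------------------------

    def check_root(self) -> None:
        names = {e.relpath for e in self.index.root_files}
        if "dataset_description.json" not in names:
            self.add(
                "R1", "<root>",
                "dataset root lacks the required dataset_description.json",
            )

    def check_grammar(self) -> None:
        for label, entries in self.index.subject_files.items():
            for e in entries:
                if not e.unparseable:
                    continue
                # an eeg-suffixed file with a disallowed extension is a
                # format violation, not a naming one
                stem = e.relpath.rsplit("/", 1)[-1].partition(".")[0]
                ext = e.relpath.rsplit("/", 1)[-1][len(stem):]
                if stem.endswith("_eeg") and ext not in EEG_DATA_EXTENSIONS | {".json"}:
                    self.add(
                        "R5", e.relpath,
                        f"extension {ext!r} is not an allowed EEG data format",
                    )
                else:
                    self.add(
                        "R12", e.relpath,
                        f"filename does not parse: {e.error}",
                    )

    def check_data_files(self) -> None:
        for e in self._entries():
            p = e.parsed
            if isinstance(p, BIDSPath) and p.suffix == "eeg":
                if p.extension == ".json":
                    continue
                if p.extension not in EEG_DATA_EXTENSIONS:
                    self.add(
                        "R5", e.relpath,
                        f"extension {p.extension!r} is not an allowed EEG format",
                    )
                elif p.extension in UNOFFICIAL_EXTENSIONS:
                    self.add(
                        "R6", e.relpath,
                        f"{p.extension} is an unofficial format; EDF or "
                        "BrainVision is recommended",
                    )

        for e in self._data_files():
            p = e.parsed
            assert isinstance(p, BIDSPath)
            if self._sibling(p, "channels", ".tsv") is None:
                self.add(
                    "R2", e.relpath,
                    f"no channels.tsv matches {p.entities.chain()}",
                )
            if self._sibling(p, "events", ".tsv") is None:
                self.add(
                    "R4", e.relpath,
                    f"no events.tsv for task recording {p.basename}",
                )

    def check_electrode_pairing(self) -> None:
        electrodes = [
            e for e in self._entries()
            if isinstance(e.parsed, BIDSPath)
            and e.parsed.suffix == "electrodes" and e.parsed.extension == ".tsv"
        ]
        coordsystems = [
            e for e in self._entries()
            if isinstance(e.parsed, BIDSPath) and e.parsed.suffix == "coordsystem"
        ]

        def scope(e: IndexEntry) -> tuple:
            p = e.parsed
            assert isinstance(p, BIDSPath)
            return (p.entities.get("sub"), p.entities.get("ses"))

        coord_scopes = {scope(e) for e in coordsystems}
        elec_scopes = {scope(e) for e in electrodes}
        for e in electrodes:
            if scope(e) not in coord_scopes:
                self.add(
                    "R3", e.relpath,
                    "electrodes.tsv without an accompanying coordsystem.json",
                )
        for e in coordsystems:
            if scope(e) not in elec_scopes:
                self.add(
                    "R3", e.relpath,
                    "coordsystem.json without an accompanying electrodes.tsv",
                )

    def check_channels_tables(self) -> None:
        for e in self._data_files():
            p = e.parsed
            assert isinstance(p, BIDSPath)
            ch_entry = self._sibling(p, "channels", ".tsv")
            header = (
                self._read_data_header(e)
                if p.extension in (".edf", ".vhdr")
                else None
            )
            table = None
            if ch_entry is not None:
                try:
                    table = sidecars.read_table(
                        self.root / ch_entry.relpath, sidecars.CHANNELS_SCHEMA
                    )
                except EEGBIDSError as exc:
                    self.add("R13", ch_entry.relpath, f"unreadable channels.tsv: {exc}")
            if table is not None:
                if "status" in table.columns:
                    bad = [
                        v for v in table["status"]
                        if v not in sidecars.CHANNEL_STATUS_VALUES
                        and v != sidecars.NA
                    ]
                    if bad:
                        self.add(
                            "R13", ch_entry.relpath,
                            f"status value(s) {bad!r} outside {{good, bad}}",
                        )
                if header is not None:
                    names, _ = header
                    if len(table) != len(names):
                        self.add(
                            "R7", ch_entry.relpath,
                            f"channels.tsv lists {len(table)} channels but the "
                            f"data header has {len(names)}",
                        )
                    elif list(table["name"]) != names:
                        self.add(
                            "R8", ch_entry.relpath,
                            "channel names/order differ between channels.tsv "
                            "and the data header",
                        )
            self._check_electrode_coverage(p, table)

    def _check_electrode_coverage(self, data: BIDSPath, channels_table) -> None:
        if channels_table is None:
            return
        elec = self._sibling(data, "electrodes", ".tsv") or self._nearest_electrodes(data)
        if elec is None:
            return
        try:
            etable = sidecars.read_table(
                self.root / elec.relpath, sidecars.ELECTRODES_SCHEMA
            )
        except EEGBIDSError:
            return
        electrode_names = set(etable["name"])
        for _, row in channels_table.iterrows():
            if row.get("type", "EEG") == "EEG" and row["name"] not in electrode_names:
                self.add(
                    "R9", elec.relpath,
                    f"EEG channel {row['name']!r} has no electrodes.tsv row",
                )

    def _nearest_electrodes(self, data: BIDSPath) -> IndexEntry | None:
        """electrodes.tsv for the same subject/session (task-less is legal)."""
        for e in self._entries():
            p = e.parsed
            if (
                isinstance(p, BIDSPath)
                and p.suffix == "electrodes"
                and p.extension == ".tsv"
                and p.entities.get("sub") == data.entities.get("sub")
                and p.entities.get("ses") == data.entities.get("ses")
            ):
                return e
        return None

    def check_metadata(self) -> None:
        for e in self._data_files():
            p = e.parsed
            assert isinstance(p, BIDSPath)
            try:
                meta = sidecars.resolve_metadata(self.index, p)
            except EEGBIDSError as exc:
                self.add("R10", e.relpath, f"metadata resolution failed: {exc}")
                continue
            missing = sidecars.check_eeg_metadata(meta)
            if missing:
                self.add(
                    "R10", e.relpath,
                    f"resolved eeg.json metadata missing required key(s) "
                    f"{missing}",
                )
            header = (
                self._read_data_header(e)
                if p.extension in (".edf", ".vhdr")
                else None
            )
            sf = meta.get("SamplingFrequency")
            if header is not None and isinstance(sf, (int, float)) and sf > 0:
                _, actual = header
                if actual > 0 and abs(actual - sf) / actual > 1e-6:
                    self.add(
                        "R10", e.relpath,
                        f"SamplingFrequency {sf} Hz disagrees with data "
                        f"header {actual} Hz",
                    )

    def check_events(self) -> None:
        for e in self._data_files():
            p = e.parsed
            assert isinstance(p, BIDSPath)
            ev_entry = self._sibling(p, "events", ".tsv")
            if ev_entry is None:
                continue
            try:
                table = sidecars.read_table(self.root / ev_entry.relpath)
            except EEGBIDSError as exc:
                self.add("R11", ev_entry.relpath, f"unreadable events.tsv: {exc}")
                continue
            cols = list(table.columns)
            if cols[:2] != ["onset", "duration"]:
                self.add(
                    "R11", ev_entry.relpath,
                    f"first columns must be (onset, duration), got {cols[:2]}",
                )
                continue
            end = self._recording_end(e)
            for i, row in table.iterrows():
                try:
                    onset = float(row["onset"])
                except ValueError:
                    self.add(
                        "R11", ev_entry.relpath,
                        f"row {i}: non-numeric onset {row['onset']!r}",
                    )
                    continue
                if onset < 0:
                    self.add(
                        "R11", ev_entry.relpath, f"row {i}: negative onset {onset}"
                    )
                elif end is not None and onset > end:
                    self.add(
                        "R11", ev_entry.relpath,
                        f"row {i}: onset {onset}s beyond recording end {end}s",
                    )
                if "stim_file" in table.columns and row["stim_file"] != sidecars.NA:
                    stim = self.root / "stimuli" / row["stim_file"]
                    if not stim.is_file():
                        self.add(
                            "R14", ev_entry.relpath,
                            f"stim_file {row['stim_file']!r} not found under "
                            "stimuli/",
                        )

    def _recording_end(self, entry: IndexEntry) -> float | None:
        p = entry.parsed
        assert isinstance(p, BIDSPath)
        try:
            if p.extension == ".edf":
                h = edf.read_header(self.root / entry.relpath)
                return h.n_records * h.record_duration
            if p.extension == ".vhdr":
                doc = brainvision.read_header(self.root / entry.relpath)
                eeg_path = (self.root / entry.relpath).parent / doc.data_file
                if eeg_path.is_file() and doc.n_channels:
                    width = brainvision.BINARY_FORMATS[doc.binary_format].itemsize
                    n = eeg_path.stat().st_size // (width * doc.n_channels)
                    return n / doc.sampling_frequency
        except (EEGBIDSError, OSError, ValueError):
            return None
        return None

    def run(self) -> list[Issue]:
        for check in (
            self.check_root,
            self.check_grammar,
            self.check_data_files,
            self.check_electrode_pairing,
            self.check_channels_tables,
            self.check_metadata,
            self.check_events,
        ):
            check()
        return self.issues


def validate(root: str | Path, ignore_warnings: bool = False) -> ValidationReport:
    """Validate an EEG-BIDS tree; deterministic ordering, read-only.

    Raises OSError only when ``root`` itself is unreadable; any malformed
    content inside the tree becomes an :class:`Issue`.
    """
    index = index_dataset(root)
    issues = _Checker(index).run()
    if ignore_warnings:
        issues = [i for i in issues if i.severity != "warning"]
    issues.sort(key=lambda i: (i.path, i.code, i.message))
    return ValidationReport(issues=issues)
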