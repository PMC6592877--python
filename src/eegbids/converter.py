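"""Raw recording → validator-clean EEG-BIDS subtree.

``convert_recording`` takes a :class:`~eegbids.core.Recording` (or a raw
EDF/BrainVision file path), user-supplied study metadata, and target
entities, and writes the data file plus every sidecar the standard requires
(channels.tsv, eeg.json, events.tsv, dataset_description.json,
participants.tsv).  The keystone contract is that ``validate(root)`` holds
zero errors afterwards.  Writes are staged so a failure leaves no partial
files behind.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import brainvision, edf, sidecars
from .core import BIDSPath, EntitySet, Recording, build_path
from .errors import CollisionError, InvariantError

BIDS_VERSION = "1.4.0"

#: map Recording channel-type labels to BIDS channels.tsv types
_CHANNEL_TYPES = {"EEG", "EOG", "ECG", "EMG", "TRIG", "MISC"}


@dataclass
class EEGMetadata:
    """User-facing recording metadata feeding eeg.json."""

    TaskName: str
    EEGReference: str
    PowerLineFrequency: float | str = "n/a"
    SoftwareFilters: Mapping[str, Any] | str = "n/a"
    SamplingFrequency: float | None = None  # filled from the data if None
    Manufacturer: str | None = None

    def document(self, r: Recording) -> dict[str, Any]:
        doc: dict[str, Any] = {
            "TaskName": self.TaskName,
            "SamplingFrequency": self.SamplingFrequency or r.sampling_frequency,
            "EEGReference": self.EEGReference,
            "PowerLineFrequency": self.PowerLineFrequency,
            "SoftwareFilters": (
                dict(self.SoftwareFilters)
                if isinstance(self.SoftwareFilters, Mapping)
                else self.SoftwareFilters
            ),
            "EEGChannelCount": sum(t == "EEG" for t in r.channel_types),
            "EOGChannelCount": sum(t == "EOG" for t in r.channel_types),
            "TriggerChannelCount": sum(t == "TRIG" for t in r.channel_types),
            "RecordingDuration": r.duration,
        }
        if self.Manufacturer:
            doc["Manufacturer"] = self.Manufacturer
        return doc


def _load_source(source: Recording | str | Path) -> tuple[Recording, Path | None]:
    if isinstance(source, Recording):
        return source, None
    path = Path(source)
    if path.suffix == ".edf":
        return edf.read_edf(path), path
    if path.suffix == ".vhdr":
        return brainvision.read_brainvision(path), path
    raise InvariantError(
        f"cannot read source {path}: only .edf and .vhdr inputs are supported"
    )


def _channels_frame(r: Recording) -> pd.DataFrame:
    types = [t if t in _CHANNEL_TYPES else "MISC" for t in r.channel_types]
    return pd.DataFrame(
        {
            "name": r.channel_names,
            "type": types,
            "units": r.channel_units,
            "status": ["good"] * r.n_channels,
        }
    )


def _events_frame(r: Recording) -> pd.DataFrame:
    onsets = [str(float(o)) for o, _, _ in r.events]
    durations = [str(float(d)) for _, d, _ in r.events]
    frame = pd.DataFrame({"onset": onsets, "duration": durations})
    if any(desc for _, _, desc in r.events):
        frame["trial_type"] = [desc or sidecars.NA for _, _, desc in r.events]
    return frame


def append_participant(
    root: str | Path, sub_label: str, fields: Mapping[str, str] | None = None
) -> Path:
    """Add one row to participants.tsv; idempotent per subject.

    New columns introduced by later subjects are backfilled with ``n/a``
    for existing rows.
    """
    root = Path(root)
    path = root / "participants.tsv"
    pid = f"sub-{sub_label}"
    if path.is_file():
        table = sidecars.read_table(path, sidecars.PARTICIPANTS_SCHEMA)
    else:
        table = pd.DataFrame({"participant_id": []}, dtype=str)
    if pid in set(table["participant_id"]):
        return path
    row = {"participant_id": pid, **{k: str(v) for k, v in (fields or {}).items()}}
    table = pd.concat([table, pd.DataFrame([row])], ignore_index=True)
    table = table.fillna(sidecars.NA)
    sidecars.write_table(table, path, sidecars.PARTICIPANTS_SCHEMA)
    return path


def ensure_dataset_description(root: str | Path, name: str = "EEG dataset") -> Path:
    root = Path(root)
    path = root / "dataset_description.json"
    if not path.is_file():
        sidecars.write_json({"Name": name, "BIDSVersion": BIDS_VERSION}, path)
    return path


def convert_recording(
    source: Recording | str | Path,
    entities: EntitySet | Mapping[str, str],
    meta: EEGMetadata,
    root: str | Path,
    format: str = "brainvision",
    copy_through: bool = False,
    overwrite: bool = False,
) -> list[str]:
    """Convert one recording into an EEG-BIDS subtree; returns written paths.

    ``copy_through`` byte-copies a source file already in an allowed format
    instead of re-encoding it.  Existing targets raise
    :class:`CollisionError` unless ``overwrite`` is set.  On any failure the
    tree is left untouched.
    """
    entities = EntitySet(entities)
    if "sub" not in entities or "task" not in entities:
        raise InvariantError("conversion requires sub and task entities")
    if format not in ("brainvision", "edf"):
        raise InvariantError(f"unknown output format {format!r}")
    root = Path(root)
    recording, source_path = _load_source(source)

    if copy_through:
        if source_path is None:
            raise InvariantError("copy_through requires a file source")
        data_ext = source_path.suffix
    else:
        data_ext = ".vhdr" if format == "brainvision" else ".edf"

    data_bp = BIDSPath(entities, "eeg", data_ext, "eeg")
    rel_data = build_path(data_bp)
    plan = {
        "data": rel_data,
        "channels": build_path(BIDSPath(entities, "channels", ".tsv", "eeg")),
        "eegjson": build_path(BIDSPath(entities, "eeg", ".json", "eeg")),
        "events": build_path(BIDSPath(entities, "events", ".tsv", "eeg")),
    }
    targets = [root / p for p in plan.values()]
    if format == "brainvision" and not copy_through:
        targets += [
            (root / rel_data).with_suffix(".vmrk"),
            (root / rel_data).with_suffix(".eeg"),
        ]
    if not overwrite:
        existing = [t for t in targets if t.exists()]
        if existing:
            raise CollisionError(
                f"target file(s) exist: {[str(t) for t in existing]}; "
                "pass overwrite to replace"
            )

    # stage everything, then move into place: atomicity on failure
    written: list[str] = []
    staged: list[tuple[Path, Path]] = []
    stage = root / ".eegbids-staging"
    if stage.exists():
        shutil.rmtree(stage)
    try:
        data_target = stage / rel_data
        data_target.parent.mkdir(parents=True, exist_ok=True)
        if copy_through:
            shutil.copyfile(source_path, data_target)
            staged.append((data_target, root / rel_data))
            if source_path.suffix == ".vhdr":  # carry the triplet siblings
                for sib in (".vmrk", ".eeg"):
                    shutil.copyfile(
                        source_path.with_suffix(sib), data_target.with_suffix(sib)
                    )
                    staged.append(
                        (data_target.with_suffix(sib),
                         (root / rel_data).with_suffix(sib))
                    )
        elif format == "brainvision":
            paths = brainvision.write_brainvision(
                recording, data_target.with_suffix("")
            )
            for p in paths:
                staged.append((p, root / rel_data.rsplit("/", 1)[0] / p.name))
        else:
            edf.write_edf(recording, data_target)
            staged.append((data_target, root / rel_data))

        sidecars.write_table(
            _channels_frame(recording),
            stage / plan["channels"],
            sidecars.CHANNELS_SCHEMA,
        )
        staged.append((stage / plan["channels"], root / plan["channels"]))

        sidecars.write_json(meta.document(recording), stage / plan["eegjson"])
        staged.append((stage / plan["eegjson"], root / plan["eegjson"]))

        sidecars.write_table(_events_frame(recording), stage / plan["events"])
        staged.append((stage / plan["events"], root / plan["events"]))

        for src, dst in staged:
            dst.parent.mkdir(parents=True, exist_ok=True)
            shutil.move(str(src), str(dst))
            written.append(dst.relative_to(root).as_posix())
    finally:
        if stage.exists():
            shutil.rmtree(stage)

    ensure_dataset_description(root)
    append_participant(root, entities["sub"])
    return written
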