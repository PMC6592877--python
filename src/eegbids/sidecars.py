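"""Sidecar metadata: TSV tables, JSON documents, and inheritance resolution.

BIDS stores all metadata next to the data in tab-separated tables and JSON
dictionaries.  JSON sidecars placed high in the tree apply to every data
file below them unless a deeper sidecar overrides a key — the Inheritance
Principle.  This module owns the table schemas (required columns, leading
column order, the ``n/a`` missing-value token) and the resolver that merges
applicable sidecars root-first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from .core import BIDSPath, DatasetIndex, SidecarPath
from .errors import AmbiguityError, SchemaError

NA = "n/a"

#: Required eeg.json keys (validator rule R10 enforces these).
REQUIRED_EEG_JSON_KEYS = (
    "TaskName",
    "SamplingFrequency",
    "EEGReference",
    "PowerLineFrequency",
    "SoftwareFilters",
)


@dataclass(frozen=True)
class TableSchema:
    """Column contract for one TSV kind.

    ``leading`` columns must open the header in this exact order;
    ``unique`` names a column whose values must not repeat.
    """

    name: str
    leading: tuple[str, ...]
    unique: str | None = None

    def check(self, columns: Sequence[str]) -> None:
        if tuple(columns[: len(self.leading)]) != self.leading:
            raise SchemaError(
                f"{self.name}: first columns must be {list(self.leading)}, "
                f"got {list(columns[: len(self.leading)])}"
            )
        if len(set(columns)) != len(columns):
            raise SchemaError(f"{self.name}: duplicate column names")


CHANNELS_SCHEMA = TableSchema("channels.tsv", ("name", "type", "units"), unique="name")
ELECTRODES_SCHEMA = TableSchema("electrodes.tsv", ("name", "x", "y", "z"), unique="name")
EVENTS_SCHEMA = TableSchema("events.tsv", ("onset", "duration"))
PARTICIPANTS_SCHEMA = TableSchema(
    "participants.tsv", ("participant_id",), unique="participant_id"
)

#: channels.tsv status column vocabulary.
CHANNEL_STATUS_VALUES = frozenset({"good", "bad"})


def read_table(path: str | Path, schema: TableSchema | None = None) -> pd.DataFrame:
    """Read a BIDS TSV into string-typed cells; ``n/a`` stays literal.

    Cells are kept as strings so that the write→read round trip is lossless;
    numeric interpretation happens at the point of use.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
        )
    except Exception as exc:
        raise SchemaError(f"{path}: cannot parse TSV ({exc})") from exc
    if schema is not None:
        schema.check(list(df.columns))
        if schema.unique and df[schema.unique].duplicated().any():
            dupes = df[schema.unique][df[schema.unique].duplicated()].tolist()
            raise SchemaError(f"{schema.name}: duplicate {schema.unique} {dupes}")
    return df


def write_table(table: pd.DataFrame, path: str | Path,
                schema: TableSchema | None = None) -> None:
    """Write a TSV with LF line endings; missing cells become ``n/a``."""
    if schema is not None:
        schema.check(list(table.columns))
    out = table.astype(object).where(table.notna(), NA)
    out = out.replace("", NA)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_json(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: top-level JSON value must be an object")
    return doc


def write_json(doc: Mapping[str, Any], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, ensure_ascii=False, sort_keys=False)
        fh.write("\n")


def check_eeg_metadata(doc: Mapping[str, Any]) -> list[str]:
    """Return the required eeg.json keys missing from ``doc``."""
    return [k for k in REQUIRED_EEG_JSON_KEYS if k not in doc]


def _level(relpath: str) -> tuple[int, str]:
    """Sort key: directory depth first (root=0), then path for determinism."""
    return (relpath.count("/"), relpath)


def applicable_sidecars(index: DatasetIndex, target: BIDSPath) -> list[str]:
    """JSON sidecars applying to ``target``, ordered root-first then deeper.

    A sidecar applies iff its suffix matches the target's and its entity set
    is a subset of the target's entities.  Two applicable sidecars at the
    same directory level are ambiguous and rejected.
    """
    hits: list[tuple[tuple[int, str], str]] = []
    for entry in index.all_entries():
        parsed = entry.parsed
        if parsed is None:
            continue
        if isinstance(parsed, SidecarPath):
            suffix, entities = parsed.suffix, parsed.entities
        elif isinstance(parsed, BIDSPath) and parsed.extension == ".json":
            suffix, entities = parsed.suffix, parsed.entities
        else:
            continue
        if suffix != target.suffix:
            continue
        if entities.issubset(target.entities):
            hits.append((_level(entry.relpath), entry.relpath))
    hits.sort()
    levels = [lvl for (lvl, _), _ in hits]
    for a, b in zip(levels, levels[1:]):
        if a == b:
            same = [p for (lvl, _), p in hits if lvl == a]
            raise AmbiguityError(
                f"sidecars {same} at the same level both apply to "
                f"{target.basename}"
            )
    return [p for _, p in hits]


def resolve_metadata(index: DatasetIndex, target: BIDSPath) -> dict[str, Any]:
    """Merge all applicable sidecars, deeper documents overriding key-by-key.

    The merge is shallow: a deeper sidecar that redefines a top-level key
    replaces the whole value, nested objects included.
    """
    merged: dict[str, Any] = {}
    for rel in applicable_sidecars(index, target):
        merged.update(read_json(index.root / rel))
    return merged
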