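"""Core dataset model: entity filename grammar, paths, recordings, tree index.

BIDS identifies every file by a chain of entity key-value pairs embedded in
its name (``sub-01_ses-02_task-rest_eeg.edf``), a suffix naming the file's
role, and an extension naming its format.  This module owns that grammar:
parsing, serialization, and the in-memory ``Recording`` container that the
codecs, converter and synthetic generator exchange.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import GrammarError, InvariantError

#: Canonical entity ordering.  ``sub`` is mandatory for subject-level files.
ENTITY_ORDER: tuple[str, ...] = ("sub", "ses", "task", "acq", "run")

_ENTITY_RANK = {k: i for i, k in enumerate(ENTITY_ORDER)}
_LABEL_RE = re.compile(r"^[A-Za-z0-9]+$")

#: Suffixes whose files carry a task entity by construction.
TASK_SUFFIXES = frozenset({"eeg", "channels", "events"})

#: Allowed extensions for an ``eeg``-suffixed data file (plus ``.json`` sidecar).
EEG_DATA_EXTENSIONS = frozenset(
    {".edf", ".vhdr", ".vmrk", ".eeg", ".set", ".fdt", ".bdf"}
)

#: suffix -> allowed extensions
SUFFIX_EXTENSIONS: dict[str, frozenset[str]] = {
    "eeg": EEG_DATA_EXTENSIONS | {".json"},
    "channels": frozenset({".tsv", ".json"}),
    "electrodes": frozenset({".tsv", ".json"}),
    "events": frozenset({".tsv", ".json"}),
    "coordsystem": frozenset({".json"}),
    "participants": frozenset({".tsv", ".json"}),
    "dataset_description": frozenset({".json"}),
    "README": frozenset({"", ".md", ".txt"}),
}

#: Root-level filenames that carry no entities.
_ROOT_SUFFIXES = frozenset({"participants", "dataset_description", "README"})

DATATYPES = frozenset({"eeg", "anat"})

#: Free-form container directories whose contents are never parsed as BIDS.
CONTAINER_DIRS = frozenset({"sourcedata", "stimuli", "code", "derivatives"})


class EntitySet(dict):
    """Ordered ``entity key -> label`` mapping under the canonical order.

    Behaves as a plain dict but validates keys/labels and re-sorts itself
    into canonical order (sub < ses < task < acq < run) on construction.
    """

    def __init__(self, entries: Mapping[str, str] | None = None, **kw: str):
        merged: dict[str, str] = dict(entries or {})
        merged.update(kw)
        for key, label in merged.items():
            if key not in _ENTITY_RANK:
                raise GrammarError(f"unknown entity key {key!r}")
            if not isinstance(label, str) or not _LABEL_RE.match(label):
                raise GrammarError(
                    f"entity {key!r} label {label!r} must be non-empty alphanumeric"
                )
        super().__init__(
            sorted(merged.items(), key=lambda kv: _ENTITY_RANK[kv[0]])
        )

    def issubset(self, other: Mapping[str, str]) -> bool:
        return all(other.get(k) == v for k, v in self.items())

    def chain(self) -> str:
        """Serialized ``key-label`` chain, e.g. ``sub-01_task-rest``."""
        return "_".join(f"{k}-{v}" for k, v in self.items())


@dataclass(frozen=True)
class BIDSPath:
    """Parsed identity of one file inside a BIDS tree."""

    entities: EntitySet
    suffix: str
    extension: str
    datatype: str | None = None

    def __post_init__(self) -> None:
        allowed = SUFFIX_EXTENSIONS.get(self.suffix)
        if allowed is None:
            raise InvariantError(f"unknown suffix {self.suffix!r}")
        if self.extension not in allowed:
            raise InvariantError(
                f"suffix {self.suffix!r} incompatible with extension "
                f"{self.extension!r} (allowed: {sorted(allowed)})"
            )
        if self.datatype is not None and self.datatype not in DATATYPES:
            raise InvariantError(f"unknown datatype {self.datatype!r}")
        if self.suffix in _ROOT_SUFFIXES:
            if self.entities:
                raise InvariantError(
                    f"root-level suffix {self.suffix!r} takes no entities"
                )
        else:
            if "sub" not in self.entities:
                raise InvariantError(
                    f"subject-level suffix {self.suffix!r} requires a sub entity"
                )
            if self.suffix in TASK_SUFFIXES and "task" not in self.entities:
                # task-only sidecars at root level are legal (e.g.
                # task-rest_eeg.json); those carry task but no sub and are
                # handled by parse_path before reaching here.
                raise InvariantError(
                    f"suffix {self.suffix!r} requires a task entity"
                )

    @property
    def basename(self) -> str:
        chain = self.entities.chain()
        stem = f"{chain}_{self.suffix}" if chain else self.suffix
        return stem + self.extension

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return self.basename


@dataclass(frozen=True)
class SidecarPath:
    """A JSON sidecar that may sit above the subject level.

    Unlike :class:`BIDSPath`, its entity set may lack ``sub`` (a root-level
    ``task-rest_eeg.json`` applies to every subject's rest recording).
    """

    entities: EntitySet
    suffix: str
    relpath: str


@dataclass
class Recording:
    """Continuous multichannel signal with channel metadata and events.

    ``samples`` is a ``(n_channels, n_samples)`` float array of physical
    values (by default microvolts).  Events are ``(onset_s, duration_s,
    description)`` triples with onsets inside the recording.
    """

    channel_names: list[str]
    sampling_frequency: float
    samples: np.ndarray
    channel_types: list[str] = field(default_factory=list)
    channel_units: list[str] = field(default_factory=list)
    events: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise InvariantError("samples must be a channels x n_samples matrix")
        n_ch = self.samples.shape[0]
        if len(self.channel_names) != n_ch:
            raise InvariantError("channel_names length must match sample rows")
        if len(set(self.channel_names)) != n_ch:
            raise InvariantError("channel names must be unique")
        if not self.sampling_frequency > 0:
            raise InvariantError("sampling_frequency must be positive")
        if not self.channel_types:
            self.channel_types = ["EEG"] * n_ch
        if not self.channel_units:
            self.channel_units = ["µV"] * n_ch
        if len(self.channel_types) != n_ch or len(self.channel_units) != n_ch:
            raise InvariantError("per-channel metadata length mismatch")
        end = self.duration
        for onset, dur, _ in self.events:
            if onset < 0 or dur < 0 or onset > end:
                raise InvariantError(
                    f"event at {onset}s (duration {dur}s) outside [0, {end}s]"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_frequency


@dataclass
class IndexEntry:
    """One file in a dataset index; ``parsed`` is None when unparseable."""

    relpath: str
    parsed: BIDSPath | SidecarPath | None
    error: str | None = None

    @property
    def unparseable(self) -> bool:
        return self.parsed is None


@dataclass
class DatasetIndex:
    """Deterministic (sorted) listing of a BIDS tree."""

    root: Path
    root_files: list[IndexEntry] = field(default_factory=list)
    subject_files: dict[str, list[IndexEntry]] = field(default_factory=dict)
    container_dirs: list[str] = field(default_factory=list)

    def all_entries(self) -> Iterator[IndexEntry]:
        yield from self.root_files
        for entries in self.subject_files.values():
            yield from entries


_SUB_DIR_RE = re.compile(r"^sub-([A-Za-z0-9]+)$")
_SES_DIR_RE = re.compile(r"^ses-([A-Za-z0-9]+)$")


def _split_name(name: str) -> tuple[str, str]:
    """Split a basename into (stem, extension-with-dot)."""
    if "." not in name:
        return name, ""
    stem, _, ext = name.partition(".")
    return stem, "." + ext


def _parse_stem(stem: str) -> tuple[EntitySet, str]:
    """Parse ``sub-01_task-rest_eeg`` into entities + suffix, enforcing order."""
    if stem in SUFFIX_EXTENSIONS:  # dataset_description contains an underscore
        return EntitySet({}), stem
    parts = stem.split("_")
    suffix = parts[-1]
    entities: dict[str, str] = {}
    last_rank = -1
    for token in parts[:-1]:
        key, dash, label = token.partition("-")
        if not dash:
            raise GrammarError(f"token {token!r} is not an entity key-value pair")
        if key not in _ENTITY_RANK:
            raise GrammarError(f"unknown entity key {key!r} in {stem!r}")
        if key in entities:
            raise GrammarError(f"duplicate entity key {key!r} in {stem!r}")
        rank = _ENTITY_RANK[key]
        if rank <= last_rank:
            raise GrammarError(
                f"entity {key!r} out of canonical order "
                f"({' < '.join(ENTITY_ORDER)}) in {stem!r}"
            )
        last_rank = rank
        if not _LABEL_RE.match(label):
            raise GrammarError(f"entity {key!r} has invalid label {label!r}")
        entities[key] = label
    if suffix not in SUFFIX_EXTENSIONS:
        raise GrammarError(f"unknown or missing suffix {suffix!r} in {stem!r}")
    return EntitySet(entities), suffix


def parse_path(relative_path: str) -> BIDSPath:
    """Parse a POSIX-style path relative to the dataset root.

    Enforces canonical entity order, suffix/extension compatibility, and
    agreement between directory-embedded ``sub``/``ses`` labels and the
    filename entities.  Raises :class:`GrammarError` on any violation.
    """
    p = PurePosixPath(relative_path)
    if p.is_absolute() or any(part in ("..", ".") for part in p.parts):
        raise GrammarError(f"path {relative_path!r} must be relative and plain")
    *dirs, name = p.parts
    stem, ext = _split_name(name)
    entities, suffix = _parse_stem(stem)

    dir_sub = dir_ses = None
    datatype: str | None = None
    for i, d in enumerate(dirs):
        if i == 0:
            m = _SUB_DIR_RE.match(d)
            if not m:
                raise GrammarError(f"directory {d!r} is not a sub-<label> directory")
            dir_sub = m.group(1)
        elif i == 1 and (m := _SES_DIR_RE.match(d)):
            dir_ses = m.group(1)
        elif d in DATATYPES and i == len(dirs) - 1:
            datatype = d
        else:
            raise GrammarError(f"unexpected directory {d!r} in {relative_path!r}")

    if dirs:
        if entities.get("sub") != dir_sub:
            raise GrammarError(
                f"filename sub-{entities.get('sub')} does not match directory "
                f"sub-{dir_sub} in {relative_path!r}"
            )
        if dir_ses is not None and entities.get("ses") != dir_ses:
            raise GrammarError(
                f"filename ses-{entities.get('ses')} does not match directory "
                f"ses-{dir_ses} in {relative_path!r}"
            )
        if dir_ses is None and "ses" in entities:
            raise GrammarError(
                f"filename carries ses-{entities['ses']} but path has no "
                f"session directory: {relative_path!r}"
            )
    elif "sub" in entities:
        raise GrammarError(
            f"subject file {relative_path!r} must live under sub-{entities['sub']}/"
        )

    try:
        return BIDSPath(entities, suffix, ext, datatype)
    except InvariantError as exc:
        raise GrammarError(str(exc)) from exc


def parse_root_sidecar(name: str) -> SidecarPath:
    """Parse a root-level JSON sidecar such as ``task-rest_eeg.json``.

    These carry entities without ``sub`` and participate in inheritance.
    """
    stem, ext = _split_name(name)
    if ext != ".json":
        raise GrammarError(f"root sidecar {name!r} must be .json")
    entities, suffix = _parse_stem(stem)
    return SidecarPath(entities, suffix, name)


def build_path(p: BIDSPath) -> str:
    """Serialize a :class:`BIDSPath` to its canonical relative path.

    Left inverse of :func:`parse_path`: ``parse_path(build_path(p)) == p``
    for every invariant-satisfying path.
    """
    if p.suffix in _ROOT_SUFFIXES:
        return p.basename
    parts = [f"sub-{p.entities['sub']}"]
    if "ses" in p.entities:
        parts.append(f"ses-{p.entities['ses']}")
    if p.datatype:
        parts.append(p.datatype)
    parts.append(p.basename)
    return "/".join(parts)


def index_dataset(root: str | Path) -> DatasetIndex:
    """Walk a dataset tree into a deterministic, lexicographically sorted index.

    Files that fail the grammar are retained with an ``unparseable`` flag so
    the validator can report them; container directories (sourcedata,
    stimuli, code) are recorded by name but their contents never parsed.
    """
    root = Path(root)
    if not root.is_dir():
        raise IOError(f"dataset root {root} does not exist")
    index = DatasetIndex(root=root)

    for child in sorted(root.iterdir(), key=lambda c: c.name):
        if child.is_dir():
            if child.name in CONTAINER_DIRS:
                index.container_dirs.append(child.name)
            elif _SUB_DIR_RE.match(child.name):
                label = child.name.split("-", 1)[1]
                index.subject_files[label] = _index_subject(root, child)
            else:
                index.root_files.append(
                    IndexEntry(child.name, None, f"unexpected directory {child.name!r}")
                )
            continue
        name = child.name
        entry: IndexEntry
        try:
            entry = IndexEntry(name, parse_path(name))
        except GrammarError:
            try:
                entry = IndexEntry(name, parse_root_sidecar(name))
            except GrammarError as exc:
                entry = IndexEntry(name, None, str(exc))
        index.root_files.append(entry)
    return index


def _index_subject(root: Path, subdir: Path) -> list[IndexEntry]:
    entries: list[IndexEntry] = []
    for path in sorted(subdir.rglob("*"), key=lambda c: str(c)):
        if path.is_dir():
            continue
        rel = path.relative_to(root).as_posix()
        try:
            entries.append(IndexEntry(rel, parse_path(rel)))
        except GrammarError as exc:
            entries.append(IndexEntry(rel, None, str(exc)))
    return entries
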