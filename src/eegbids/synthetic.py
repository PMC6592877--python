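"""Deterministic synthetic recordings, datasets, and seeded-violation mutants.

The generator replaces any external download in tests: multichannel
sinusoid-plus-noise recordings with event markers, full valid BIDS trees
(via the converter, so they exercise the production write path), and a
mutation operator that injects exactly one validator-catalog violation into
a pristine tree.  Everything is seeded; no wall clock reaches the outputs,
so a fixed seed yields a byte-identical tree.  The signals are structural
stand-ins, not physiological EEG (no 1/f spectrum, artifacts or ERPs).
"""

from __future__ import annotations

import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import sidecars
from .converter import EEGMetadata, convert_recording, ensure_dataset_description
from .core import DatasetIndex, EntitySet, Recording, index_dataset
from .errors import UnknownCodeError
from .validator import RULE_CATALOG

#: Default spectral content: alpha-band sinusoid dominating, line-ish hum.
DEFAULT_COMPONENTS: tuple[tuple[float, float], ...] = ((10.0, 40.0), (22.0, 12.0))

#: 10–20-style montage on a unit sphere (meters); synthetic positions.
MONTAGE_1020: dict[str, tuple[float, float, float]] = {
    "Fp1": (-0.03, 0.09, 0.01),
    "Fp2": (0.03, 0.09, 0.01),
    "F3": (-0.05, 0.05, 0.06),
    "F4": (0.05, 0.05, 0.06),
    "C3": (-0.06, 0.0, 0.06),
    "C4": (0.06, 0.0, 0.06),
    "P3": (-0.05, -0.05, 0.06),
    "P4": (0.05, -0.05, 0.06),
    "O1": (-0.03, -0.09, 0.01),
    "O2": (0.03, -0.09, 0.01),
    "F7": (-0.07, 0.05, 0.0),
    "F8": (0.07, 0.05, 0.0),
    "T7": (-0.08, 0.0, 0.0),
    "T8": (0.08, 0.0, 0.0),
    "Fz": (0.0, 0.06, 0.06),
    "Cz": (0.0, 0.0, 0.09),
    "Pz": (0.0, -0.06, 0.06),
}

_CHANNEL_POOL = list(MONTAGE_1020)


def make_recording(
    n_channels: int = 8,
    sfreq: float = 250.0,
    duration_s: float = 4.0,
    components: Sequence[tuple[float, float]] = DEFAULT_COMPONENTS,
    noise_sd_uv: float = 5.0,
    n_events: int = 4,
    seed: int = 0,
) -> Recording:
    """Sinusoid + Gaussian-noise recording with uniformly placed events.

    Each channel is the sum of the requested (frequency Hz, amplitude µV)
    components with a channel-specific phase, plus white noise.  Identical
    seeds produce identical recordings.
    """
    if n_channels < 1 or sfreq <= 0 or duration_s <= 0:
        raise ValueError("n_channels >= 1, sfreq > 0, duration_s > 0 required")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration_s * sfreq))
    t = np.arange(n_samples) / sfreq

    names = [
        _CHANNEL_POOL[i] if i < len(_CHANNEL_POOL) else f"EEG{i + 1:03d}"
        for i in range(n_channels)
    ]
    samples = np.zeros((n_channels, n_samples))
    for c in range(n_channels):
        phase = rng.uniform(0, 2 * np.pi)
        for freq, amp in components:
            samples[c] += amp * np.sin(2 * np.pi * freq * t + phase)
        if noise_sd_uv > 0:
            samples[c] += rng.normal(0.0, noise_sd_uv, n_samples)

    events = []
    if n_events > 0 and n_samples > 1:
        positions = np.sort(
            rng.choice(np.arange(n_samples), size=min(n_events, n_samples),
                       replace=False)
        )
        for k, pos in enumerate(positions):
            events.append((pos / sfreq, 0.0, f"stim{k % 2 + 1}"))

    return Recording(
        channel_names=names,
        sampling_frequency=sfreq,
        samples=samples,
        events=events,
    )


def _write_electrodes(root: Path, sub: str, channel_names: Sequence[str]) -> None:
    rows = []
    for name in channel_names:
        x, y, z = MONTAGE_1020.get(name, (0.0, 0.0, 0.0))
        rows.append({"name": name, "x": str(x), "y": str(y), "z": str(z)})
    # the reference electrode is listed here but is deliberately not a channel
    rows.append({"name": "REF", "x": "0.0", "y": "-0.02", "z": "0.1"})
    table = pd.DataFrame(rows, columns=["name", "x", "y", "z"])
    sidecars.write_table(
        table,
        root / f"sub-{sub}" / "eeg" / f"sub-{sub}_electrodes.tsv",
        sidecars.ELECTRODES_SCHEMA,
    )
    sidecars.write_json(
        {
            "EEGCoordinateSystem": "CapTrak-like synthetic",
            "EEGCoordinateUnits": "m",
            "EEGCoordinateSystemDescription": (
                "Synthetic 10-20-style positions on a unit-sphere head model; "
                "generated, not digitized."
            ),
        },
        root / f"sub-{sub}" / "eeg" / f"sub-{sub}_coordsystem.json",
    )


def make_dataset(
    root: str | Path,
    n_subjects: int = 2,
    tasks: Sequence[str] = ("rest",),
    format: str = "brainvision",
    seed: int = 0,
    n_channels: int = 8,
    sfreq: float = 250.0,
    duration_s: float = 4.0,
) -> DatasetIndex:
    """Write a complete, validator-clean EEG-BIDS tree.

    One recording per subject × task, converted through the production
    converter, plus dataset_description.json, participants.tsv, README, and
    per-subject electrodes/coordsystem files.
    """
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        raise FileExistsError(f"{root} is not empty")
    root.mkdir(parents=True, exist_ok=True)

    ensure_dataset_description(root, name="Synthetic EEG-BIDS fixture")
    (root / "README").write_text(
        "Synthetic EEG-BIDS dataset generated by eegbids for testing.\n",
        encoding="utf-8",
    )

    for s in range(1, n_subjects + 1):
        sub = f"{s:02d}"
        for task in tasks:
            rec = make_recording(
                n_channels=n_channels,
                sfreq=sfreq,
                duration_s=duration_s,
                seed=(seed * 10007 + s * 101 + zlib.crc32(task.encode()) % 97)
                % (2**31),
            )
            convert_recording(
                rec,
                EntitySet(sub=sub, task=task),
                EEGMetadata(
                    TaskName=task,
                    EEGReference="Cz",
                    PowerLineFrequency=50,
                    SoftwareFilters="n/a",
                ),
                root,
                format=format,
            )
        _write_electrodes(root, sub, _channel_names(n_channels))
    return index_dataset(root)


def _channel_names(n: int) -> list[str]:
    return [
        _CHANNEL_POOL[i] if i < len(_CHANNEL_POOL) else f"EEG{i + 1:03d}"
        for i in range(n)
    ]


def _first(root: Path, pattern: str) -> Path:
    hits = sorted(root.rglob(pattern))
    if not hits:
        raise FileNotFoundError(f"no {pattern} under {root}")
    return hits[0]


def inject_violation(root: str | Path, code: str) -> str:
    """Minimally mutate a pristine tree so the validator reports ``code``.

    Returns a one-line description of the mutation performed.
    """
    root = Path(root)
    if code not in RULE_CATALOG:
        raise UnknownCodeError(f"{code!r} not in the validator catalog")

    if code == "R1":
        target = root / "dataset_description.json"
        target.unlink()
        return "deleted dataset_description.json"

    if code == "R2":
        target = _first(root, "sub-*_channels.tsv")
        target.unlink()
        return f"deleted {target.name}"

    if code == "R3":
        target = _first(root, "*_coordsystem.json")
        target.unlink()
        return f"deleted {target.name} (unpairing electrodes.tsv)"

    if code == "R4":
        target = _first(root, "sub-*_events.tsv")
        target.unlink()
        return f"deleted {target.name}"

    if code == "R5":
        target = _first_data(root)
        bad = target.with_suffix(".xyz")
        target.rename(bad)
        return f"renamed {target.name} -> {bad.name}"

    if code == "R6":
        target = _first_data(root)
        bad = target.with_suffix(".bdf")
        target.rename(bad)
        return f"renamed {target.name} -> {bad.name}"

    if code == "R7":
        target = _first(root, "sub-*_channels.tsv")
        table = sidecars.read_table(target)
        sidecars.write_table(table.iloc[:-1], target)
        return f"dropped last row of {target.name}"

    if code == "R8":
        target = _first(root, "sub-*_channels.tsv")
        table = sidecars.read_table(target)
        table.loc[0, "name"] = table.loc[0, "name"] + "X"
        sidecars.write_table(table, target)
        return f"renamed first channel in {target.name}"

    if code == "R9":
        target = _first(root, "sub-*_electrodes.tsv")
        table = sidecars.read_table(target)
        sidecars.write_table(table.iloc[1:], target)
        return f"dropped first electrode row of {target.name}"

    if code == "R10":
        target = _first(root, "sub-*_eeg.json")
        doc = sidecars.read_json(target)
        doc.pop("EEGReference", None)
        sidecars.write_json(doc, target)
        return f"removed EEGReference from {target.name}"

    if code == "R11":
        target = _first(root, "sub-*_events.tsv")
        table = sidecars.read_table(target)
        if len(table) == 0:
            table = pd.DataFrame({"onset": ["-1.0"], "duration": ["0.0"]})
        else:
            table.loc[0, "onset"] = "-1.0"
        sidecars.write_table(table, target)
        return f"set a negative onset in {target.name}"

    if code == "R12":
        sub_dir = sorted(root.glob("sub-*"))[0]
        bad = sub_dir / "eeg" / "notbids.txt"
        bad.write_text("stray\n", encoding="utf-8")
        return f"created {bad.relative_to(root)}"

    if code == "R13":
        target = _first(root, "sub-*_channels.tsv")
        table = sidecars.read_table(target)
        table.loc[0, "status"] = "meh"
        sidecars.write_table(table, target)
        return f"set status 'meh' in {target.name}"

    if code == "R14":
        target = _first(root, "sub-*_events.tsv")
        table = sidecars.read_table(target)
        if len(table) == 0:
            table = pd.DataFrame(
                {"onset": ["0.0"], "duration": ["0.0"]}
            )
        table["stim_file"] = "ghost.png"
        sidecars.write_table(table, target)
        return f"pointed stim_file at ghost.png in {target.name}"

    raise UnknownCodeError(code)  # pragma: no cover


def _first_data(root: Path) -> Path:
    """First primary data file in the tree, whichever official format."""
    for pattern in ("sub-*_eeg.edf", "sub-*_eeg.vhdr"):
        hits = sorted(root.rglob(pattern))
        if hits:
            return hits[0]
    raise FileNotFoundError(f"no EEG data file under {root}")
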