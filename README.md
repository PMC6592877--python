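# eegbids

A toolkit for organizing continuous EEG recordings under the Brain Imaging
Data Structure (BIDS). It is aimed at EEG practitioners who need to turn raw
recordings into standard-compliant datasets and at pipeline authors who need
to check such datasets programmatically.

BIDS identifies every file by a chain of entity key–value pairs embedded in
its name, e.g.

```
sub-01/eeg/sub-01_task-rest_eeg.vhdr
```

with canonical entity order `sub < ses < task < acq < run`, a suffix naming
the file's role (`eeg`, `channels`, `events`, …) and an extension naming its
format. Metadata lives beside the data in TSV tables and JSON dictionaries;
JSON sidecars placed high in the tree apply to all data files below unless a
deeper sidecar overrides a key (the Inheritance Principle).

The package provides, as importable modules:

- **`eegbids.core`** — the entity filename grammar (`parse_path`,
  `build_path`), the `Recording` container, and deterministic tree indexing.
- **`eegbids.edf`** — a reader/writer for the European Data Format: fixed-width
  ASCII headers plus 16-bit integer records with per-signal affine
  calibration `p = p_min + (d − d_min)·(p_max − p_min)/(d_max − d_min)`.
- **`eegbids.brainvision`** — a reader/writer for the BrainVision Core Data
  Format triplet (`.vhdr` INI header, `.vmrk` markers, `.eeg` binary payload),
  in `IEEE_FLOAT_32` (default, 32 bits/sample) or `INT_16` encodings.
- **`eegbids.sidecars`** — TSV/JSON schemas and the inheritance resolver.
- **`eegbids.validator`** — a rule engine with a 14-code catalog (missing
  `channels.tsv`, unpaired `electrodes.tsv`/`coordsystem.json`,
  underspecified `eeg.json`, malformed events, …) emitting machine-readable
  issues with `error`/`warning` severities.
- **`eegbids.converter`** — raw recording → validator-clean BIDS subtree.
- **`eegbids.synthetic`** — seeded generator of recordings, whole valid
  datasets, and single-violation mutants for testing.

## Worked example

```python
from eegbids import EEGMetadata, EntitySet, convert_recording, make_recording, validate

rec = make_recording(n_channels=8, sfreq=250.0, duration_s=4.0, seed=7)
meta = EEGMetadata(TaskName="rest", EEGReference="Cz",
                   PowerLineFrequency=50, SoftwareFilters="n/a")
written = convert_recording(rec, EntitySet(sub="01", task="rest"),
                            meta, "study/", format="brainvision")
print("\n".join(written))
print(validate("study/").to_text())
```

prints

```
sub-01/eeg/sub-01_task-rest_eeg.vhdr
sub-01/eeg/sub-01_task-rest_eeg.vmrk
sub-01/eeg/sub-01_task-rest_eeg.eeg
sub-01/eeg/sub-01_task-rest_channels.tsv
sub-01/eeg/sub-01_task-rest_eeg.json
sub-01/eeg/sub-01_task-rest_events.tsv
Summary: 0 error(s), 0 warning(s) -> OK
```

The six written files are the BrainVision triplet plus the three required
sidecars; `dataset_description.json` and `participants.tsv` are created at
the root as needed. Electrode positions are optional, so their absence here
raises no issue; `make_dataset` additionally writes `electrodes.tsv` and
`coordsystem.json` with a synthetic 10–20-style montage.

The same stack is scriptable from a shell:

```sh
eegbids fixture --output ds/ --subjects 2 --tasks rest --seed 1
eegbids validate ds/ --json
eegbids convert --input raw.edf --sub 01 --task rest --output study/
```

`validate` exits 0 only when the tree has no error-severity issues;
warnings never change the exit code.

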