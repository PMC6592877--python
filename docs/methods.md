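# Methods

## The data model

A `Recording` is a `(n_channels, n_samples)` float64 matrix of physical
values (microvolts by default), one sampling frequency shared by all
channels, per-channel names/types/units, and a list of
`(onset_s, duration_s, description)` events with onsets inside
`[0, n_samples / sfreq]`. It is deliberately minimal: a channel here is the
amplifier + ADC chain that produced one stored time series, which is why
reference and ground *electrodes* can appear in `electrodes.tsv` without a
corresponding channel row, and why the validator's electrode-coverage check
(R9) flags missing electrodes for EEG channels but never flags extra
electrodes.

## Filename grammar

Entities are key–value tokens from `{sub, ses, task, acq, run}` in that
fixed order, labels restricted to `[A-Za-z0-9]+`, filenames treated
case-sensitively; both choices favor portability across filesystems over
permissiveness. `parse_path` is total: every string yields either a
`BIDSPath` or a `GrammarError` (out-of-order or duplicate entities, unknown
keys, directory/filename entity disagreement, suffix/extension
incompatibility). `build_path` is its right inverse by construction, which
the suite checks with a derandomized 250-case property test. Datatype
directories are limited to `eeg` and `anat`; `sourcedata`, `stimuli`,
`code` and `derivatives` are indexed by name but their contents are never
parsed.

## EDF codec

Continuous EDF only: a 256-byte fixed header, 256 ASCII bytes per signal,
then records of 16-bit little-endian two's-complement integers. The
calibration is affine per signal; the worst representable error of a write →
read cycle is one quantization step `(p_max − p_min)/(d_max − d_min)`.

Numerical choices that matter:

- **Physical range.** Per channel, symmetric `[−m, m]` with
  `m = 1.01·max|x|` (1 µV for an all-zero channel), then *snapped upward*
  to the nearest value whose negation prints in 8 ASCII characters. EDF
  stores calibration as 8-character fields, so quantization must use the
  value the header will actually carry; snapping upward guarantees no
  sample is clipped and keeps the round-trip bound intact.
- **Records.** `record_duration` defaults to 1 s; for non-integer sampling
  rates the smallest k ≤ 10 s with `sfreq·k` integral is used, otherwise
  the write is refused. A final partial record is padded with each
  channel's last sample and counted in `n_records`.
- **Start stamp.** `01.01.85 / 00.00.00` unless the caller supplies one:
  acquisition time carries no information for synthetic data and a fixed
  epoch makes generated trees byte-identical across runs.
- EDF+ annotation channels are neither written (events belong in
  `events.tsv`) nor interpreted on read.

## BrainVision codec

The triplet is written with LF line endings, UTF-8 (Latin-1 fallback on
read), little-endian payload, and only the BINARY/MULTIPLEXED layout;
VECTORIZED and ASCII are rejected with a clear error. `IEEE_FLOAT_32` is
the default encoding — physical values stored verbatim, so write → read is
bit-exact at single precision — with `INT_16` available
(`resolution = max|x|/32767` per channel). Markers are 1-based in samples;
BIDS event onsets are 0-based seconds; the mapping
`position = round(onset·sfreq) + 1` is an exact inverse for onsets on the
sample grid, which is where the synthetic generator places them. Commas
inside marker descriptions are escaped as `\1`, the format's convention.

## Sidecars and inheritance

TSVs are read with all cells kept as strings and `n/a` as the only
missing-value token, making the write → read round trip lossless; numeric
interpretation happens at the point of use. A JSON sidecar applies to a
data file iff its suffix matches and its entity set is a subset of the
target's; applicable sidecars are merged root-first with **shallow**
(top-level key) override — a deeper `SoftwareFilters` object replaces the
root one wholesale rather than deep-merging, because key-level override
semantics are predictable and order-independent of filesystem enumeration.
Two applicable sidecars at the same directory depth are an error
(`AmbiguityError`) rather than a silent choice.

The required `eeg.json` keys are `TaskName`, `SamplingFrequency`,
`EEGReference`, `PowerLineFrequency`, `SoftwareFilters` — the minimal set
covering the task and the recording system, and what validator rule R10
enforces.

## Validator

Fourteen rules with stable codes R1–R14; severities follow the standard's
modal verbs ("must" → error, "should"/"can" → warning), so e.g. a missing
`channels.tsv` (R2) is an error while a missing `events.tsv` (R4) is a
warning, and the `ok` flag depends only on errors. Header-content checks
(R7 channel count, R8 names/order, the R10 sampling-frequency comparison at
1e−6 relative tolerance) open EDF and BrainVision headers only; `.set` and
`.bdf` files are recognized by extension and never parsed. Malformed
content becomes an issue, never an exception; issues are ordered by
(path, code, message) so reports are deterministic; validation is
read-only, which the suite asserts by tree checksum. Unsorted event onsets
are deliberately not an issue — the standard does not require ordering.

## Converter

`convert_recording` writes the data file (BrainVision/IEEE_FLOAT_32 by
default, the higher-precision official format; EDF on request, or a byte
copy when `copy_through` and the source is already an allowed format),
`channels.tsv` from the recording's channel metadata, `eeg.json` from the
user metadata with `SamplingFrequency` and channel counts filled from the
data, and `events.tsv` (the `trial_type` column is omitted entirely when no
event has a description, rather than written all-`n/a`). Everything is
staged in a temporary directory and moved into place at the end, so a
failing write leaves the tree untouched. `participants.tsv` grows one row
per subject, idempotently, with `n/a` backfill when later subjects
introduce new columns. Existing targets are refused without the overwrite
flag. The keystone contract — conversion output always validates with zero
errors — is asserted over 25 randomized recordings in the suite.

## Synthetic generator

`make_recording` sums the requested `(frequency, amplitude)` sinusoids with
one random phase per channel, adds white Gaussian noise, and places events
uniformly on the sample grid. Defaults (8 channels, 250 Hz, 4 s, a 40 µV
10 Hz component with 12 µV at 22 Hz, 5 µV noise, 4 events) give
alpha-dominated signals of realistic EEG magnitude while keeping every test
well under a second. All randomness flows through one seeded
`numpy.random.Generator`; task labels are folded in via CRC32, never
Python's salted `hash`; no wall clock reaches any output, so a fixed seed
yields a byte-identical tree (asserted by checksum). The sampled peak of a
noiseless sinusoid is bounded by `amp·cos(π·f/sfreq) ≤ peak ≤ amp` — the
crest can fall between samples — and the suite asserts exactly that bound.

These signals are structural stand-ins, not physiology: no 1/f spectrum,
artifacts, ERPs, or inter-channel correlation. Passing tests therefore
demonstrate the formats, grammar, metadata and validation machinery on
realistic *structure*, not that any analysis of real EEG would succeed.
Electrode coordinates are 10–20-style labels on a unit-sphere head model in
meters under the documented synthetic name "CapTrak-like synthetic".

`inject_violation` applies the minimal mutation triggering one validator
code (delete a file, drop a table row, rename an extension, poison a status
cell, point `stim_file` at a ghost). Some mutations legitimately cascade —
renaming a channel (R8) also uncovers a missing electrode row (R9) — so
soundness is stated as "the injected code is reported and pristine trees
never report it", not as single-issue reports.

## Sizes and limitations

The full suite (138 tests) runs in a few seconds; the acceptance script in
under two: recordings of 1–16 channels, 0.5–10 s at 100–1000 Hz are ample
to pin down format arithmetic, which is size-independent. Known
limitations: no EDF+ discontinuous files, no per-signal sampling rates, no
segmented BrainVision files, no HED event annotation, no content parsing of
EEGLAB/Biosemi files, and no validation of anatomical MRI content beyond
directory placement.
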