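"""Converter: file plan, participants handling, keystone validate-clean."""

import numpy as np
import pytest

from eegbids import edf
from eegbids.converter import EEGMetadata, append_participant, convert_recording
from eegbids.core import EntitySet
from eegbids.errors import CollisionError
from eegbids.sidecars import NA, read_table
from eegbids.synthetic import make_recording
from eegbids.validator import validate

META = EEGMetadata(
    TaskName="rest", EEGReference="Cz", PowerLineFrequency=50,
    SoftwareFilters="n/a",
)


def test_brainvision_conversion_writes_six_files(tmp_path, recording):
    written = convert_recording(
        recording, EntitySet(sub="01", task="rest"), META, tmp_path
    )
    assert sorted(written) == [
        "sub-01/eeg/sub-01_task-rest_channels.tsv",
        "sub-01/eeg/sub-01_task-rest_eeg.eeg",
        "sub-01/eeg/sub-01_task-rest_eeg.json",
        "sub-01/eeg/sub-01_task-rest_eeg.vhdr",
        "sub-01/eeg/sub-01_task-rest_eeg.vmrk",
        "sub-01/eeg/sub-01_task-rest_events.tsv",
    ]
    assert (tmp_path / "dataset_description.json").is_file()
    assert (tmp_path / "participants.tsv").is_file()


def test_events_tsv_content(tmp_path):
    r = make_recording(n_channels=2, sfreq=100, duration_s=4, seed=0, n_events=0)
    r.events = [(1.0, 0.0, "go"), (2.5, 0.0, "stop")]
    convert_recording(r, EntitySet(sub="01", task="rest"), META, tmp_path)
    table = read_table(tmp_path / "sub-01/eeg/sub-01_task-rest_events.tsv")
    assert list(table["onset"]) == ["1.0", "2.5"]
    assert list(table["trial_type"]) == ["go", "stop"]


def test_trial_type_omitted_when_no_descriptions(tmp_path):
    r = make_recording(n_channels=2, sfreq=100, duration_s=2, seed=0, n_events=0)
    r.events = [(0.5, 0.0, "")]
    convert_recording(r, EntitySet(sub="01", task="rest"), META, tmp_path)
    table = read_table(tmp_path / "sub-01/eeg/sub-01_task-rest_events.tsv")
    assert "trial_type" not in table.columns


def test_copy_through_is_byte_identical(tmp_path, recording):
    src = tmp_path / "orig.edf"
    edf.write_edf(recording, src)
    convert_recording(
        src, EntitySet(sub="01", task="rest"), META, tmp_path / "ds",
        copy_through=True,
    )
    out = tmp_path / "ds/sub-01/eeg/sub-01_task-rest_eeg.edf"
    assert out.read_bytes() == src.read_bytes()


def test_collision_refused_without_overwrite(tmp_path, recording):
    ent = EntitySet(sub="01", task="rest")
    convert_recording(recording, ent, META, tmp_path)
    with pytest.raises(CollisionError):
        convert_recording(recording, ent, META, tmp_path)
    convert_recording(recording, ent, META, tmp_path, overwrite=True)


def test_failed_conversion_leaves_no_partial_files(tmp_path):
    r = make_recording(n_channels=2, sfreq=100, duration_s=2, seed=0)
    r.samples[0, 0] = np.inf  # EDF writer must refuse non-finite data
    with pytest.raises(Exception):
        convert_recording(
            r, EntitySet(sub="01", task="rest"), META, tmp_path, format="edf"
        )
    assert not (tmp_path / "sub-01").exists() or not any(
        (tmp_path / "sub-01").rglob("*_eeg.*")
    )


def test_participants_backfill(tmp_path):
    append_participant(tmp_path, "01")
    append_participant(tmp_path, "01")  # idempotent
    append_participant(tmp_path, "02", {"age": "31"})
    table = read_table(tmp_path / "participants.tsv")
    assert list(table["participant_id"]) == ["sub-01", "sub-02"]
    assert list(table["age"]) == [NA, "31"]


def test_signal_fidelity_edf(tmp_path, recording):
    convert_recording(
        recording, EntitySet(sub="01", task="rest"), META, tmp_path, format="edf"
    )
    back = edf.read_edf(tmp_path / "sub-01/eeg/sub-01_task-rest_eeg.edf")
    h = edf.read_header(tmp_path / "sub-01/eeg/sub-01_task-rest_eeg.edf")
    for i, sig in enumerate(h.signals):
        err = np.max(np.abs(back.samples[i, : recording.n_samples]
                            - recording.samples[i]))
        assert err <= sig.quantization_step


@pytest.mark.parametrize("fmt", ["brainvision", "edf"])
def test_keystone_convert_then_validate(tmp_path, fmt):
    """A converted recording plus sidecars always passes validation."""
    rng = np.random.default_rng(42)
    for seed in range(5):
        r = make_recording(
            n_channels=int(rng.integers(2, 17)),
            sfreq=float(rng.choice([100, 250, 500, 1000])),
            duration_s=float(rng.uniform(2, 10)),
            seed=seed,
        )
        root = tmp_path / f"{fmt}-{seed}"
        convert_recording(
            r, EntitySet(sub="01", task="rest"), META, root, format=fmt
        )
        report = validate(root)
        assert report.n_errors == 0, report.to_text()
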