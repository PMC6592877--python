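"""Entity grammar, path round trips, and dataset indexing."""

import pytest
from hypothesis import given, settings, strategies as st

from eegbids.core import (
    BIDSPath,
    EntitySet,
    build_path,
    index_dataset,
    parse_path,
)
from eegbids.errors import GrammarError, InvariantError

LABEL = st.text(alphabet="abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789",
                min_size=1, max_size=6)


@pytest.mark.parametrize(
    "path, entities, datatype, suffix, ext",
    [
        ("sub-XX/eeg/sub-XX_task-YY_channels.tsv",
         {"sub": "XX", "task": "YY"}, "eeg", "channels", ".tsv"),
        ("dataset_description.json", {}, None, "dataset_description", ".json"),
        ("sub-01/eeg/sub-01_task-rest_eeg.edf",
         {"sub": "01", "task": "rest"}, "eeg", "eeg", ".edf"),
        ("sub-01/ses-02/eeg/sub-01_ses-02_task-med_eeg.vhdr",
         {"sub": "01", "ses": "02", "task": "med"}, "eeg", "eeg", ".vhdr"),
        ("participants.tsv", {}, None, "participants", ".tsv"),
        ("README", {}, None, "README", ""),
    ],
)
def test_parse_path_examples(path, entities, datatype, suffix, ext):
    p = parse_path(path)
    assert dict(p.entities) == entities
    assert p.datatype == datatype
    assert p.suffix == suffix
    assert p.extension == ext


@pytest.mark.parametrize(
    "path",
    [
        "sub-01/eeg/sub-01_run-1_task-rest_eeg.edf",  # run before task
        "sub-01/eeg/sub-02_task-rest_eeg.edf",        # dir/filename mismatch
        "sub-01/eeg/sub-01_task-rest_nonsense.tsv",   # unknown suffix
        "sub-01/eeg/sub-01_task-rest_eeg.wav",        # disallowed extension
        "sub-01/eeg/sub-01_foo-x_task-rest_eeg.edf",  # unknown entity key
        "sub-01/eeg/sub-01_task-rest_task-other_eeg.edf",  # duplicate entity
        "sub-01_task-rest_eeg.edf",                   # subject file at root
        "sub-01/eeg/sub-01_task-_eeg.edf",            # empty label
        "sub-01/anat/deeper/sub-01_task-a_eeg.edf",   # junk directory level
    ],
)
def test_parse_path_rejections(path):
    with pytest.raises(GrammarError):
        parse_path(path)


def test_entity_set_canonical_order():
    es = EntitySet({"task": "rest", "sub": "01", "run": "1"})
    assert list(es) == ["sub", "task", "run"]
    assert es.chain() == "sub-01_task-rest_run-1"


def test_build_path_examples():
    p = BIDSPath(EntitySet(sub="XX", task="YY"), "eeg", ".edf", "eeg")
    assert build_path(p) == "sub-XX/eeg/sub-XX_task-YY_eeg.edf"
    p2 = BIDSPath(EntitySet(sub="01", ses="02", task="med"), "eeg", ".vhdr", "eeg")
    assert build_path(p2) == "sub-01/ses-02/eeg/sub-01_ses-02_task-med_eeg.vhdr"


def test_suffix_extension_compatibility_enforced():
    with pytest.raises(InvariantError):
        BIDSPath(EntitySet(sub="01", task="a"), "channels", ".edf", "eeg")
    with pytest.raises(InvariantError):
        BIDSPath(EntitySet(sub="01", task="a"), "coordsystem", ".tsv", "eeg")


@st.composite
def bids_paths(draw):
    entities = {"sub": draw(LABEL), "task": draw(LABEL)}
    if draw(st.booleans()):
        entities["ses"] = draw(LABEL)
    if draw(st.booleans()):
        entities["acq"] = draw(LABEL)
    if draw(st.booleans()):
        entities["run"] = draw(LABEL)
    suffix, ext = draw(
        st.sampled_from(
            [
                ("eeg", ".edf"), ("eeg", ".vhdr"), ("eeg", ".json"),
                ("channels", ".tsv"), ("events", ".tsv"),
            ]
        )
    )
    return BIDSPath(EntitySet(entities), suffix, ext, "eeg")


@settings(max_examples=250, derandomize=True)
@given(p=bids_paths())
def test_parse_build_round_trip(p):
    """parse_path is a left inverse of build_path on grammar-valid paths."""
    q = parse_path(build_path(p))
    assert dict(q.entities) == dict(p.entities)
    assert (q.suffix, q.extension, q.datatype) == (p.suffix, p.extension, p.datatype)


def test_index_dataset_counts(pristine_dataset):
    idx = index_dataset(pristine_dataset)
    assert sorted(idx.subject_files) == ["01", "02"]
    for entries in idx.subject_files.values():
        suffixes = {e.parsed.suffix for e in entries if e.parsed}
        assert {"eeg", "channels", "events", "electrodes", "coordsystem"} <= suffixes
    names = {e.relpath for e in idx.root_files}
    assert "dataset_description.json" in names and "participants.tsv" in names


def test_index_empty_and_missing(tmp_path):
    empty = tmp_path / "empty"
    empty.mkdir()
    idx = index_dataset(empty)
    assert not idx.root_files and not idx.subject_files
    with pytest.raises(IOError):
        index_dataset(tmp_path / "nope")


def test_index_retains_unparseable(pristine_dataset):
    stray = pristine_dataset / "sub-01" / "eeg" / "notbids.txt"
    stray.write_text("x\n")
    idx = index_dataset(pristine_dataset)
    flagged = [e for e in idx.subject_files["01"] if e.unparseable]
    assert [e.relpath for e in flagged] == ["sub-01/eeg/notbids.txt"]


def test_index_is_deterministic(pristine_dataset):
    a = index_dataset(pristine_dataset)
    b = index_dataset(pristine_dataset)
    assert [e.relpath for e in a.all_entries()] == [e.relpath for e in b.all_entries()]
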