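"""BrainVision triplet codec: INI parsing, payload layout, round trips."""

import numpy as np
import pytest

from eegbids.brainvision import (
    parse_ini,
    read_brainvision,
    read_header,
    write_brainvision,
)
from eegbids.errors import FormatError
from eegbids.synthetic import make_recording


def test_parse_ini_sections_and_comments():
    text = "; a comment\n[Common Infos]\nNumberOfChannels=4\n; more\nKey=va=lue\n"
    out = parse_ini(text)
    assert out == {"Common Infos": {"NumberOfChannels": "4", "Key": "va=lue"}}


def test_parse_ini_duplicate_key_last_wins():
    out = parse_ini("[S]\na=1\na=2\n")
    assert out["S"]["a"] == "2"


def test_parse_ini_key_before_section_rejected():
    with pytest.raises(FormatError):
        parse_ini("a=1\n[S]\n")


def test_sampling_interval_microseconds(tmp_path):
    r = make_recording(n_channels=2, sfreq=1000, duration_s=1, seed=0)
    vhdr, _, _ = write_brainvision(r, tmp_path / "x")
    doc = read_header(vhdr)
    assert doc.sampling_interval_us == 1000
    assert doc.sampling_frequency == 1000


def test_float32_payload_size_and_bits(tmp_path):
    r = make_recording(n_channels=3, sfreq=250, duration_s=2, seed=1)
    _, _, eeg = write_brainvision(r, tmp_path / "x")
    assert eeg.stat().st_size == 4 * r.n_channels * r.n_samples
    assert 8 * eeg.stat().st_size / (r.n_channels * r.n_samples) == 32


def test_int16_payload_size(tmp_path):
    r = make_recording(n_channels=3, sfreq=250, duration_s=2, seed=1)
    _, _, eeg = write_brainvision(r, tmp_path / "x", binary_format="INT_16")
    assert eeg.stat().st_size == 2 * r.n_channels * r.n_samples


def test_float32_round_trip_exact_at_single_precision(tmp_path):
    r = make_recording(n_channels=4, sfreq=500, duration_s=2, seed=2)
    vhdr, _, _ = write_brainvision(r, tmp_path / "x")
    back = read_brainvision(vhdr)
    assert back.channel_names == r.channel_names
    assert back.sampling_frequency == r.sampling_frequency
    assert np.array_equal(
        back.samples, r.samples.astype(np.float32).astype(np.float64)
    )


def test_int16_scaling_oracle(tmp_path):
    """Stored integer 100 at resolution 0.5 µV decodes to 50 µV."""
    base = tmp_path / "x"
    (base.with_suffix(".eeg")).write_bytes(np.array([100], dtype="<i2").tobytes())
    (base.with_suffix(".vhdr")).write_text(
        "[Common Infos]\nDataFile=x.eeg\nNumberOfChannels=1\n"
        "SamplingInterval=1000\nDataFormat=BINARY\nDataOrientation=MULTIPLEXED\n"
        "[Binary Infos]\nBinaryFormat=INT_16\n"
        "[Channel Infos]\nCh1=Cz,,0.5,µV\n"
    )
    back = read_brainvision(base.with_suffix(".vhdr"))
    assert back.samples[0, 0] == 50.0


def test_markers_round_trip_on_sample_grid(tmp_path):
    r = make_recording(n_channels=2, sfreq=250, duration_s=4, seed=3, n_events=5)
    vhdr, vmrk, _ = write_brainvision(r, tmp_path / "x")
    text = vmrk.read_text()
    assert text.count("Stimulus") == 5
    assert "Mk1=New Segment" in text
    back = read_brainvision(vhdr)
    # synthetic onsets sit on the sample grid, so the mapping is exact
    assert [e[0] for e in back.events] == [e[0] for e in r.events]
    assert [e[2] for e in back.events] == [e[2] for e in r.events]


def test_triplet_cross_references_closed(tmp_path):
    r = make_recording(n_channels=2, sfreq=100, duration_s=1, seed=4)
    vhdr, vmrk, eeg = write_brainvision(r, tmp_path / "x")
    doc = read_header(vhdr)
    assert doc.data_file == eeg.name
    assert doc.marker_file == vmrk.name
    assert parse_ini(vmrk.read_text())["Common Infos"]["DataFile"] == eeg.name


def test_missing_eeg_sibling_named_in_error(tmp_path):
    r = make_recording(n_channels=2, sfreq=100, duration_s=1, seed=5)
    vhdr, _, eeg = write_brainvision(r, tmp_path / "x")
    eeg.unlink()
    with pytest.raises(FormatError, match="x.eeg"):
        read_brainvision(vhdr)


def test_unsupported_orientation_rejected(tmp_path):
    base = tmp_path / "x"
    base.with_suffix(".vhdr").write_text(
        "[Common Infos]\nDataFile=x.eeg\nNumberOfChannels=1\n"
        "SamplingInterval=1000\nDataOrientation=VECTORIZED\n"
        "[Binary Infos]\nBinaryFormat=INT_16\n[Channel Infos]\nCh1=Cz,,1,µV\n"
    )
    with pytest.raises(FormatError, match="VECTORIZED"):
        read_brainvision(base.with_suffix(".vhdr"))


def test_channel_count_mismatch_rejected(tmp_path):
    r = make_recording(n_channels=2, sfreq=100, duration_s=1, seed=6)
    vhdr, _, _ = write_brainvision(r, tmp_path / "x")
    text = vhdr.read_text().replace("NumberOfChannels=2", "NumberOfChannels=3")
    vhdr.write_text(text)
    with pytest.raises(FormatError, match="Ch3"):
        read_brainvision(vhdr)


def test_mne_reads_our_brainvision(tmp_path):
    """Independent reader agreement on the written triplet."""
    mne = pytest.importorskip("mne")
    r = make_recording(n_channels=4, sfreq=250, duration_s=2, seed=7)
    vhdr, _, _ = write_brainvision(r, tmp_path / "x")
    raw = mne.io.read_raw_brainvision(vhdr, verbose="error")
    data_uv = raw.get_data() * 1e6
    assert list(raw.ch_names) == r.channel_names
    assert np.allclose(data_uv, r.samples.astype(np.float32), atol=1e-9)
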