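"""EDF codec: calibration math, header layout, round-trip fidelity."""

import numpy as np
import pytest

from eegbids.core import Recording
from eegbids.edf import (
    EDFSignalHeader,
    digital_to_physical,
    physical_to_digital,
    read_edf,
    read_header,
    write_edf,
)
from eegbids.errors import FormatError
from eegbids.synthetic import make_recording


def _header(pmin=-1000.0, pmax=1000.0, dmin=-32768, dmax=32767):
    return EDFSignalHeader(
        label="Cz", physical_dimension="uV",
        physical_min=pmin, physical_max=pmax,
        digital_min=dmin, digital_max=dmax, samples_per_record=256,
    )


def test_calibration_boundaries_exact():
    h = _header()
    assert digital_to_physical(h.digital_min, h) == h.physical_min
    assert digital_to_physical(h.digital_max, h) == h.physical_max


def test_calibration_midpoint_matches_direct_formula():
    # independent evaluation of the affine map at d = 0, frozen here:
    # -1000 + (0 + 32768) * 2000 / 65535 = 0.015259021896667946
    h = _header()
    expected = -1000.0 + 32768 * 2000.0 / 65535.0
    assert digital_to_physical(0, h) == pytest.approx(expected, abs=1e-12)
    assert expected == pytest.approx(0.015259021896667946, abs=1e-12)


def test_physical_to_digital_round_trips_within_one_step():
    h = _header()
    rng = np.random.default_rng(11)
    x = rng.uniform(-1000, 1000, 500)
    back = digital_to_physical(physical_to_digital(x, h), h)
    assert np.max(np.abs(back - x)) <= h.quantization_step


def test_physical_to_digital_clamps():
    h = _header()
    assert physical_to_digital(1e9, h) == h.digital_max
    assert physical_to_digital(-1e9, h) == h.digital_min


def test_header_bytes_arithmetic(tmp_path):
    r = make_recording(n_channels=4, sfreq=256, duration_s=1, seed=0)
    h = write_edf(r, tmp_path / "x.edf")
    assert h.header_bytes == 256 * (4 + 1) == 1280


def test_record_layout(tmp_path):
    r = make_recording(n_channels=3, sfreq=256, duration_s=10, seed=0)
    h = write_edf(r, tmp_path / "x.edf")
    assert h.n_records == 10
    assert all(s.samples_per_record == 256 for s in h.signals)
    size = (tmp_path / "x.edf").stat().st_size
    assert size == h.header_bytes + h.n_records * 3 * 256 * 2


def test_sixteen_bits_per_sample(tmp_path):
    r = make_recording(n_channels=5, sfreq=200, duration_s=3, seed=1)
    h = write_edf(r, tmp_path / "x.edf")
    size = (tmp_path / "x.edf").stat().st_size
    spr = h.signals[0].samples_per_record
    bits = 8 * (size - h.header_bytes) / (h.n_signals * h.n_records * spr)
    assert bits == 16


def test_partial_record_padded_and_counted(tmp_path):
    r = make_recording(n_channels=2, sfreq=100, duration_s=2.5, seed=0, n_events=0)
    h = write_edf(r, tmp_path / "x.edf")
    assert h.n_records == 3
    back = read_edf(tmp_path / "x.edf")
    assert back.n_samples == 300
    # padding repeats each channel's final sample
    for i in range(2):
        step = h.signals[i].quantization_step
        assert np.all(np.abs(back.samples[i, 250:] - r.samples[i, -1]) <= step)


def test_zero_channel_round_trips_to_zero(tmp_path):
    r = Recording(["flat", "live"], 100.0,
                  np.vstack([np.zeros(200), np.sin(np.arange(200) / 10.0)]))
    h = write_edf(r, tmp_path / "x.edf")
    back = read_edf(tmp_path / "x.edf")
    assert np.max(np.abs(back.samples[0])) <= h.signals[0].quantization_step


def test_header_is_printable_ascii_and_verbatim(tmp_path):
    r = make_recording(n_channels=3, sfreq=250, duration_s=2, seed=5)
    written = write_edf(r, tmp_path / "x.edf")
    blob = (tmp_path / "x.edf").read_bytes()[: written.header_bytes]
    assert all(32 <= b <= 126 for b in blob)
    h = read_header(tmp_path / "x.edf")
    assert [s.label for s in h.signals] == r.channel_names
    for a, b in zip(h.signals, written.signals):
        assert (a.physical_min, a.physical_max) == (b.physical_min, b.physical_max)
        assert (a.digital_min, a.digital_max) == (b.digital_min, b.digital_max)


@pytest.mark.parametrize("seed", range(10))
def test_round_trip_error_within_quantization_step(tmp_path, seed):
    rng = np.random.default_rng(seed)
    r = make_recording(
        n_channels=int(rng.integers(1, 9)),
        sfreq=float(rng.choice([100, 250, 256, 500])),
        duration_s=float(rng.uniform(0.5, 3.0)),
        seed=seed,
    )
    h = write_edf(r, tmp_path / "x.edf")
    back = read_edf(tmp_path / "x.edf")
    for i, sig in enumerate(h.signals):
        err = np.max(np.abs(back.samples[i, : r.n_samples] - r.samples[i]))
        assert err <= sig.quantization_step


def test_truncated_file_raises_with_offset(tmp_path):
    r = make_recording(n_channels=2, sfreq=100, duration_s=2, seed=0)
    write_edf(r, tmp_path / "x.edf")
    data = (tmp_path / "x.edf").read_bytes()
    (tmp_path / "trunc.edf").write_bytes(data[: len(data) - 100])
    with pytest.raises(FormatError, match="byte"):
        read_edf(tmp_path / "trunc.edf")


def test_bad_version_field_rejected(tmp_path):
    r = make_recording(n_channels=1, sfreq=100, duration_s=1, seed=0)
    write_edf(r, tmp_path / "x.edf")
    data = bytearray((tmp_path / "x.edf").read_bytes())
    data[0:1] = b"9"
    (tmp_path / "bad.edf").write_bytes(bytes(data))
    with pytest.raises(FormatError, match="version"):
        read_edf(tmp_path / "bad.edf")


def test_mne_reads_our_edf(tmp_path):
    """Independent reader agreement: MNE decodes our file to the same signal."""
    mne = pytest.importorskip("mne")
    r = make_recording(n_channels=4, sfreq=256, duration_s=2, seed=3)
    h = write_edf(r, tmp_path / "x.edf")
    raw = mne.io.read_raw_edf(tmp_path / "x.edf", verbose="error")
    data_uv = raw.get_data() * 1e6
    assert list(raw.ch_names) == r.channel_names
    step = max(s.quantization_step for s in h.signals)
    assert np.allclose(data_uv, r.samples, atol=2 * step)
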