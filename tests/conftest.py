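import pytest

from eegbids.synthetic import make_dataset, make_recording


@pytest.fixture
def recording():
    """Small deterministic 4-channel recording with events."""
    return make_recording(n_channels=4, sfreq=250.0, duration_s=2.0, seed=7)


@pytest.fixture
def pristine_dataset(tmp_path):
    """A validator-clean 2-subject BrainVision dataset."""
    root = tmp_path / "ds"
    make_dataset(root, n_subjects=2, tasks=["rest"], seed=1)
    return root
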