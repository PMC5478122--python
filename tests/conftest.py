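import numpy as np
import pytest

from preictal.iodata import IEEGClip


def make_clip(
    subject="Dog_9",
    kind="interictal",
    index=1,
    sequence=1,
    rate=400.0,
    channels=2,
    duration=120.0,
    seed=0,
):
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    return IEEGClip(
        subject_id=subject,
        segment_kind=kind,
        segment_index=index,
        sequence_index=sequence,
        sampling_rate_hz=rate,
        channel_labels=[f"e{c}" for c in range(channels)],
        data=rng.standard_normal((channels, n)) * 50.0,
        duration_sec=duration,
    )


@pytest.fixture
def clip():
    return make_clip()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
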