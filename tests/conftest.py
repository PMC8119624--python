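from __future__ import annotations

import numpy as np
import pytest

from eegdiv import Recording, as_clean
from eegdiv.io_signals import MONTAGE_10_20


def make_recording(
    data: np.ndarray,
    rate_hz: float = 250.0,
    condition: str = "meditation",
    labels=None,
    participant_id: str = "p0",
) -> Recording:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        labels = MONTAGE_10_20[: data.shape[0]]
    return Recording(
        participant_id=participant_id,
        condition=condition,
        practice="unknown",
        channel_labels=tuple(labels),
        rate_hz=rate_hz,
        data=data,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session", autouse=True)
def _warm_lz76():
    # first call compiles the jitted LCP/LPF kernels; do it once up front
    from eegdiv import lz76_count

    lz76_count("01")


@pytest.fixture
def clean_noise_recording(rng):
    data = rng.standard_normal((4, 7500)) * 10.0
    return as_clean(make_recording(data))
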