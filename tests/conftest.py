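"""Shared fixtures: small synthetic recordings and feature tables.

Everything is generated at test time from fixed seeds; the expensive
multi-night dataset is session-scoped so the selection, stager and
acceptance tests share one copy.
"""

import numpy as np
import pytest

import somnostage as ss

FS = 128.0


@pytest.fixture(scope="session")
def night():
    """One 30-minute synthetic night (recording + hypnogram) at 128 Hz."""
    return ss.simulate_night(n_epochs=60, fs=FS, seed=11)


@pytest.fixture(scope="session")
def night_segments(night):
    rec, hyp = night
    return ss.preprocess_recording(rec, hyp)


@pytest.fixture(scope="session")
def four_night_features():
    """Feature table for four 2-hour nights (shared by the heavy tests)."""
    return ss.make_dataset(n_nights=4, n_epochs=240, fs=FS, seed=42)


def sine(freq: float, fs: float = FS, seconds: float = 5.0,
         amp: float = 1.0) -> np.ndarray:
    t = np.arange(int(round(seconds * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
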