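import numpy as np
import pytest

import squeaksort as sq
from squeaksort.features import extract_feature_table


@pytest.fixture(scope="session")
def small_dataset():
    """30 calls/class, default (noisy) sampler — shared across tests."""
    return sq.generate_dataset(sq.balanced_profile(30, seed=7))


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return extract_feature_table(small_dataset.calls)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """15 calls/class without background noise."""
    return sq.generate_dataset(
        sq.balanced_profile(15, seed=3), sq.CallSampler(noiseless=True)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def flat_call_spectrogram():
    """Noiseless 60 kHz flat call, 30 ms, plus its spectrogram."""
    spec = sq.CallSpec(sq.CallClass.FLAT, duration=0.030, base_frequency=60_000.0)
    call = sq.synthesize_call(spec, 250_000, rng_seed=0)
    return call, sq.compute_spectrogram(call, sq.StftParams())
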