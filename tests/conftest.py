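import numpy as np
import pytest

from icawave.synthetic import generate_beat, generate_record


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_beat():
    return generate_beat("N", d=162, noise_sd=0.0, seed=1)


@pytest.fixture
def clean_record():
    return generate_record(
        50, baseline_amp=0.0, powerline_amp=0.0, noise_sd=0.0, seed=3
    )
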