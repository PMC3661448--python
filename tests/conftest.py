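import math

import numpy as np
import pytest

from epgkit import (
    DetectionConfig,
    generate_trace,
    highpass,
    load_preset,
)


@pytest.fixture(scope="session")
def wt_basal():
    return load_preset("wt_basal_chip")


@pytest.fixture(scope="session")
def wt_5ht():
    return load_preset("wt_5ht_chip")


@pytest.fixture(scope="session")
def eat4():
    return load_preset("eat4_chip")


@pytest.fixture(scope="session")
def clean_5ht_trace(wt_5ht):
    """Noise- and drift-free 5-HT trace with ground truth (~70 pumps)."""
    return generate_trace(wt_5ht, duration=20, snr=math.inf, drift=False, seed=1)


@pytest.fixture(scope="session")
def noisy_5ht_trace(wt_5ht):
    """Default-noise 5-HT trace, high-passed, with ground truth."""
    trace, truth = generate_trace(wt_5ht, duration=60, seed=2)
    return highpass(trace), truth
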