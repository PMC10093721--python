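import numpy as np
import pandas as pd
import pytest

from ppg2bp.features import FEATURE_NAMES
from ppg2bp.signal_io import FeatureTable
from ppg2bp.synthetic import SynthConfig, generate_record


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free, drift-free synthetic record with exact ABP extrema."""
    cfg = SynthConfig(noise_sd=0.0, baseline_amp=0.0, bp_noise_sd=0.0,
                      duration=40.0, seed=7)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def noisy_record():
    """Default-condition synthetic record (noise + baseline wander)."""
    return generate_record(SynthConfig(duration=60.0, seed=11))


def make_linear_table(n=500, noise_sd=2.0, seed=123):
    """Feature table whose targets are linear in 3 informative features.

    The remaining 21 columns are pure noise; the irreducible prediction
    error is `noise_sd` mmHg by construction.
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 24))
    beta = np.zeros(24)
    beta[:3] = [4.0, -3.0, 2.0]
    sbp = 120.0 + X @ beta + rng.normal(0.0, noise_sd, n)
    dbp = 75.0 + X @ (0.5 * beta) + rng.normal(0.0, noise_sd, n)
    frame = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    frame["SBP"] = sbp
    frame["DBP"] = dbp
    return FeatureTable(frame), beta


@pytest.fixture(scope="session")
def linear_table():
    table, _ = make_linear_table()
    return table
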