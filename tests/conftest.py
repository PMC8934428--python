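"""Shared fixtures: small synthetic recordings generated at test time."""

import numpy as np
import pytest

from seizenergy.preprocess import preprocess_recording
from seizenergy.synthetic import SyntheticConfig, generate_recording


@pytest.fixture(scope="session")
def seizure_config():
    """30 s, one seizure at 10-20 s, strong ictal band-power effect."""
    return SyntheticConfig(
        duration=30.0,
        seizure_intervals=((10.0, 20.0),),
        ictal_amplitude=60.0,
        background_rms=20.0,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def seizure_recording(seizure_config):
    return generate_recording(seizure_config)


@pytest.fixture(scope="session")
def referenced_recording(seizure_recording):
    recording, annotations = seizure_recording
    return preprocess_recording(recording), annotations


@pytest.fixture(scope="session")
def tiny_records():
    """Three preprocessed single-seizure records for detector tests."""
    records = []
    for i in range(3):
        cfg = SyntheticConfig(
            duration=40.0,
            seizure_intervals=((15.0, 23.0),),
            ictal_amplitude=60.0,
            background_rms=20.0,
            rng_seed=100 + i,
        )
        rec, ann = generate_recording(cfg)
        records.append((preprocess_recording(rec), ann))
    return records


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
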