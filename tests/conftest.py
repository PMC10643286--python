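import logging

import numpy as np
import pytest

import stereoflight as sf

# stuck-LED warnings from short clips are expected noise in the test output
logging.getLogger("stereoflight.sync").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_config() -> sf.FlightConfig:
    return sf.FlightConfig()


@pytest.fixture(scope="session")
def clean_config() -> sf.FlightConfig:
    """Default study conditions but with noiseless digitisation."""
    return sf.synthetic.replace_config(sf.FlightConfig(), noise_sd_pixels=0.0)


@pytest.fixture(scope="session")
def clean_setup() -> sf.RecordingSetup:
    return sf.RecordingSetup(checkerboard_noise_px=0.0)


@pytest.fixture(scope="session")
def cameras() -> tuple[sf.CameraModel, sf.CameraModel]:
    return sf.default_cameras(rng=np.random.default_rng(0))


def run_clean_pipeline(seed: int, clean_config, clean_setup) -> tuple:
    """Noiseless synthetic flight through the whole reconstruction chain."""
    flight = sf.generate_flight(clean_config, rng_seed=seed)
    rec = sf.simulate_recording(flight, clean_setup, rng_seed=seed + 50)
    res = sf.process_recording(rec, flight_id=seed)
    return flight, rec, res


@pytest.fixture(scope="session")
def clean_run(clean_config, clean_setup):
    """One noiseless end-to-end run shared by several test modules."""
    return run_clean_pipeline(1, clean_config, clean_setup)
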