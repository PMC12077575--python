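import json
from importlib import resources

import pytest

from nirsfeed.device_config import load_device_descriptor
from nirsfeed.protocol_session import build_example_schedule
from nirsfeed.simulator import SimulationConfig


def make_descriptor(n_channels: int, name: str = "test device"):
    return load_device_descriptor(
        json.dumps(
            {
                "name": name,
                "type": "NIRS",
                "channels": n_channels,
                "wavelengths": [760, 850],
            }
        )
    )


@pytest.fixture(scope="session")
def descriptor26():
    """The packaged 26-channel two-wavelength template (105 columns)."""
    text = (
        resources.files("nirsfeed") / "devices" / "nirs_generic.json"
    ).read_text(encoding="utf-8")
    return load_device_descriptor(text)


@pytest.fixture(scope="session")
def short_schedule():
    """Two runs of two trials each: 1 baseline + 8 phases + 1 break."""
    return build_example_schedule(trials_per_run=[2, 2])


@pytest.fixture(scope="session")
def short_sim_config(short_schedule):
    return SimulationConfig(schedule=short_schedule, seed=1)
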