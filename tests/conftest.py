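import pandas as pd
import pytest

from mixotracer.synthetic_data import SimulationConfig, generate_experiment

ZERO_NOISE = dict(
    sd_colony=0.0,
    sd_tank=0.0,
    sd_measurement_d15N=0.0,
    sd_measurement_d13C=0.0,
    sd_CN=0.0,
    sd_fa=0.0,
    sd_source_fa=0.0,
    sd_rate=0.0,
)


class PreySource:
    """Heterotrophic endmember means used throughout the tests."""

    d13C = -20.5
    d15N = 9.8
    CN_molar = 4.48


@pytest.fixture(scope="session")
def prey_source():
    return PreySource()


@pytest.fixture(scope="session")
def default_experiment():
    """One default-config experiment shared across tests (seed 11)."""
    return generate_experiment(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def zero_noise_experiment():
    return generate_experiment(SimulationConfig(seed=5, **ZERO_NOISE))


@pytest.fixture()
def host_design(default_experiment):
    fragments, _, _, _ = default_experiment
    host = fragments[fragments["fraction"] == "host"].reset_index(drop=True)
    fa_cols = [c for c in host.columns if c.startswith("fa_")]
    values = host[fa_cols].rename(columns=lambda c: c[3:])
    design = host[["treatment", "colony", "tank_id"]]
    return values, design
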