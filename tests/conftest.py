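import dataclasses

import pytest

from hdxdelta.simulate import (
    DigestionParams,
    Footprint,
    SimulationConfig,
    StateSpec,
    generate_dataset,
    random_protein_sequence,
)


def make_config(**overrides) -> SimulationConfig:
    """A small two-state experiment with one planted 20x footprint."""
    defaults = dict(
        protein_id="toy",
        protein_sequence=random_protein_sequence(120, seed=5),
        states=(
            StateSpec(name="alone"),
            StateSpec(name="complex", footprints=(Footprint(60, 80, 20.0),)),
        ),
        exposures=(10.0, 60.0, 300.0),
        n_replicates=3,
        noise_sd=0.02,
        back_exchange=0.7,
        digestion=DigestionParams(),
        seed=9,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_config() -> SimulationConfig:
    return make_config()


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(make_config())


@pytest.fixture(scope="session")
def noise_free_dataset():
    return generate_dataset(make_config(noise_sd=0.0))


def replace_config(config: SimulationConfig, **overrides) -> SimulationConfig:
    return dataclasses.replace(config, **overrides)
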