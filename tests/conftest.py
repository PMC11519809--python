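import pytest

from mszscreen import PipelineConfig, SimulationConfig, generate_dataset


def noise_free_config(seed: int = 11) -> SimulationConfig:
    """Near-deterministic design: no contamination, no dropout, tiny dispersion."""
    return SimulationConfig(
        dispersion_by_method={"laser": 0.01, "manual": 0.01},
        dropout_prob_by_method={"laser": 0.0, "manual": 0.0},
        contamination_by_method={"laser": 0.0, "manual": 0.0},
        seed=seed,
    )


@pytest.fixture(scope="session")
def noisefree_data():
    return generate_dataset(noise_free_config())


@pytest.fixture(scope="session")
def noisy_data():
    return generate_dataset(SimulationConfig(seed=0))


@pytest.fixture()
def noisefree_pipeline_config():
    return PipelineConfig(simulation=noise_free_config())
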