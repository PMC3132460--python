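import pytest

from subtelcnv import SimulationConfig, build_region_model
from subtelcnv.pipeline import simulate_study


@pytest.fixture(scope="session")
def region():
    return build_region_model()


@pytest.fixture(scope="session")
def default_study():
    """Default-noise tiling study shared across tests (seed fixed)."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def screening_study():
    """Default-noise screening-platform study (seed fixed)."""
    return simulate_study(SimulationConfig(seed=3), platform="screening")


@pytest.fixture(scope="session")
def noise_free_study():
    """Noise-free emulation cohort: exactly 13 carrier cases, 1 carrier
    control, plus a 15-sample normal reference panel."""
    config = SimulationConfig(
        sigma_probe=0.0, gc_slope=0.0, batch_effect_sd=0.0, seed=7
    )
    return simulate_study(config, carrier_counts=(13, 1))
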