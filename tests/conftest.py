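import numpy as np
import pytest

from pelletpat.types import CoatingRunConfig


@pytest.fixture
def p4_config() -> CoatingRunConfig:
    """Run parameterised from the P4 process record, stopped on the true
    deposited-thickness mass balance at the 8.0 um post-drying film."""
    return CoatingRunConfig(
        load_mass=1000.0,
        spray_rate=14.0,
        dry_fraction=0.207,
        process_yield=0.713,
        n_per_mass=1.256,
        ssa_m_core=4.56e6,
        coating_density=1.76,
        target_thickness=8.0,
        endpoint_mode="true_thickness",
        seed=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
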