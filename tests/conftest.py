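import numpy as np
import pytest

import surfdecode as sd


@pytest.fixture(scope="session")
def default_design() -> sd.DesignSpec:
    return sd.DesignSpec()


@pytest.fixture(scope="session")
def small_effect() -> sd.EffectSpec:
    """Reduced voxel count for fast unit tests."""
    return sd.EffectSpec(n_voxels=30)


@pytest.fixture(scope="session")
def null_effect() -> sd.EffectSpec:
    """No condition information in the patterns."""
    return sd.EffectSpec(n_voxels=30, pattern_amplitude=0.0)


@pytest.fixture(scope="session")
def default_schedule(default_design) -> sd.BlockSchedule:
    return sd.build_design(default_design, seed=123)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2026)
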