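import numpy as np
import pytest

from medpower321 import DesignSpec, derive_components, generate


@pytest.fixture(scope="session")
def large_effect_spec() -> DesignSpec:
    """Large indirect paths, medium direct effect; the worked example design."""
    return DesignSpec(a3=0.59, b3=0.59, c3p=0.39, b2=0.39,
                      icc_m3=0.2, icc_y2=0.1, icc_y3=0.2,
                      n3=10, n2=5, n1=3)


@pytest.fixture(scope="session")
def large_effect_params(large_effect_spec):
    return derive_components(large_effect_spec)


@pytest.fixture(scope="session")
def small_dataset(large_effect_params):
    """One small balanced dataset shared by estimator tests."""
    return generate(large_effect_params, 10, 5, 3, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
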