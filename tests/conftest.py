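import numpy as np
import pytest

from ccdkit import AnalysisConfig, SimulationConfig, generate_factorial_study


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture
def study8():
    """One default synthetic 8-group study (fixed seed)."""
    return generate_factorial_study(SimulationConfig(seed=11))


@pytest.fixture
def normal_pair():
    """Two clearly normal samples with similar variances."""
    a = np.random.default_rng(2).normal(0.0, 1.0, 10)
    b = np.random.default_rng(3).normal(0.0, 1.0, 10)
    return a, b
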