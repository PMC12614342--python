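import numpy as np
import pytest

from hdokin.synthetic import (
    GeneratorConfig,
    IsotopologueTruth,
    branching_scheme_lval,
    stopped_flow_truth,
)


@pytest.fixture
def branching_scheme():
    """Four-way branching scheme with the reported valine branch constants."""
    return branching_scheme_lval()


@pytest.fixture
def iso_truth():
    """Default serial two-step isotopologue ground truth."""
    return IsotopologueTruth()


@pytest.fixture
def noiseless_cfg():
    return GeneratorConfig(seed=0, noise_sd=0.0, replicates=1)


@pytest.fixture
def sf_truth():
    return stopped_flow_truth()


@pytest.fixture
def dense_grid():
    """Dense time grid (minutes) long enough to reach every plateau."""
    return np.concatenate([[1e-3], np.geomspace(0.01, 200.0, 120)])
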