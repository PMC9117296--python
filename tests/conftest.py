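import numpy as np
import pytest

from hytest import make_fixture, preprocess, run_dea


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fixture_dataset():
    """Default synthetic paired data set with planted DE genes."""
    expr, pairs, truth = make_fixture(seed=0)
    return expr, pairs, truth


@pytest.fixture(scope="session")
def fixture_dea_table(fixture_dataset):
    """run_dea output on the preprocessed default fixture."""
    expr, pairs, truth = fixture_dataset
    matrix = preprocess(expr, offset=0.0)
    return run_dea(matrix, pairs), truth
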