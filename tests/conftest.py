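import numpy as np
import pytest

from vsfgorient.solver import OrientationRegressor
from vsfgorient.synth import gen_test_set, gen_training_set


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_training_set():
    return gen_training_set(2000, seed=11)


@pytest.fixture(scope="session")
def test_set_1k():
    return gen_test_set(1000, seed=11)


@pytest.fixture(scope="session")
def trained_model(benchmark_training_set):
    """One solver shared by every test that needs a trained network.

    Trained at a reduced problem size (see docs/methods.md) so the whole
    suite stays fast; the acceptance script runs the bigger recipe.
    """
    est = OrientationRegressor(epochs=400, random_state=11)
    est.fit(benchmark_training_set.inputs, benchmark_training_set.outputs)
    return est


@pytest.fixture(scope="session")
def benchmark_training_set():
    return gen_training_set(100000, seed=11)
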