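import numpy as np
import pytest

from mvpakit import BenchmarkConfig, DataSet, generate_benchmark


@pytest.fixture(scope="session")
def small_benchmark() -> DataSet:
    """Default-blend hierarchical benchmark: 200 features, 100 trials/condition."""
    return generate_benchmark(BenchmarkConfig(n_features=200, trials_per_condition=100, seed=1))


@pytest.fixture()
def toy_dataset() -> DataSet:
    """10 examples x 4 features with condition and subject attributes."""
    rng = np.random.default_rng(7)
    return DataSet(
        data=rng.standard_normal((10, 4)),
        sample_attributes={
            "condition": np.array([0, 1] * 5),
            "subject": np.array(["A", "A", "A", "B", "B", "B", "C", "C", "C", "C"]),
        },
    )
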