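import numpy as np
import pytest

from exprdist import ExpressionMatrix, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """20 normal genes x 12 samples, no conditions structure."""
    values = rng.normal(8.0, 0.5, (20, 12))
    return ExpressionMatrix(
        [f"g{i}" for i in range(20)], [f"s{j}" for j in range(12)], values
    )


@pytest.fixture
def null_study():
    """Small condition-free synthetic study: no affected genes."""
    spec = SyntheticSpec(
        n_genes=300,
        n_samples=30,
        condition_labels={"a": 10, "b": 10, "c": 10},
        noise_fraction=0.2,
        affected_fraction=0.0,
        seed=7,
    )
    matrix, truth = generate(spec)
    return spec, matrix, truth
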