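import numpy as np
import pytest

from netseg.data_io import ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """Four well-behaved profiles over six time points."""
    rng = np.random.default_rng(42)
    return ExpressionMatrix(
        entity_ids=[f"g{i}" for i in range(4)],
        time_labels=[f"t{j}" for j in range(6)],
        values=rng.normal(size=(4, 6)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130507)
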