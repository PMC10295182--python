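import numpy as np
import pandas as pd
import pytest

from benthet.core_data import CommunityMatrix
from benthet.synthetic_data import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic survey (162 stations), shared across tests."""
    return generate_dataset(GeneratorConfig(), seed=0)


@pytest.fixture()
def toy_community():
    """Six samples x ten taxa sparse community for brute-force oracles."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(0.8, size=(6, 10)),
        index=[f"s{i}" for i in range(6)],
        columns=[f"t{i}" for i in range(10)],
    )
    counts.iloc[0, :3] += 1  # guarantee a non-empty first sample
    return CommunityMatrix(counts=counts)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
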