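import numpy as np
import pytest

from ledaffinity import (
    AffinityDataset,
    ModelSpec,
    load_reference_dataset,
)


@pytest.fixture(scope="session")
def reference_dataset() -> AffinityDataset:
    return load_reference_dataset()


@pytest.fixture(scope="session")
def m3() -> ModelSpec:
    return ModelSpec.m3()


def normal_equation_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent OLS oracle: solve the normal equations directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


@pytest.fixture(scope="session")
def oracle_ols():
    return normal_equation_fit
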