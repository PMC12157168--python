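import numpy as np
import pandas as pd
import pytest

from formubo.design import Dataset, DesignSpace, FeatureSpec, ResponseSpec


@pytest.fixture
def two_feature_space() -> DesignSpace:
    return DesignSpace([
        FeatureSpec("residual_rhsa", 0.0, 1.5, "mg/mL"),
        FeatureSpec("spiked_rhsa", 0.0, 5.0, "mg/mL"),
    ])


@pytest.fixture
def rhsa_space() -> DesignSpace:
    return DesignSpace([
        FeatureSpec("residual_rhsa", 0.0, 1.5, "mg/mL"),
        FeatureSpec("spiked_rhsa", 0.0, 5.0, "mg/mL"),
        FeatureSpec("total_rhsa", 0.0, 6.5, "mg/mL", role="derived",
                    parents=("residual_rhsa", "spiked_rhsa")),
    ])


def make_dataset(space: DesignSpace, X: np.ndarray, y: np.ndarray,
                 response: str = "titer_loss", direction: str = "minimize") -> Dataset:
    frame = pd.DataFrame(X, columns=space.base_names)
    for f in space.features:
        if f.role == "derived":
            frame[f.name] = frame[list(f.parents)].sum(axis=1)
    frame[response] = y
    return Dataset(space, frame, ResponseSpec(response, "", direction))


@pytest.fixture
def small_dataset(two_feature_space) -> Dataset:
    rng = np.random.default_rng(42)
    X = rng.random((12, 2)) * [1.5, 5.0]
    y = 1.0 + 0.3 * X[:, 1] - 0.5 * X[:, 0]
    return make_dataset(two_feature_space, X, y)
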