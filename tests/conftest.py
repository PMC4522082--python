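import dataclasses

import numpy as np
import pytest

from omicsbias.data_model import ExpressionDataset
from omicsbias.synthetic import (amplify_to_min_distance, generate, preset,
                                 skewed_signal_fixture)


@pytest.fixture(scope="session")
def skew_dataset():
    """1:4 label-skewed dataset with a smooth class signal in
    high-frequency noise (the label-skewness-bias regime)."""
    return skewed_signal_fixture(seed=1)


@pytest.fixture(scope="session")
def amplified_skew_dataset():
    """Skewed cohort with the profiling signal-amplification property
    installed (min pairwise squared distance >= 100 after per-sample
    standardization) - the overfitting-bias regime."""
    spec = dataclasses.replace(preset("breastibc_like"), seed=7)
    return amplify_to_min_distance(generate(spec), 100.0)


@pytest.fixture(scope="session")
def balanced_dataset():
    """Balanced, well-separated normal-intensity cohort."""
    spec = dataclasses.replace(preset("hcc_like"), seed=3)
    return generate(spec)


@pytest.fixture()
def tiny_dataset():
    return ExpressionDataset(
        values=np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 7.0]]),
        feature_ids=["fA", "fB", "fC"],
        sample_ids=["s1", "s2"],
        labels=np.array([1, -1]),
    )
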