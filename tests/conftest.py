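"""Shared fixtures: small synthetic datasets and fast learner specs."""

from __future__ import annotations

import numpy as np
import pytest

from cvep.learners import BaseLearnerSpec
from cvep.preprocess import build_training_design
from cvep.synthetic import SyntheticConfig, generate_dataset, generate_worked_fixture

#: Reduced tree counts keep unit-test fits fast; contracts are unchanged.
FAST_HP = {
    "GLM": {},
    "GBM": {"ntrees": 40, "max_depth": 4},
    "DRF": {"ntrees": 40, "max_depth": 12},
}


def fast_specs(distribution: str = "multinomial") -> list[BaseLearnerSpec]:
    return [
        BaseLearnerSpec(kind=k, hyperparameters=FAST_HP[k], distribution=distribution)
        for k in ("GLM", "GBM", "DRF")
    ]


@pytest.fixture(scope="session")
def worked():
    """The frozen 30-row hand-checkable fixture."""
    return generate_worked_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """A 600-row default-condition synthetic dataset."""
    return generate_dataset(SyntheticConfig(n=600, seed=42))


@pytest.fixture(scope="session")
def small_design(small_dataset):
    _, matrix, codes = small_dataset
    return build_training_design(matrix, codes, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
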