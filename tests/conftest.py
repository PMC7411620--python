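"""Shared fixtures: the default synthetic dataset is generated once per
test session (it is deterministic), and its feature matrix is reused by
classification and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from temsense.fusion_classify import build_feature_matrix
from temsense.synthgen import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """(sessions, truths, manifest) for the default 21 x 4 configuration."""
    return generate_dataset(SynthConfig())


@pytest.fixture(scope="session")
def feature_matrix(default_dataset):
    sessions, _, _ = default_dataset
    return build_feature_matrix(sessions)


@pytest.fixture(scope="session")
def dataset_labels(default_dataset):
    _, truths, _ = default_dataset
    return np.array([t.emotion for t in truths])
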