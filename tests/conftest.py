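"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pytest

from endophylo import synthetic
from endophylo.read_qc import QcParams, trim_and_filter


@pytest.fixture(scope="session")
def ancestor():
    return synthetic.make_ancestor(42)


@pytest.fixture(scope="session")
def two_copy_dataset():
    """2-donor hybrid, tefA focus: the workhorse for recovery tests."""
    return synthetic.build_dataset("FaTG3", seed=101, markers=("tefA",))


@pytest.fixture(scope="session")
def trimmed_pairs(two_copy_dataset):
    pairs, _ = trim_and_filter(two_copy_dataset.pairs, QcParams())
    return pairs


@pytest.fixture
def rng():
    return np.random.default_rng(0)
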