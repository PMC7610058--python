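"""Shared fixtures.

The heavy fixtures (the full 20-subject study and its two-level consensus
fit) are session-scoped: they are simulated once and shared by the
acceptance tests, which keeps the whole suite inside a desktop-scale run.
"""

from __future__ import annotations

import logging

import numpy as np
import pytest

import erpconsensus as ec
from erpconsensus.ensemble import fit_group
from erpconsensus.pipeline import PipelineConfig, default_targets

logging.getLogger("erpconsensus").setLevel(logging.ERROR)

#: study seed for the full-scale fixtures (fixed once for reproducibility)
STUDY_SEED = 1
CONSENSUS_METHODS = ["hierarchical_corr", "aahc", "modified_kmeans"]


@pytest.fixture(scope="session")
def full_spec():
    """The stock two-condition, 20-subject, 65-channel, 429 Hz study spec."""
    return ec.default_study_spec(n_subjects=20, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def full_study(full_spec):
    return ec.simulate_study(full_spec)


@pytest.fixture(scope="session")
def full_config(full_spec):
    return PipelineConfig(k=7, seed=STUDY_SEED, targets=default_targets(full_spec))


@pytest.fixture(scope="session")
def full_fit(full_study):
    """Two-level consensus of the full study with the selected method trio."""
    return fit_group(full_study, 7, CONSENSUS_METHODS, seed=STUDY_SEED + 100)


@pytest.fixture(scope="session")
def small_study():
    """A light study (4 subjects, 16 channels) for pipeline/io tests."""
    spec = ec.default_study_spec(n_subjects=4, n_channels=16, seed=3)
    return ec.simulate_study(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_block_data(templates: np.ndarray, block: int, noise: float, rng) -> tuple:
    """Rows = templates repeated in contiguous blocks plus Gaussian noise.

    Returns (X, labels) with labels 1..k in block order — a planted
    partition every reasonable clusterer should recover when the templates
    are well separated.
    """
    k, f = templates.shape
    X = np.repeat(templates, block, axis=0) + noise * rng.standard_normal((k * block, f))
    labels = np.repeat(np.arange(1, k + 1), block)
    return X, labels


@pytest.fixture()
def planted_blocks(rng):
    """Three orthogonal 20-channel templates, 20 time-points each."""
    templates = np.zeros((3, 20))
    templates[0, :7] = 5.0
    templates[1, 7:14] = 5.0
    templates[2, 14:] = 5.0
    templates -= templates.mean(axis=1, keepdims=True)
    X, labels = make_block_data(templates, block=20, noise=0.15, rng=rng)
    return X, labels, templates
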