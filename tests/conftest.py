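"""Shared fixtures: the seeded synthetic benchmark is expensive to build, so
the trained class model, the calibrated spatial prior and the held-out
evaluation are session-scoped and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from quantos.benchmark import evaluate_benchmark, train_default_model
from quantos.classifier import calibrate_random_factor
from quantos.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def default_model():
    return train_default_model(base_seed=100)


@pytest.fixture(scope="session")
def prior_model():
    return calibrate_random_factor(seed=11)


@pytest.fixture(scope="session")
def benchmark_all(default_model, prior_model):
    """(RocResult, labelled candidate table) for the full parameter set."""
    return evaluate_benchmark(default_model, prior_model, subset="all")


@pytest.fixture(scope="session")
def benchmark_distance(default_model, prior_model):
    return evaluate_benchmark(default_model, prior_model, subset="distance")


@pytest.fixture(scope="session")
def small_scene():
    """One training-style scene for cheap unit-level checks."""
    return generate_scene(SceneConfig(seed=100, noise_region="outside_opl"))
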