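"""Shared fixtures: one synthetic benchmark split reused across the suite.

Building the benchmark (signal synthesis, filtering, feature extraction)
takes ~10 s, so it is session-scoped; tests must not mutate it.
"""

from __future__ import annotations

import numpy as np
import pytest

from swctnet.dataset import DatasetSplit
from swctnet.synthetic import ScenarioConfig, make_benchmark

BENCH_SEED = 7


@pytest.fixture(scope="session")
def scenario() -> ScenarioConfig:
    return ScenarioConfig(seed=BENCH_SEED)


@pytest.fixture(scope="session")
def benchmark_split(scenario) -> DatasetSplit:
    """Default-scenario benchmark; carries labels, features and envelopes."""
    return make_benchmark("classification", scenario, split_seed=BENCH_SEED)


@pytest.fixture(scope="session")
def tiny_split(benchmark_split) -> DatasetSplit:
    """Small stratified slice of the benchmark for fast training tests."""
    def thin(samples, step):
        return list(samples[::step])
    return DatasetSplit(train=thin(benchmark_split.train, 12),
                        val=thin(benchmark_split.val, 12),
                        test=thin(benchmark_split.test, 12),
                        normalization=benchmark_split.normalization)
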