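import numpy as np
import pytest

import reservescan as rs
from reservescan.pipeline import build_and_calibrate_models, run_benchmark
from reservescan.synthetic_cohort import CohortConfig, DistributionSpec, Scenario


@pytest.fixture(scope="session")
def registry():
    return rs.load_registry()


@pytest.fixture(scope="session")
def mini_registry(registry):
    """Small registry slice (one de novo enzyme, single- and multi-domain
    enzymes) for fast end-to-end tests."""
    return registry.subset(["pep2", "glgA", "phaB", "ws_dgat"])


@pytest.fixture(scope="session")
def mini_models(mini_registry):
    return build_and_calibrate_models(
        mini_registry, seed=7, n_homologs=12, n_calibration=150
    )


def mini_cohort_config(seed: int, n: int = 8, size_effect: int = 0) -> CohortConfig:
    """Tiny two-clade cohort over the mini registry."""
    return CohortConfig(
        n_proteomes=n,
        scenario_table=(
            Scenario("CladeA", {"pep2": 1, "glgA": 1, "phaB": 1, "ws_dgat": 2}, 0.5),
            Scenario("CladeB", {}, 0.5),
        ),
        decoy_count_sampler=DistributionSpec("fixed", {"value": 10}),
        decoy_length_sampler=DistributionSpec("normal", {"mean": 120, "sd": 25}, minimum=40),
        size_effect=size_effect,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def benchmark_result():
    """One full default-conditions benchmark run (100 proteomes, identities
    0.85-0.95, >= 50 decoys per proteome), shared across acceptance tests."""
    return run_benchmark(seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
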