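import numpy as np
import pytest

from roadrisk.pipeline import config_for_world, run_pipeline
from roadrisk.synth import WorldParams, make_benchmark_fixture, simulate_world


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    """A 6-species lattice world with closed-form ground truth."""
    out = tmp_path_factory.mktemp("world_small")
    truth = simulate_world(WorldParams(seed=7, n_species=6), out)
    return out, truth


@pytest.fixture(scope="session")
def small_world_run(small_world, tmp_path_factory):
    out, truth = small_world
    run_dir = tmp_path_factory.mktemp("run_small")
    results = run_pipeline(config_for_world(out, run_dir))
    return truth, results


@pytest.fixture(scope="session")
def benchmark_world(tmp_path_factory):
    """The deterministic 36-species fixture with a known ranking structure."""
    out = tmp_path_factory.mktemp("world_benchmark")
    truth = make_benchmark_fixture(out)
    return out, truth


@pytest.fixture(scope="session")
def benchmark_world_run(benchmark_world, tmp_path_factory):
    out, truth = benchmark_world
    run_dir = tmp_path_factory.mktemp("run_benchmark")
    results = run_pipeline(config_for_world(out, run_dir))
    return truth, results


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
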