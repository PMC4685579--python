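import numpy as np
import pandas as pd
import pytest

from hydracross.io_core import CountMatrix, RunConfig, Sample, SampleSheet
from hydracross import synthetic_data as sd
from hydracross.pipeline import run_synthetic_pipeline


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def tiny_matrix():
    return CountMatrix(("g1", "g2"), ("s1", "s2"), np.array([[0, 5], [3, 0]]))


@pytest.fixture
def small_random_matrix():
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 200, size=(50, 6))
    return CountMatrix(
        tuple(f"g{i}" for i in range(50)), tuple(f"s{j}" for j in range(6)), counts
    )


@pytest.fixture(scope="session")
def default_programs():
    return sd.default_programs(rng_seed=0)


@pytest.fixture(scope="session")
def default_design():
    return sd.SimulationDesign(rng_seed=0)


@pytest.fixture(scope="session")
def noisefree_design():
    return sd.SimulationDesign(rng_seed=0, nb_dispersion=0.0, library_size_log_sd=0.0)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default-seed pipeline run shared across the suite."""
    return run_synthetic_pipeline(seed=1)


@pytest.fixture
def spatial_sheet():
    samples = [
        Sample(f"sp_{r}_r{k}", "spatial", r, k)
        for r in ("H", "R1", "R3", "R4", "F")
        for k in (1, 2, 3)
    ]
    return SampleSheet(samples)
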