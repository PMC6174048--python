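import dataclasses

import pytest

from blinkwatch.benchmark import run_benchmark
from blinkwatch.synthetic import EyeImageParams


@pytest.fixture(scope="session")
def benchmark_result():
    """The frozen 9964-record benchmark, trained once per test session."""
    return run_benchmark(init_seed=42)


@pytest.fixture
def noise_free_params() -> EyeImageParams:
    return dataclasses.replace(EyeImageParams(), noise_sd=0.0)
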