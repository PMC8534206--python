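import time

import pytest
from hypothesis import HealthCheck, settings

from enoseq.pipeline import PipelineConfig, run_pipeline
from enoseq.preprocess import preprocess_dataset
from enoseq.synthdata import SyntheticConfig, generate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def synth_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=123)


@pytest.fixture(scope="session")
def dataset(synth_cfg):
    return generate_dataset(synth_cfg)


@pytest.fixture(scope="session")
def preprocessed(dataset):
    return preprocess_dataset(dataset)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default-scale pipeline run (12 cuts x 2220 min, seed 0)."""
    t0 = time.monotonic()
    result = run_pipeline(PipelineConfig(seed=0))
    result.elapsed_s = time.monotonic() - t0
    return result
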