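import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def montage():
    from deltasync import default_montage

    return default_montage()


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 2+2-participant cohort at reduced scale, shared across tests."""
    from deltasync import CohortConfig, simulate_cohort
    from dataclasses import replace

    cfg = CohortConfig(
        n_per_group=2,
        n_demos=4,
        rate=128.0,
        duration_range_s=(9.0, 12.0),
        n_rest_blocks=2,
        rest_block_s=30.0,
        rest_analysis_offset_s=5.0,
        rest_analysis_span_s=20.0,
        n_background=4,
        seed=77,
    )
    bundles, manifest = simulate_cohort(cfg)
    return cfg, bundles, manifest
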