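import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pgtpcr.config import CohortConfig, ErrorModel, PipelineConfig

settings.register_profile(
    "ci", deadline=None, max_examples=25, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def big_cohort():
    """One large cohort shared by the statistical recovery tests."""
    from pgtpcr import simulate

    cfg = PipelineConfig()
    truth = simulate.simulate_karyotypes(CohortConfig(n_embryos=10_000, seed=424242))
    detections = simulate.simulate_locus_detections(truth, cfg.errors, seed=424243)
    return truth, detections


@pytest.fixture
def noise_free_config():
    """All stochastic error sources off: detections must mirror presence."""
    cfg = PipelineConfig()
    cfg.cohort = CohortConfig(n_embryos=300, p_wga_failure=0.0, seed=99)
    cfg.errors = ErrorModel(
        ado={l: 0.0 for l in cfg.errors.ado},
        fa={l: 0.0 for l in cfg.errors.fa},
    )
    cfg.melt.noise_sd = 0.0
    return cfg


@pytest.fixture
def rng():
    return np.random.default_rng(20170622)
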