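import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")

from facelba.hierarchy import HyperPriorConfig
from facelba.lba_core import SubjectParams
from facelba.sampler import SamplerConfig, run_sampler
from facelba.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20160201)


@pytest.fixture
def params():
    """A typical mid-range subject parameter vector."""
    return SubjectParams(A=1.2, k=1.8, t0=0.5, v_c_face=2.0, v_e_face=0.8,
                         v_c_oval=2.4, v_e_oval=1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort shared by read-only tests."""
    cfg = CohortConfig(n_mdd=5, n_hcl=5, seed=314)
    trials, roi, truth = generate_cohort(cfg)
    return cfg, trials, roi, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A short hierarchical fit shared by read-only tests."""
    _, trials, _, _ = small_cohort
    cfg = SamplerConfig(n_chains=8, n_samples=150, burn_in=150, seed=99)
    draws = run_sampler(trials, HyperPriorConfig.default(), cfg)
    return draws
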