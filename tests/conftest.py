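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


@pytest.fixture(scope="session")
def discovery_cohort():
    from fpescan.genotypes import simulate_cohort

    return simulate_cohort(208, 151, seed=11)


@pytest.fixture(scope="session")
def small_null_genotypes(discovery_cohort):
    from fpescan.genotypes import SnpPanelSpec, simulate_null_genotypes

    panel = SnpPanelSpec(n_tier1=60, n_chrx_other=80, n_autosomal=120, seed=5)
    return simulate_null_genotypes(panel, discovery_cohort)
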