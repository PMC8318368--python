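import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small single-seed cohort shared by structural tests."""
    from splitmr.simulate import SimConfig, simulate_cohort

    cfg = SimConfig(
        n_individuals=600,
        n_snps=30,
        n_causal=8,
        n_causal_edu=6,
        ld_block_size=3,
        ld_rho=0.5,
        h2_score=0.2,
        seed=42,
    )
    return simulate_cohort(cfg)
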