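import pytest
from hypothesis import HealthCheck, settings

from arealepi import expected_counts, simulate_panel

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_small():
    """5x5 lattice, 7 years: quick fixture for unit tests."""
    sim = simulate_panel(n_side=5, seed=42)
    sim.panel = expected_counts(sim.panel)
    return sim


@pytest.fixture(scope="session")
def sim_medium():
    """10x10 lattice, 7 years: the desk-scale study condition."""
    sim = simulate_panel(n_side=10, seed=7)
    sim.panel = expected_counts(sim.panel)
    return sim


@pytest.fixture(scope="session")
def glmm_fit_small(sim_small):
    """One fitted non-spatial GLMM shared by diagnostic tests."""
    from arealepi import NegBinGLMM

    model = NegBinGLMM(sim_small.panel, ["ndvi_per01", "no2", "lst"])
    return model.fit(draws=300, warmup=300, chains=2, seed=3, on_unconverged="flag")
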