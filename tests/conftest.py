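import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from mircomp.pipeline import run_pipeline  # noqa: E402
from mircomp.simulate import SimulationConfig, simulate_study  # noqa: E402


@pytest.fixture(scope="session")
def small_study():
    """A compact synthetic study for unit-level recovery checks."""
    return simulate_study(SimulationConfig(n_families=40, n_genes=60, rng_seed=11))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline run at the generator's default study conditions."""
    out = tmp_path_factory.mktemp("default_run")
    run_pipeline(out, {"seed": 1})
    return out


@pytest.fixture(scope="session")
def strong_coupling_study():
    """Study with strong repression and low noise for coupling recovery."""
    return simulate_study(
        SimulationConfig(repression_gamma=1.0, noise_sigma=0.05, rng_seed=1)
    )
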