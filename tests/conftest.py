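import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from chronosim.defaults import ModelBundle, default_bundle
from chronosim.population import PopulationConfig, generate_population
from chronosim.rng import substream
from chronosim.specs import ModelRepository, RegressionSpec


@pytest.fixture(scope="session")
def bundle() -> ModelBundle:
    return default_bundle()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def small_pop(bundle):
    cfg = PopulationConfig(n=500)
    return generate_population(cfg, substream(42, "population"), gcp_spec=bundle.gcp)


def identity_repository() -> ModelRepository:
    """Persistence-identity dynamics: every factor reproduces its lagged value
    exactly (residual sd 0), medications/flags/smoking never change."""
    from chronosim.population import CONTINUOUS_FACTORS

    repo = ModelRepository()
    for f in CONTINUOUS_FACTORS:
        log = f in ("sbp", "dbp")
        lag = f"lag_log_{f}" if log else f"lag_{f}"
        repo.add(
            RegressionSpec(
                name=f, family="linear", outcome=f,
                coefficients={"intercept": 0.0, lag: 1.0},
                transform="log-outcome" if log else "none",
            )
        )
    repo.add(RegressionSpec(name="smoking_quit", family="logistic", outcome="smoking_status",
                            coefficients={"intercept": -50.0}))
    repo.add(RegressionSpec(name="med_add", family="logistic", outcome="n_antihypertensives",
                            coefficients={"intercept": -50.0}))
    repo.add(RegressionSpec(name="statin", family="logistic", outcome="statin",
                            coefficients={"intercept": -50.0, "lag_statin": 100.0}))
    repo.add(RegressionSpec(name="other_lipid", family="logistic", outcome="other_lipid_agent",
                            coefficients={"intercept": -50.0, "lag_other_lipid_agent": 100.0}))
    return repo


@pytest.fixture()
def identity_repo() -> ModelRepository:
    return identity_repository()
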