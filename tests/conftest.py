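import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from memphen.fitting import FitConfig, ModelSpec, PMDispersion
from memphen.synthetic_data import CohortSpec, generate_cohort
from memphen.task_model import ModelParameters, ParameterRanges, TaskDesign

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ranges() -> ParameterRanges:
    return ParameterRanges()


@pytest.fixture(scope="session")
def design() -> TaskDesign:
    return TaskDesign()


@pytest.fixture(scope="session")
def cohort_mean_params() -> ModelParameters:
    """A parameter set at the cohort-level means of the fitted population."""
    return ModelParameters(
        alpha=1.93, beta=1.27, gamma=0.5, eps_pos=1.09, eps_neg=1.12,
        sigma=0.7, c=1.95, s=4.133,
    )


@pytest.fixture(scope="session")
def default_spec() -> ModelSpec:
    """The selected model: alpha, beta, c, eps_pos, eps_neg free."""
    return ModelSpec(
        free_names=("alpha", "beta", "c", "eps_pos", "eps_neg"),
        fixed_values={"gamma": 0.5, "sigma": 0.7, "s": 4.133},
    )


@pytest.fixture(scope="session")
def unit_dispersion() -> PMDispersion:
    return PMDispersion(np.ones(8))


@pytest.fixture(scope="session")
def small_cohort():
    """A 25-subject synthetic cohort shared by read-only tests."""
    spec = CohortSpec.table1(n_subjects=25, master_seed=42)
    genotypes, logs, pm_table, truth = generate_cohort(spec)
    return spec, genotypes, logs, pm_table, truth
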