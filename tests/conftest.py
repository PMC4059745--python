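import numpy as np
import pytest

from caloradapt import DEFAULT_PARAMS, build_AL, build_H1, simulate, with_lead_in
from caloradapt.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def params():
    return DEFAULT_PARAMS


@pytest.fixture(scope="session", autouse=True)
def _warm_kernel():
    # trigger numba compilation once, outside timed assertions
    simulate(DEFAULT_PARAMS, build_AL(2))


@pytest.fixture(scope="session")
def clean_al_cohort():
    """Three noiseless, identical-parameter ad-libitum rats (constant
    expenditure rate, the regime the estimation steps 1-2 assume)."""
    spec = CohortSpec(n_per_group=3, param_cv=0.0, weight_noise_sd=0.0,
                      intake_noise_sd=0.0, rwat_noise_sd=0.0,
                      initial_bw_sd=10.0, seed=1)
    return generate_cohort(spec, {"AL": build_AL(56)}, DEFAULT_PARAMS,
                           memory_on=False)


@pytest.fixture(scope="session")
def noisy_h1_cohort():
    """Six rats fed a weekly-varying hypocaloric schedule, generated by
    the full model (memory on) with weighing noise only."""
    sched = build_H1(56, seed=101)
    spec = CohortSpec(n_per_group=6, param_cv=0.0, weight_noise_sd=5.0,
                      intake_noise_sd=0.0, rwat_noise_sd=0.0, seed=1)
    return generate_cohort(spec, {"H1": sched}, DEFAULT_PARAMS,
                           memory_on=True), sched
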