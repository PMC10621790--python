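import os

# pin BLAS to one thread before numpy loads: reduction order then matches
# across machines, keeping seeded training/sampling runs bit-reproducible
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from warfarin_mipd.config import default_config
from warfarin_mipd.population import (REFERENCE_COVARIATES,
                                      Demographics, PopulationParameters,
                                      typical_parameters)


@pytest.fixture()
def config():
    return default_config()


@pytest.fixture()
def theta(config):
    return PopulationParameters.from_config(config.mechanistic,
                                            config.population)


@pytest.fixture()
def demographics(config):
    return Demographics.from_config(config.demographics)


@pytest.fixture()
def typical_psi(theta):
    """Reference patient (GG, *1*1, age 71) typical parameters."""
    return typical_parameters(theta, REFERENCE_COVARIATES)


@pytest.fixture()
def quiet_config(config):
    """Degenerate clinical-trial model: no noise, no IIV, one covariate
    class."""
    config.iov.sigma_eta = 0.0
    config.execution.tau_min = 0.0
    config.measurement.sigma = 0.0
    config.population.omegas = {}
    config.demographics.cyp2c9_freqs = {
        "*1*1": 1.0, "*1*2": 0.0, "*1*3": 0.0,
        "*2*2": 0.0, "*2*3": 0.0, "*3*3": 0.0}
    config.demographics.vkorc1_freqs = {"GG": 1.0, "GA": 0.0, "AA": 0.0}
    config.demographics.age_mean = 71.0
    config.demographics.age_sd = 0.0
    return config


def bateman_concentration(dose_mg, t_h, psi):
    """Closed-form single-dose concentration for first-order absorption.

    Independent oracle for the ODE drivers: D ka / (V (ka - ke)) *
    (exp(-ke t) - exp(-ka t)).
    """
    t = np.asarray(t_h, dtype=float)
    return (dose_mg * psi.ka / (psi.V * (psi.ka - psi.ke))
            * (np.exp(-psi.ke * t) - np.exp(-psi.ka * t)))
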