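import logging

import numpy as np
import pytest

from seabird_ipm.inference import MCMCConfig, ModelConfig, PriorSpec, run_mcmc
from seabird_ipm.io import bundle_from_study
from seabird_ipm.synthetic import SyntheticConfig, generate_study

# the forward-recursion logger flags deliberately impossible test histories
logging.getLogger("seabird_ipm.likelihoods").setLevel(logging.ERROR)


def constant_config(**overrides) -> SyntheticConfig:
    """Study configuration with time-constant true rates (no annual
    variation), for recovery and oracle tests.

    Immigrant variability is moderate (cv 0.35) here: under the full
    conditions the breeder series' swings are shared between rate variation
    and immigration, so with rates frozen the default immigration cv would
    overstate zero-immigration crash years.
    """
    base = dict(sd_phi0=0, sd_phi2=0, sd_rho=0, sd_psi_b=0, sd_psi_s=0,
                sd_pi=0, sd_p_Y=0, sd_p_P=0, immigration_cv=0.35)
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def small_study():
    """Small, fast synthetic study with constant truth."""
    return generate_study(constant_config(seed=7, T=12, n_ringed_per_year=30,
                                          target_breeders=400))


@pytest.fixture(scope="session")
def small_fit(small_study):
    """Quick fit of the small study (constant-rate model)."""
    bundle = bundle_from_study(small_study)
    draws = run_mcmc(bundle, PriorSpec(),
                     MCMCConfig(n_chains=2, n_iterations=700, n_burnin=350,
                                thin=2, rng_seed=5),
                     ModelConfig())
    return small_study, bundle, draws


@pytest.fixture(scope="session")
def default_study():
    """Field-scale study under the default conditions (annual rate variation,
    no built-in behavioural couplings)."""
    return generate_study(SyntheticConfig(seed=21, T=28, n_ringed_per_year=80))


@pytest.fixture(scope="session")
def default_fit(default_study):
    """Fit of the default study with all demographic rates year-specific
    (the model the emulated analysis uses); shared by the derived-statistics
    and calibration tests."""
    bundle = bundle_from_study(default_study)
    draws = run_mcmc(bundle, PriorSpec(),
                     MCMCConfig(n_chains=2, n_iterations=2400, n_burnin=1200,
                                thin=2, rng_seed=9),
                     ModelConfig(time_varying=("phi0", "phi2", "rho3", "rho4",
                                               "rho5", "rho6", "psi_b", "psi_s",
                                               "pi_f", "pi_e")))
    return default_study, bundle, draws


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
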