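"""Does breeding propensity respond to habitat quality and competitors?

Fits the model with year-specific breeding rates to a study generated WITH
built-in negative density dependence of breeding propensity, then computes
the posterior partial correlations between status-specific propensity at t
and the population features at t-1 (each controlling for the other two).
Runs in a few minutes.
"""

import logging

from seabird_ipm import (
    MCMCConfig, ModelConfig, PriorSpec, SyntheticConfig,
    analysis_tables, generate_study, run_mcmc,
)
from seabird_ipm.io import bundle_from_study

logging.disable(logging.WARNING)

cfg = SyntheticConfig(seed=3, dd_psi_b=-1.0, dd_psi_s=-0.8,
                      quality_effect_psi_b=0.5, quality_effect_recruitment=0.5,
                      sd_psi_b=0.25, sd_psi_s=0.25)
study = generate_study(cfg)
bundle = bundle_from_study(study)

draws = run_mcmc(bundle, PriorSpec(),
                 MCMCConfig(n_chains=2, n_iterations=2400, n_burnin=1200,
                            thin=2, rng_seed=0),
                 ModelConfig(time_varying=("phi0", "phi2", "rho3", "rho4",
                                           "rho5", "rho6", "psi_b", "psi_s",
                                           "pi_f", "pi_e")))

counts = bundle.counts.sort_values("year")["count"].to_numpy(float)
growth, propensity = analysis_tables(draws, observed_counts=counts)

print("partial correlations of the breeding population growth rate:")
print(growth.round(3).to_string(index=False))
print("\nstatus-specific propensity at t vs population features at t-1:")
print(propensity.round(3).to_string(index=False))
print("\nNegative 'breeders' cells with P near 1 recover the built-in density")
print("dependence; P near 0.5 means no evidence for either sign.")
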