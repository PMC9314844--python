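"""Sampler determinism, initialization, diagnostics and predictive checks."""

import numpy as np
import pandas as pd
import pytest

from seabird_ipm.draws import PosteriorDraws
from seabird_ipm.inference import (
    MCMCConfig,
    ModelConfig,
    PriorSpec,
    convergence_report,
    initialize_state,
    posterior_predictive_check,
    run_mcmc,
)
from seabird_ipm.io import StudyBundle, bundle_from_study
from seabird_ipm.likelihoods import joint_loglik
from seabird_ipm.model import DemographicRates, ObservationModel
from seabird_ipm.synthetic import generate_study
from tests.conftest import constant_config


def _tiny_bundle():
    study = generate_study(constant_config(seed=3, T=8, n_ringed_per_year=12,
                                           target_breeders=250))
    return study, bundle_from_study(study)


def test_config_validation():
    with pytest.raises(ValueError):
        MCMCConfig(n_chains=1)
    with pytest.raises(ValueError):
        MCMCConfig(n_burnin=100, n_iterations=100)
    with pytest.raises(ValueError):
        ModelConfig(time_varying=("sigma_obs",))
    with pytest.raises(ValueError):
        PriorSpec(immigrant_low=0.5)


def test_same_seed_gives_identical_chains():
    _, bundle = _tiny_bundle()
    cfg = MCMCConfig(n_chains=2, n_iterations=160, n_burnin=80, thin=2, rng_seed=17)
    a = run_mcmc(bundle, PriorSpec(), cfg, ModelConfig())
    b = run_mcmc(bundle, PriorSpec(), cfg, ModelConfig())
    for name in a.params:
        assert np.array_equal(a.params[name], b.params[name])
    assert np.array_equal(a.latent["N"], b.latent["N"])


def test_initialize_state_properties():
    study, bundle = _tiny_bundle()
    prior = PriorSpec()
    params, latent = initialize_state(bundle, prior, ModelConfig(), seed=2)
    params2, latent2 = initialize_state(bundle, prior, ModelConfig(), seed=2)
    for n in params:
        assert np.array_equal(params[n], params2[n])

    # finite joint density at the starting point
    T = bundle.T
    rates = DemographicRates.constant(
        T, **{k: float(params[k][0]) for k in
              ("phi0", "phi2", "rho3", "rho4", "rho5", "rho6",
               "psi_b", "psi_s", "pi_f", "pi_e")})
    obs = ObservationModel(T=T, sigma_obs=float(params["sigma_obs"][0]),
                           p_Y=float(params["p_Y"][0]), p_P=float(params["p_P"][0]),
                           p_R=float(params["p_R"][0]))
    ll = joint_loglik(bundle.counts, bundle.histories, bundle.reproduction,
                      rates, obs, latent)
    assert np.isfinite(ll)

    # latent breeder totals track the observed counts
    N = latent.counts()
    B = N[:, 6] + N[:, 7]
    C = bundle.counts.sort_values("year")["count"].to_numpy(float)
    assert np.all(np.abs(B - C) / C < 0.2)


def test_prior_recovery_without_data():
    """With no data the sampler reproduces the prior (checked on a small
    latent space where the chain can traverse it), and immigrant draws span
    negative values as the Uniform(-5, 1000) prior allows."""
    empty = StudyBundle(counts=None, histories=None, histories_frame=None,
                        reproduction=None, patches=None, T=3)
    draws = run_mcmc(empty, PriorSpec(n0_upper=12),
                     MCMCConfig(n_chains=2, n_iterations=12000, n_burnin=2000,
                                thin=5, rng_seed=4),
                     ModelConfig())
    for name in ("psi_b", "psi_s", "rho4", "phi0"):
        a = draws.flat_param(name)
        assert abs(a.mean() - 0.5) < 0.08, name
    I = draws.flat_latent("I")[:, 1:]
    assert I.min() < 0.0
    # the immigrant series explores its huge uniform range slowly (its value
    # is tied to the latent flows), so the mean carries a large MC error
    assert abs(I.mean() - 497.5) < 150.0


def test_convergence_report_psrf_and_ess():
    rng = np.random.default_rng(0)
    chain = rng.standard_normal(400)

    def make(params):
        return PosteriorDraws(params=params,
                              latent={"N": np.zeros((2, 400, 3, 9))}, T=3)

    dup = make({"theta": np.vstack([chain, chain])})
    rep = convergence_report(dup).set_index("parameter")
    assert rep.loc["theta", "psrf"] == 1.0  # duplicated chains

    apart = make({"theta": np.vstack([np.zeros(400), np.ones(400)])})
    rep = convergence_report(apart).set_index("parameter")
    assert np.isinf(rep.loc["theta", "psrf"])

    iid = make({"theta": rng.standard_normal((2, 2000))})
    rep = convergence_report(iid).set_index("parameter")
    assert abs(rep.loc["theta", "ess"] - 4000) / 4000 < 0.10

    single = PosteriorDraws(params={"theta": np.zeros((1, 10))}, latent={}, T=3)
    with pytest.raises(ValueError):
        convergence_report(single)


def test_posterior_predictive_checks(small_fit):
    """Data simulated from the model yield non-extreme Bayesian p-values;
    corrupting one count year is detected."""
    study, bundle, draws = small_fit
    pvals = posterior_predictive_check(draws, bundle, seed=1)
    assert set(pvals) == {"counts", "reproduction"}
    for v in pvals.values():
        assert 0.0 <= v <= 1.0
    assert 0.02 <= pvals["counts"] <= 0.98  # fitted model, no gross misfit

    # corrupt the reproduction stream: the Poisson model has no free
    # dispersion parameter, so inflated fledgling counts are detected
    # (the count stream is robust to single-year corruption because the
    # annual immigrant pulse and the free count-error SD can absorb it)
    corrupt = bundle.reproduction.copy()
    mix = corrupt["category"] == "MIX"
    corrupt.loc[mix, "n_fledglings"] = (3 * corrupt.loc[mix, "n_fledglings"]).astype(int)
    bad_bundle = StudyBundle(counts=bundle.counts, histories=bundle.histories,
                             histories_frame=bundle.histories_frame,
                             reproduction=corrupt, patches=None,
                             T=bundle.T)
    bad_draws = run_mcmc(bad_bundle, PriorSpec(),
                         MCMCConfig(n_chains=2, n_iterations=700, n_burnin=350,
                                    thin=2, rng_seed=6), ModelConfig())
    p_bad = posterior_predictive_check(bad_draws, bad_bundle, seed=1)
    assert p_bad["reproduction"] < 0.05


def test_posterior_contraction_with_more_data():
    """More capture histories shrink the credible intervals of survival and
    breeding rate."""
    widths = {}
    for n_ringed in (20, 120):
        study = generate_study(constant_config(seed=13, T=12, n_ringed_per_year=n_ringed,
                                               target_breeders=400))
        draws = run_mcmc(bundle_from_study(study), PriorSpec(),
                         MCMCConfig(n_chains=2, n_iterations=2200, n_burnin=1100,
                                    thin=2, rng_seed=8), ModelConfig())
        for name in ("phi2", "psi_b"):
            a = draws.flat_param(name)
            lo, hi = np.percentile(a, [2.5, 97.5])
            widths.setdefault(name, []).append(hi - lo)
    for name, (w_small, w_large) in widths.items():
        assert w_large < w_small, name


def test_empty_draws_rejected(small_fit):
    study, bundle, draws = small_fit
    with pytest.raises(ValueError):
        posterior_predictive_check(draws, StudyBundle(
            counts=None, histories=None, histories_frame=None,
            reproduction=None, patches=None, T=bundle.T), seed=0)
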