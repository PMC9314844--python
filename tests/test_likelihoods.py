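"""The three likelihood components against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from seabird_ipm.model import DemographicRates, ObservationModel
from seabird_ipm.likelihoods import (
    CaptureHistory,
    forward_loglik,
    forward_loglik_pooled,
    pool_histories,
    loglik_counts,
    loglik_reproduction,
    joint_loglik,
    state_logprob,
    validate_history,
)
from seabird_ipm.io import bundle_from_study
from seabird_ipm.synthetic import flows_from_trajectory
from tests.conftest import constant_config


def random_model(seed, T):
    rng = np.random.default_rng(seed)
    rates = DemographicRates(
        T=T, phi0=rng.uniform(0.3, 0.9, T), phi2=rng.uniform(0.5, 0.95, T),
        rho3=rng.uniform(0.0, 0.5, T), rho4=rng.uniform(0.1, 0.7, T),
        rho5=rng.uniform(0.2, 0.8, T), rho6=rng.uniform(0.3, 0.9, T),
        psi_b=rng.uniform(0.5, 0.99, T), psi_s=rng.uniform(0.3, 0.9, T),
        pi_f=0.16, pi_e=0.36,
    )
    obs = ObservationModel(T=T, sigma_obs=0.05, p_Y=rng.uniform(0.02, 0.2, T),
                           p_P=rng.uniform(0.4, 0.95, T), p_R=rng.uniform(0.9, 0.999))
    return rates, obs


def brute_force_loglik(codes, ring_year, rates, obs):
    """Exhaustive sum over all latent state paths (independent oracle)."""
    T = rates.T
    rho = rates.rho_matrix()

    def trans(t, s, s2):
        f0, f2 = rates.phi0[t], rates.phi2[t]
        if s == 8:
            return 1.0 if s2 == 8 else 0.0
        if s == 0:
            return {1: f0, 8: 1 - f0}.get(s2, 0.0)
        if 1 <= s <= 5:
            r = rho[s - 1, t] if s <= 4 else 1.0
            d = {6: f2 * r, 8: 1 - f2}
            if s < 5:
                d[s + 1] = f2 * (1 - r)
            return d.get(s2, 0.0)
        psi = rates.psi_b[t] if s == 6 else rates.psi_s[t]
        return {6: f2 * psi, 7: f2 * (1 - psi), 8: 1 - f2}.get(s2, 0.0)

    def emit(t, s, c):
        if s == 8:
            return 1.0 if c == 0 else 0.0
        p, code = ((obs.p_Y[t], 1) if s == 0 else (obs.p_P[t], 1) if s <= 5
                   else (obs.p_R, 2) if s == 6 else (obs.p_R, 3))
        return 1 - p if c == 0 else (p if c == code else 0.0)

    L = T - 1 - ring_year
    if L <= 0:
        return 0.0
    total = 0.0
    for path in itertools.product(range(9), repeat=L):
        p = {0: rates.phi0[ring_year], 8: 1 - rates.phi0[ring_year]}.get(path[0], 0.0)
        if p == 0.0:
            continue
        p *= emit(ring_year + 1, path[0], codes[ring_year + 1])
        for k in range(1, L):
            if p == 0.0:
                break
            t = ring_year + k
            p *= trans(t, path[k - 1], path[k])
            if p:
                p *= emit(t + 1, path[k], codes[t + 1])
        total += p
    return np.log(total) if total > 0 else -np.inf


def test_forward_equals_brute_force_enumeration():
    """Forward recursion equals the exhaustive path sum for every history of
    length <= 4 (the acceptance suite extends this to length 5)."""
    T = 5
    rates, obs = random_model(0, T)
    checked = 0
    for ring in range(T - 1):
        horizon = T - 1 - ring
        for seq in itertools.product(range(4), repeat=horizon):
            codes = np.zeros(T, dtype=np.int8)
            codes[ring + 1:] = seq
            bf = brute_force_loglik(codes, ring, rates, obs)
            fw = forward_loglik(CaptureHistory(ring_year=ring, codes=codes), rates, obs)
            if np.isinf(bf) and np.isinf(fw):
                checked += 1
                continue
            assert fw == pytest.approx(bf, abs=1e-10)
            checked += 1
    assert checked == 4 ** 4 + 4 ** 3 + 4 ** 2 + 4


def test_forward_total_probability_is_one():
    """For fixed ringing the forward likelihood sums to 1 over all possible
    observation sequences."""
    T = 5
    rates, obs = random_model(1, T)
    for ring in (0, 1):
        horizon = T - 1 - ring
        total = 0.0
        for seq in itertools.product(range(4), repeat=horizon):
            codes = np.zeros(T, dtype=np.int8)
            codes[ring + 1:] = seq
            ll = forward_loglik(CaptureHistory(ring_year=ring, codes=codes), rates, obs)
            if np.isfinite(ll):
                total += np.exp(ll)
        assert total == pytest.approx(1.0, abs=1e-12)


def test_forward_never_seen_closed_form():
    rates = DemographicRates.constant(2, phi0=0.6, phi2=0.8, rho3=0.1, rho4=0.4,
                                      rho5=0.5, rho6=0.7, psi_b=0.9, psi_s=0.7,
                                      pi_f=0.2, pi_e=0.4)
    obs = ObservationModel(T=2, sigma_obs=0.05, p_Y=0.12, p_P=0.8, p_R=0.99)
    ll = forward_loglik(CaptureHistory(ring_year=0, codes=[0, 0]), rates, obs)
    assert ll == pytest.approx(np.log((1 - 0.6) + 0.6 * (1 - 0.12)), abs=1e-12)


def test_forward_impossible_history_is_neg_inf():
    """A recruited bird is seen almost surely; breeder-gap-breeder with p_R=1
    has zero probability, as does a breeder code at age 2."""
    T = 8
    rates, obs = random_model(2, T)
    obs_sure = ObservationModel(T=T, sigma_obs=0.05, p_Y=obs.p_Y, p_P=obs.p_P, p_R=1.0)
    codes = np.zeros(T, dtype=np.int8)
    codes[4], codes[6] = 2, 2  # breeder, unseen, breeder
    ll = forward_loglik(CaptureHistory(ring_year=0, codes=codes), rates, obs_sure)
    assert ll == -np.inf

    codes = np.zeros(T, dtype=np.int8)
    codes[2] = 2  # breeder at age 2
    ll = forward_loglik(CaptureHistory(ring_year=0, codes=codes), rates, obs)
    assert ll == -np.inf
    with pytest.raises(ValueError):
        validate_history(CaptureHistory(ring_year=0, codes=codes), T)


def test_pooling_preserves_likelihood_and_exchangeability():
    T = 6
    rates, obs = random_model(3, T)
    rng = np.random.default_rng(8)
    hists = []
    for _ in range(60):
        ring = int(rng.integers(0, T - 1))
        codes = np.zeros(T, dtype=np.int8)
        # build a structurally valid history: maybe one pre-breeder sighting
        if ring + 2 < T and rng.random() < 0.6:
            codes[ring + 1] = 1
        hists.append(CaptureHistory(ring_year=ring, codes=codes))
    hm = pool_histories(hists, T)
    assert hm.codes.shape[0] < len(hists)  # duplicates were pooled
    total = sum(forward_loglik(h, rates, obs) for h in hists)
    assert forward_loglik_pooled(hm, rates, obs) == pytest.approx(total, abs=1e-9)
    # exchangeability: shuffled input gives the same pooled likelihood
    rng.shuffle(hists)
    hm2 = pool_histories(hists, T)
    assert forward_loglik_pooled(hm2, rates, obs) == pytest.approx(total, abs=1e-9)


def test_counts_loglik_closed_form_and_oracle(rng):
    # at the mode with one year: -log(sigma * C * sqrt(2 pi))
    ll = loglik_counts(np.array([1000.0]), np.array([1000.0]), 0.05)
    assert ll == pytest.approx(-np.log(0.05 * 1000 * np.sqrt(2 * np.pi)), abs=1e-12)

    # with C != B the likelihood falls without bound as sigma -> 0
    # (monotonically once sigma is below the log-ratio |log C/B| ~ 0.095)
    lls = [loglik_counts(np.array([1100.0]), np.array([1000.0]), s)
           for s in (0.08, 0.05, 0.02, 0.01, 0.004)]
    assert np.all(np.diff(lls) < 0)
    assert lls[-1] < -200

    # arbitrary series against scipy's lognormal density
    C = rng.uniform(500, 2500, 20)
    B = rng.uniform(500, 2500, 20)
    sigma = 0.07
    oracle = stats.lognorm.logpdf(C, s=sigma, scale=B).sum()
    assert loglik_counts(C, B, sigma) == pytest.approx(oracle, abs=1e-10)


def test_reproduction_weighted_mix_rate_and_oracle():
    # hand-computed weighted per-nest rate: 2*(20*0.16 + 80*0.36)/100 = 0.64
    table = pd.DataFrame({"year": [0], "category": ["MIX"],
                          "n_nests": [50], "n_fledglings": [30]})
    ll = loglik_reproduction(table, 0.16, 0.36, np.array([20.0]), np.array([80.0]))
    assert ll == pytest.approx(stats.poisson.logpmf(30, 0.64 * 50), abs=1e-12)

    assert loglik_reproduction(pd.DataFrame(columns=["year", "category", "n_nests", "n_fledglings"]),
                               0.2, 0.3, np.array([10.0]), np.array([10.0])) == 0.0

    # per-cell agreement with scipy across all three categories
    table = pd.DataFrame({
        "year": [0, 0, 0], "category": ["FF", "EE", "MIX"],
        "n_nests": [12, 40, 60], "n_fledglings": [4, 30, 35],
    })
    ll = loglik_reproduction(table, 0.16, 0.36, np.array([20.0]), np.array([80.0]))
    oracle = (stats.poisson.logpmf(4, 2 * 0.16 * 12)
              + stats.poisson.logpmf(30, 2 * 0.36 * 40)
              + stats.poisson.logpmf(35, 0.64 * 60))
    assert ll == pytest.approx(oracle, abs=1e-12)

    # zero rate with positive fledglings is impossible
    table = pd.DataFrame({"year": [0], "category": ["FF"],
                          "n_nests": [5], "n_fledglings": [2]})
    assert loglik_reproduction(table, 0.0, 0.3, np.array([5.0]), np.array([5.0])) == -np.inf


def test_state_logprob_matches_scipy_oracle(small_study):
    """The state-process log-probability equals the sum of scipy pmfs
    evaluated at the exact simulated flows."""
    traj = small_study.truth["trajectory"]
    la = flows_from_trajectory(traj)
    rates = traj.rates
    got = state_logprob(la, rates)

    N = la.counts()
    expected = 0.0
    for t in range(la.T - 1):
        lam = rates.phi0[t] * (N[t, 6] * rates.pi_f[t] + N[t, 7] * rates.pi_e[t])
        expected += stats.poisson.logpmf(la.ypois[t], lam)
        expected += stats.binom.logpmf(la.p2b[t], N[t, 0], rates.phi0[t])
        rho = [rates.rho3[t], rates.rho4[t], rates.rho5[t], rates.rho6[t], 1.0]
        for i in range(5):
            n = N[t, 1 + i]
            r, s = la.rec[t, i], la.stay[t, i] if i < 4 else 0
            probs = [rates.phi2[t] * rho[i], rates.phi2[t] * (1 - rho[i]), 1 - rates.phi2[t]]
            expected += stats.multinomial.logpmf([r, s, n - r - s], n, probs)
        for j in range(3):
            psi = rates.psi_b[t] if j < 2 else rates.psi_s[t]
            n = N[t, 6 + j]
            e, sk = la.bE[t, j], la.bS[t, j]
            probs = [rates.phi2[t] * psi, rates.phi2[t] * (1 - psi), 1 - rates.phi2[t]]
            expected += stats.multinomial.logpmf([e, sk, n - e - sk], n, probs)
    assert got == pytest.approx(float(expected), abs=1e-8)


def test_joint_loglik_is_definitional_sum(small_study):
    study = small_study
    bundle = bundle_from_study(study)
    traj = study.truth["trajectory"]
    la = flows_from_trajectory(traj)
    rates = traj.rates
    obs = study.truth["observation_model"]

    total = joint_loglik(bundle.counts, bundle.histories, bundle.reproduction,
                         rates, obs, la)
    assert np.isfinite(total)  # finite at the generating configuration

    N = la.counts()
    parts = (state_logprob(la, rates)
             + loglik_counts(bundle.counts.sort_values("year")["count"].to_numpy(),
                             (N[:, 6] + N[:, 7]).astype(float), obs.sigma_obs)
             + forward_loglik_pooled(bundle.histories, rates, obs)
             + loglik_reproduction(bundle.reproduction, rates.pi_f, rates.pi_e,
                                   N[:, 6], N[:, 7]))
    assert total == pytest.approx(parts, abs=1e-10)

    # separability: removing one stream changes only its term
    no_rep = joint_loglik(bundle.counts, bundle.histories, None, rates, obs, la)
    assert total - no_rep == pytest.approx(
        loglik_reproduction(bundle.reproduction, rates.pi_f, rates.pi_e,
                            N[:, 6], N[:, 7]), abs=1e-10)
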