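"""Stochastic projection of the nine-state life cycle."""

import numpy as np
import pytest
from scipy import stats

from seabird_ipm.model import DemographicRates, PopulationState, Y, P2, P6, F, E, S
from seabird_ipm.projection import (
    expectation_matrix,
    project_expectation,
    simulate_transition,
    simulate_trajectory,
)

RATES = dict(phi0=0.65, phi2=0.81, rho3=0.13, rho4=0.41, rho5=0.53,
             rho6=0.67, psi_b=0.90, psi_s=0.69, pi_f=0.16, pi_e=0.36)


def _slice(**over):
    vals = {**RATES, **over}
    return DemographicRates.constant(2, **vals).at(0)


def test_forced_recruitment_at_age_seven():
    # a surviving pre-breeder of age 6 always recruits (rate fixed to 1)
    state = np.zeros(9)
    state[P6] = 50
    out = project_expectation(_slice(phi2=1.0), state, I_next=0.0)
    assert out[F] == pytest.approx(50.0)


def test_all_zero_rates_annihilate():
    r = _slice(**{k: 0.0 for k in RATES})
    state = np.array([10, 20, 30, 5, 5, 5, 40, 100, 12])
    out = project_expectation(r, state, I_next=0.0)
    assert np.all(out == 0.0)


def test_negative_state_rejected():
    state = np.zeros(9)
    state[0] = -1
    with pytest.raises(ValueError):
        project_expectation(_slice(), state)


def test_out_of_range_rate_rejected():
    with pytest.raises(ValueError):
        DemographicRates.constant(2, **{**RATES, "phi2": 1.2})


def test_expectation_matches_monte_carlo(rng):
    """project_expectation equals the Monte-Carlo mean of simulate_transition."""
    state = np.array([120, 80, 60, 30, 15, 6, 90, 400, 50])
    r = _slice()
    # integer immigrant pulse: the realized inflow is the rounded value, so
    # the expectation identity is exact only on integers
    n = 30_000
    total = np.zeros(9)
    total2 = np.zeros(9)
    for _ in range(n):
        x = simulate_transition(r, state, I_next=37.0, rng=rng)
        total += x
        total2 += x.astype(float) ** 2
    mean = total / n
    se = np.sqrt(np.maximum(total2 / n - mean ** 2, 1e-12) / n)
    expected = project_expectation(r, state, I_next=37.0)
    assert np.all(np.abs(mean - expected) <= 4.0 * se + 1e-9)


def test_transition_respects_source_bounds(rng):
    """Binomial destinations never exceed their source class."""
    state = np.array([40, 25, 18, 12, 9, 4, 30, 120, 15])
    r = _slice()
    for _ in range(3000):
        nxt = simulate_transition(r, state, 0.0, rng)
        # recruits + immigrants(0): F' bounded by all pre-breeders of ages 2-6
        assert nxt[F] <= state[P2:P6 + 1].sum()
        assert nxt[E] + nxt[S] <= state[F] + state[E] + state[S]
        assert nxt[P2] <= state[Y]


def test_single_class_binomial_distribution(rng):
    """With only experienced breeders, E' ~ Binomial(n, phi2 * psi_b)."""
    state = np.zeros(9, dtype=int)
    state[E] = 200
    r = _slice(phi2=0.8, psi_b=0.9)
    n_rep = 50_000
    draws = np.array([simulate_transition(r, state, 0.0, rng)[E] for _ in range(n_rep)])
    k = np.arange(201)
    pmf = stats.binom.pmf(k, 200, 0.8 * 0.9)
    # pool tail bins so expected counts stay comfortably above 5
    edges = [0]
    acc = 0.0
    for i, p in enumerate(pmf):
        acc += p
        if acc * n_rep >= 50:
            edges.append(i + 1)
            acc = 0.0
    edges[-1] = 201
    obs = np.array([(draws >= lo) & (draws < hi) for lo, hi in zip(edges[:-1], edges[1:])]).sum(axis=1)
    exp = np.array([pmf[lo:hi].sum() for lo, hi in zip(edges[:-1], edges[1:])]) * n_rep
    chi2 = ((obs - exp) ** 2 / exp).sum()
    p_val = stats.chi2.sf(chi2, len(obs) - 1)
    assert p_val > 0.01


def test_zero_survival_empties_population(rng):
    r = _slice(phi0=0.0, phi2=0.0)
    state = np.array([10, 10, 10, 10, 10, 10, 10, 10, 10])
    nxt = simulate_transition(r, state, 0.0, rng)
    assert np.all(nxt == 0)


def test_trajectory_aggregation_identity():
    rates = DemographicRates.constant(10, **RATES)
    init = np.array([120, 80, 60, 30, 15, 6, 90, 400, 50])
    traj = simulate_trajectory(rates, np.full(10, 40.0), init, 10, rng_seed=3)
    assert np.array_equal(traj.class_counts_from_individuals(),
                          traj.population.counts)
    assert np.array_equal(traj.population.counts[0], init)


def test_trajectory_determinism():
    rates = DemographicRates.constant(8, **RATES)
    init = np.array([50, 40, 30, 20, 10, 5, 40, 150, 20])
    a = simulate_trajectory(rates, np.full(8, 20.0), init, 8, rng_seed=11)
    b = simulate_trajectory(rates, np.full(8, 20.0), init, 8, rng_seed=11)
    assert np.array_equal(a.states, b.states)
    assert np.array_equal(a.population.counts, b.population.counts)


def test_trajectory_too_short_rejected():
    rates = DemographicRates.constant(2, **RATES)
    with pytest.raises(ValueError):
        simulate_trajectory(rates, np.zeros(1), np.zeros(9, dtype=int), 1, 0)


def test_realized_growth_matches_dominant_eigenvalue():
    """With constant rates and no immigration the realized log growth rate
    converges to the log of the expectation matrix's dominant eigenvalue."""
    rates = DemographicRates.constant(28, **RATES)
    A = expectation_matrix(rates.at(0))
    lam = float(np.max(np.abs(np.linalg.eigvals(A))))
    # start at the stable structure so transients are negligible
    eigvals, eigvecs = np.linalg.eig(A)
    v = np.abs(np.real(eigvecs[:, np.argmax(np.abs(eigvals))]))
    init = np.rint(v / v.sum() * 60_000).astype(np.int64)
    logs = []
    for seed in range(25):
        traj = simulate_trajectory(rates, np.zeros(28), init, 28, rng_seed=seed)
        tot = traj.population.counts.sum(axis=1)
        logs.append(np.log(tot[-1] / tot[0]) / 27)
    logs = np.asarray(logs)
    se = logs.std(ddof=1) / np.sqrt(len(logs))
    assert abs(logs.mean() - np.log(lam)) < max(4 * se, 5e-4)


def test_population_state_invariants():
    counts = np.array([[1, 2, 3, 4, 5, 6, 7, 8, 9]])
    ps = PopulationState(counts)
    assert ps.breeders[0] == 7 + 8
    with pytest.raises(ValueError):
        PopulationState(np.array([[1, -2, 3, 4, 5, 6, 7, 8, 9]]))
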