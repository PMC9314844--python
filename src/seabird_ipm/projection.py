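"""Stochastic projection of the nine-state life cycle.

The census is pre-breeding: breeders counted at ``t`` rear chicks during
season ``t``; survivors of those chicks appear as yearlings at ``t+1``.
Demographic stochasticity follows the generative scheme

* ``Y[t+1] ~ Poisson((F pi_f + E pi_e) phi0)``  (fledging then first-year
  survival, a thinned Poisson),
* ``P2[t+1] ~ Binomial(Y[t], phi0)``,
* each pre-breeder class ``P_i`` splits ``(recruit, stay, die)`` as a
  multinomial with probabilities ``(phi2 rho_{i+1}, phi2 (1-rho_{i+1}),
  1-phi2)`` -- recruitment at age 7 is forced, so surviving ``P6`` always
  recruit,
* each of ``F``, ``E``, ``S`` splits ``(breed -> E, skip -> S, die)`` with
  breeding probability ``psi_b`` (F, E) or ``psi_s`` (S) conditional on
  ``phi2``,
* an annual immigrant pulse enters the first-time-breeder class:
  ``F[t+1] = recruits + round(max(I[t+1], 0))``.  The immigrant parameter is
  continuous and may be negative under its prior; only its clamped, rounded
  value enters the integer state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    N_CLASSES,
    DemographicRates,
    PopulationState,
    RateSlice,
    Y, P2, P3, P4, P5, P6, F, E, S,
)

# individual-level codes beyond the census classes
CHICK = 10
DEAD = -1
ABSENT = -9

ORIGIN_INITIAL = 0
ORIGIN_LOCAL = 1
ORIGIN_IMMIGRANT = 2


def _check_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state)
    if state.shape != (N_CLASSES,):
        raise ValueError(f"state must be a length-{N_CLASSES} vector")
    if np.any(state < 0) or not np.all(np.isfinite(state.astype(float))):
        raise ValueError("class counts must be non-negative and finite")
    return state


def immigrant_inflow(I_next: float) -> int:
    """Realized integer contribution of the immigrant pulse to F."""
    return int(np.rint(max(float(I_next), 0.0)))


def expectation_matrix(rates: RateSlice) -> np.ndarray:
    """9x9 matrix A with E[n(t+1)] = A n(t) (immigrants added separately)."""
    rates.validate()
    A = np.zeros((N_CLASSES, N_CLASSES))
    A[Y, F] = rates.pi_f * rates.phi0
    A[Y, E] = rates.pi_e * rates.phi0
    A[P2, Y] = rates.phi0
    rho = [rates.rho3, rates.rho4, rates.rho5, rates.rho6, 1.0]
    for k, src in enumerate((P2, P3, P4, P5, P6)):
        A[F, src] = rates.phi2 * rho[k]
        if src != P6:
            A[src + 1, src] = rates.phi2 * (1.0 - rho[k])
    for src, psi in ((F, rates.psi_b), (E, rates.psi_b), (S, rates.psi_s)):
        A[E, src] = rates.phi2 * psi
        A[S, src] = rates.phi2 * (1.0 - psi)
    return A


def project_expectation(rates: RateSlice, state: np.ndarray, I_next: float = 0.0) -> np.ndarray:
    """Expected class vector at ``t+1`` given the state at ``t``."""
    state = _check_state(state)
    expected = expectation_matrix(rates) @ state.astype(float)
    expected[F] += max(float(I_next), 0.0)
    return expected


def simulate_transition(
    rates: RateSlice,
    state: np.ndarray,
    I_next: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One stochastic annual transition at the class-count level.

    Destination counts from binomial/multinomial splits never exceed their
    source class; the yearling inflow is Poisson.
    """
    rates.validate()
    state = _check_state(state).astype(np.int64)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    nxt = np.zeros(N_CLASSES, dtype=np.int64)
    nxt[Y] = rng.poisson(rates.phi0 * (state[F] * rates.pi_f + state[E] * rates.pi_e))
    nxt[P2] = rng.binomial(state[Y], rates.phi0)
    rho = [rates.rho3, rates.rho4, rates.rho5, rates.rho6, 1.0]
    recruits = 0
    for k, src in enumerate((P2, P3, P4, P5, P6)):
        rec, stay, _ = rng.multinomial(
            state[src],
            [rates.phi2 * rho[k], rates.phi2 * (1.0 - rho[k]), 1.0 - rates.phi2],
        )
        recruits += rec
        if src != P6:
            nxt[src + 1] = stay
    nxt[F] = recruits + immigrant_inflow(I_next)
    for src, psi in ((F, rates.psi_b), (E, rates.psi_b), (S, rates.psi_s)):
        to_e, to_s, _ = rng.multinomial(
            state[src], [rates.phi2 * psi, rates.phi2 * (1.0 - psi), 1.0 - rates.phi2]
        )
        nxt[E] += to_e
        nxt[S] += to_s
    return nxt


@dataclass
class Trajectory:
    """Individual-based realization of the population process.

    ``states`` is (n_individuals, T) with entries in {0..8} while an
    individual is alive and censused, ``CHICK`` in its birth year, and
    ``ABSENT``/``DEAD`` otherwise.  Aggregating rows reproduces
    ``population.counts`` exactly.  ``rates`` holds the realized annual
    rates (they differ from the nominal input when a state-dependent
    modifier, e.g. density dependence, was active).
    """

    population: PopulationState
    states: np.ndarray
    origin: np.ndarray
    birth_year: np.ndarray
    immigrant_inflow: np.ndarray
    rates: "DemographicRates | None" = None

    def class_counts_from_individuals(self) -> np.ndarray:
        T = self.population.T
        counts = np.zeros((T, N_CLASSES), dtype=np.int64)
        for c in range(N_CLASSES):
            counts[:, c] = (self.states == c).sum(axis=0)
        return counts


class _Ledger:
    """Growable individual-by-year state matrix."""

    def __init__(self, T: int, capacity: int = 1024):
        self.T = T
        self.M = np.full((capacity, T), ABSENT, dtype=np.int16)
        self.origin = np.zeros(capacity, dtype=np.int8)
        self.birth = np.full(capacity, -1, dtype=np.int32)
        self.n = 0

    def add(self, count: int, t: int, code: int, origin: int, birth: int) -> np.ndarray:
        if count == 0:
            return np.empty(0, dtype=np.int64)
        while self.n + count > self.M.shape[0]:
            grow = self.M.shape[0]
            self.M = np.vstack([self.M, np.full((grow, self.T), ABSENT, dtype=np.int16)])
            self.origin = np.concatenate([self.origin, np.zeros(grow, dtype=np.int8)])
            self.birth = np.concatenate([self.birth, np.full(grow, -1, dtype=np.int32)])
        idx = np.arange(self.n, self.n + count)
        self.M[idx, t] = code
        self.origin[idx] = origin
        self.birth[idx] = birth
        self.n += count
        return idx


def simulate_trajectory(
    rates: DemographicRates,
    I_series: np.ndarray,
    initial_state: np.ndarray,
    T: int | None = None,
    rng_seed: np.random.Generator | int | None = None,
    modifier=None,
) -> Trajectory:
    """Simulate the full population individual-by-individual for T years.

    Individual transitions use the same Bernoulli cascades as
    :func:`simulate_transition`, so class totals have the identical
    distribution, and the per-individual paths support the generation of
    capture-resighting histories.  ``modifier(t, counts_t, rate_slice)``,
    if given, may return an adjusted :class:`RateSlice` for year ``t``
    (e.g. density-dependent breeding rates); realized rates are recorded
    on the returned trajectory.
    """
    T = rates.T if T is None else T
    if T < 2:
        raise ValueError("need at least 2 years")
    if T > rates.T:
        raise ValueError("rates series shorter than requested horizon")
    I_series = np.asarray(I_series, dtype=float)
    if I_series.shape != (T,):
        raise ValueError(f"I_series must have length {T}")
    initial_state = _check_state(initial_state).astype(np.int64)
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed

    led = _Ledger(T, capacity=int(initial_state.sum() * 2 + 64))
    for c in range(N_CLASSES):
        led.add(int(initial_state[c]), 0, c, ORIGIN_INITIAL, -1)
    inflow = np.zeros(T, dtype=np.int64)
    realized: list[RateSlice] = []

    for t in range(T - 1):
        M = led.M
        cur = M[: led.n, t]
        r = rates.at(t)
        if modifier is not None:
            counts_t = np.array([(cur == c).sum() for c in range(N_CLASSES)], dtype=np.int64)
            r = modifier(t, counts_t, r)
            r.validate()
        realized.append(r)

        # chick production by breeders at t (season t); chicks occupy year t
        n_f = int((cur == F).sum())
        n_e = int((cur == E).sum())
        chicks = int(rng.poisson(r.pi_f, n_f).sum() + rng.poisson(r.pi_e, n_e).sum())
        led.add(chicks, t, CHICK, ORIGIN_LOCAL, t)
        M = led.M  # may have grown
        cur = M[: led.n, t]

        # survival/transition cascades, vectorized per class
        def split(idx, p_survive, p_move_given_survive, code_move, code_stay):
            u = rng.random(idx.size)
            alive = u < p_survive
            v = rng.random(idx.size)
            move = alive & (v < p_move_given_survive)
            stay = alive & ~move
            M[idx[move], t + 1] = code_move
            M[idx[stay], t + 1] = code_stay
            # dead rows keep ABSENT at t+1

        split(np.flatnonzero(cur == CHICK), r.phi0, 1.0, Y, Y)
        split(np.flatnonzero(cur == Y), r.phi0, 1.0, P2, P2)
        rho = [r.rho3, r.rho4, r.rho5, r.rho6, 1.0]
        for k, src in enumerate((P2, P3, P4, P5, P6)):
            stay_code = src + 1 if src != P6 else F  # P6 survivors always recruit
            split(np.flatnonzero(cur == src), r.phi2, rho[k], F, stay_code)
        split(np.flatnonzero(cur == F), r.phi2, r.psi_b, E, S)
        split(np.flatnonzero(cur == E), r.phi2, r.psi_b, E, S)
        split(np.flatnonzero(cur == S), r.phi2, r.psi_s, E, S)

        inflow[t + 1] = immigrant_inflow(I_series[t + 1])
        led.add(int(inflow[t + 1]), t + 1, F, ORIGIN_IMMIGRANT, -1)

    # chicks of the final season (ringable, but never censused)
    cur = led.M[: led.n, T - 1]
    r_last = rates.at(T - 1)
    if modifier is not None:
        counts_last = np.array([(cur == c).sum() for c in range(N_CLASSES)], dtype=np.int64)
        r_last = modifier(T - 1, counts_last, r_last)
        r_last.validate()
    realized.append(r_last)
    n_f = int((cur == F).sum())
    n_e = int((cur == E).sum())
    chicks = int(rng.poisson(r_last.pi_f, n_f).sum() + rng.poisson(r_last.pi_e, n_e).sum())
    led.add(chicks, T - 1, CHICK, ORIGIN_LOCAL, T - 1)

    rates_real = DemographicRates(
        T=T,
        **{name: np.array([getattr(s, name) for s in realized])
           for name in ("phi0", "phi2", "rho3", "rho4", "rho5", "rho6",
                        "psi_b", "psi_s", "pi_f", "pi_e")},
    )
    states = led.M[: led.n]
    counts = np.zeros((T, N_CLASSES), dtype=np.int64)
    for c in range(N_CLASSES):
        counts[:, c] = (states == c).sum(axis=0)
    return Trajectory(
        population=PopulationState(counts),
        states=states,
        origin=led.origin[: led.n].copy(),
        birth_year=led.birth[: led.n].copy(),
        immigrant_inflow=inflow,
        rates=rates_real,
    )
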