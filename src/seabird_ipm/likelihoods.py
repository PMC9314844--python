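"""The three likelihood components of the integrated model and their sum.

* counts: state-space log-normal observation density of the breeder count
  series given the latent number of breeders (exact density of C, including
  the 1/C change-of-variable term);
* capture-resighting histories: multistate capture-recapture model evaluated
  by the per-individual marginalized hidden-Markov forward recursion
  (identical likelihood to sampling the latent CR states, but deterministic
  and far better behaved numerically);
* reproduction: Poisson counts of fledglings per year and pair category with
  per-nest rates 2*pi_f (first-time pairs), 2*pi_e (experienced pairs) and
  the experience-weighted population rate for mixed/unknown pairs.

The joint log-likelihood adds the log-probability of the latent demographic
flows (the binomial/Poisson state process).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .model import (
    DemographicRates,
    ObservationModel,
    CODE_NOT_SEEN, CODE_PREBREEDER, CODE_BREEDER, CODE_SKIPPER,
)

logger = logging.getLogger(__name__)

# CR state indices (F and E merged into B; see _kernels)
CR_Y, CR_P2, CR_P3, CR_P4, CR_P5, CR_P6, CR_B, CR_S, CR_DEAD = range(9)


@dataclass
class CaptureHistory:
    """One individual's annual observation codes.

    ``codes`` has length T with entries in {0 not seen, 1 pre-breeder,
    2 breeder, 3 skipper}; ``ring_year`` is the year the bird was ringed as
    a chick (may be negative for birds marked before the study window, in
    which case the likelihood conditions on the first in-window sighting).
    """

    ring_year: int
    codes: np.ndarray
    id: int | str | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)


def validate_history(history: CaptureHistory, T: int) -> None:
    """Enforce the structural invariants of a capture history."""
    codes = history.codes
    if codes.shape != (T,):
        raise ValueError(f"history must cover all {T} years")
    if np.any((codes < 0) | (codes > 3)):
        raise ValueError("illegal observation code")
    seen = np.flatnonzero(codes)
    if seen.size == 0:
        return
    if seen[0] <= history.ring_year:
        raise ValueError("resighting at or before ringing")
    ages = seen - history.ring_year
    recruited = np.isin(codes[seen], (CODE_BREEDER, CODE_SKIPPER))
    if np.any(recruited & (ages < 3)):
        raise ValueError("breeder or skipper code before age 3")
    if np.any(recruited):
        first_rec = seen[recruited][0]
        later_pre = seen[(seen > first_rec) & (codes[seen] == CODE_PREBREEDER)]
        if later_pre.size:
            raise ValueError("pre-breeder code after recruitment")


@dataclass
class HistoryMatrix:
    """Pooled capture histories in kernel-ready form.

    Identical histories are pooled with multiplicity weights (the likelihood
    is unchanged, evaluation cost drops with the number of *unique*
    histories).
    """

    codes: np.ndarray        # (n_unique, T) int8
    first_year: np.ndarray   # (n_unique,) int64
    first_state: np.ndarray  # (n_unique,) int64; -1 = ringed as chick
    weights: np.ndarray      # (n_unique,) float64
    n_total: int = 0

    @property
    def T(self) -> int:
        return self.codes.shape[1]


def _initial_condition(ring_year: int, codes: np.ndarray) -> tuple[int, int]:
    """(first_year, first_state) for the forward recursion."""
    if ring_year >= 0:
        return ring_year, -1
    seen = np.flatnonzero(codes)
    if seen.size == 0:
        return 0, -9  # never available in the window: contributes nothing
    t = int(seen[0])
    age = t - ring_year
    code = codes[t]
    if code == CODE_BREEDER:
        state = CR_B
    elif code == CODE_SKIPPER:
        state = CR_S
    elif age == 1:
        state = CR_Y
    elif 2 <= age <= 6:
        state = CR_Y + age - 1
    else:
        return t, -9  # pre-breeder older than 6: impossible under the life cycle
    return t, state


def pool_histories(histories: list[CaptureHistory], T: int, validate: bool = True) -> HistoryMatrix:
    if not histories:
        return HistoryMatrix(
            codes=np.zeros((0, T), dtype=np.int8),
            first_year=np.zeros(0, dtype=np.int64),
            first_state=np.zeros(0, dtype=np.int64),
            weights=np.zeros(0),
            n_total=0,
        )
    if validate:
        for h in histories:
            validate_history(h, T)
    keys: dict[tuple, int] = {}
    rows, fy, fs, w = [], [], [], []
    for h in histories:
        t0, s0 = _initial_condition(h.ring_year, h.codes)
        key = (t0, s0, h.codes.tobytes())
        if key in keys:
            w[keys[key]] += 1.0
        else:
            keys[key] = len(rows)
            rows.append(h.codes)
            fy.append(t0)
            fs.append(s0)
            w.append(1.0)
    return HistoryMatrix(
        codes=np.array(rows, dtype=np.int8),
        first_year=np.array(fy, dtype=np.int64),
        first_state=np.array(fs, dtype=np.int64),
        weights=np.array(w),
        n_total=len(histories),
    )


def histories_from_frame(df: pd.DataFrame, T: int, validate: bool = True) -> HistoryMatrix:
    """Build the pooled matrix from the long-form (id, ring_year, year, code)
    table."""
    codes = {}
    ring = {}
    for row in df.itertuples(index=False):
        i = row.id
        if i not in codes:
            codes[i] = np.zeros(T, dtype=np.int8)
            ring[i] = int(row.ring_year)
        if int(row.code) != CODE_NOT_SEEN:
            codes[i][int(row.year)] = int(row.code)
    hs = [CaptureHistory(ring_year=ring[i], codes=codes[i], id=i) for i in codes]
    return pool_histories(hs, T, validate=validate)


def _rate_arrays(rates: DemographicRates):
    return (rates.phi0, rates.phi2, rates.rho_matrix(), rates.psi_b, rates.psi_s)


def forward_loglik(
    history: CaptureHistory,
    rates: DemographicRates,
    obs: ObservationModel,
) -> float:
    """Marginal log-probability of one observation sequence given ringing.

    Sums over all latent life-history paths with the scaled forward
    recursion.  A history that is impossible under the life cycle (e.g. a
    breeder code at age 2) yields ``-inf`` with a log diagnostic rather than
    an exception.
    """
    T = rates.T
    codes = history.codes
    if codes.shape != (T,):
        raise ValueError(f"history must cover all {T} years")
    t0, s0 = _initial_condition(history.ring_year, codes)
    if s0 == -9:
        if np.any(codes):
            logger.warning("history %s impossible: unavailable initial state", history.id)
            return -np.inf
        return 0.0
    phi0, phi2, rho, psib, psis = _rate_arrays(rates)
    ll = K.cr_forward_one(codes, t0, s0, T, phi0, phi2, rho, psib, psis,
                          obs.p_Y, obs.p_P, obs.p_R)
    if ll == -np.inf:
        logger.warning("history %s has zero probability under the life cycle", history.id)
    return float(ll)


def forward_loglik_pooled(
    hm: HistoryMatrix,
    rates: DemographicRates,
    obs: ObservationModel,
) -> float:
    if hm.codes.shape[0] == 0:
        return 0.0
    phi0, phi2, rho, psib, psis = _rate_arrays(rates)
    keep = hm.first_state != -9
    return float(K.cr_forward_all(
        hm.codes[keep], hm.first_year[keep], hm.first_state[keep], hm.weights[keep],
        phi0, phi2, rho, psib, psis, obs.p_Y, obs.p_P, obs.p_R,
    ))


def loglik_counts(C: np.ndarray, B: np.ndarray, sigma_obs: float) -> float:
    """Log-normal observation density of observed counts given latent
    breeder numbers, with the 1/C change-of-variable term."""
    C = np.asarray(C, dtype=float)
    B = np.asarray(B, dtype=float)
    if sigma_obs <= 0:
        raise ValueError("sigma_obs must be > 0")
    if np.any(C <= 0) or np.any(B <= 0):
        raise ValueError("counts and latent breeder numbers must be positive")
    z = (np.log(C) - np.log(B)) / sigma_obs
    return float(np.sum(-0.5 * z ** 2 - np.log(sigma_obs) - 0.5 * np.log(2 * np.pi) - np.log(C)))


def _reproduction_arrays(table: pd.DataFrame, T: int) -> tuple[np.ndarray, np.ndarray]:
    nests = np.zeros((T, 3), dtype=np.int64)
    fled = np.zeros((T, 3), dtype=np.int64)
    cat_idx = {"FF": 0, "EE": 1, "MIX": 2}
    for row in table.itertuples(index=False):
        if row.n_nests < 0:
            raise ValueError("negative nest count")
        j = cat_idx[row.category]
        nests[int(row.year), j] += int(row.n_nests)
        fled[int(row.year), j] += int(row.n_fledglings)
    return nests, fled


def loglik_reproduction(
    table: pd.DataFrame,
    pi_f: np.ndarray,
    pi_e: np.ndarray,
    N_F: np.ndarray,
    N_E: np.ndarray,
) -> float:
    """Poisson log-likelihood of the year x category reproduction table.

    Per-nest rates: 2*pi_f (FF), 2*pi_e (EE) and the experience-weighted
    population rate ``2 (N_F pi_f + N_E pi_e) / (N_F + N_E)`` (MIX).
    """
    N_F = np.asarray(N_F, dtype=float)
    N_E = np.asarray(N_E, dtype=float)
    T = N_F.size
    pi_f = np.broadcast_to(np.asarray(pi_f, dtype=float), (T,))
    pi_e = np.broadcast_to(np.asarray(pi_e, dtype=float), (T,))
    if table.empty:
        return 0.0
    nests, fled = _reproduction_arrays(table, T)
    N = np.zeros((T, 9), dtype=np.int64)
    N[:, 6] = np.rint(N_F).astype(np.int64)
    N[:, 7] = np.rint(N_E).astype(np.int64)
    return float(K.rep_logp_total(N, nests, fled,
                                  np.ascontiguousarray(pi_f), np.ascontiguousarray(pi_e)))


@dataclass
class LatentState:
    """Latent demographic flows over the study horizon.

    All class counts derive from these flows; ``counts()`` rebuilds the
    (T, 9) matrix.  ``I`` is the continuous immigrant parameter (may be
    negative under its prior); ``Ic`` its clamped, rounded realization that
    enters the integer states.
    """

    n0: np.ndarray            # (9,)
    ypois: np.ndarray         # (T-1,) yearlings entering at t+1
    p2b: np.ndarray           # (T-1,) yearling survivors entering P2
    rec: np.ndarray           # (T-1, 5) recruits from P2..P6
    stay: np.ndarray          # (T-1, 4) pre-breeders staying to P3..P6
    bE: np.ndarray            # (T-1, 3) breeders next year from F, E, S
    bS: np.ndarray            # (T-1, 3) skippers next year from F, E, S
    I: np.ndarray             # (T,) continuous immigrant numbers (I[0] unused)

    @property
    def T(self) -> int:
        return self.ypois.shape[0] + 1

    @property
    def Ic(self) -> np.ndarray:
        return np.rint(np.maximum(self.I, 0.0)).astype(np.int64)

    def counts(self) -> np.ndarray:
        return K.build_counts(self.n0, self.ypois, self.p2b, self.rec,
                              self.stay, self.bE, self.bS, self.Ic)

    @property
    def local_recruits(self) -> np.ndarray:
        """Local first-time breeders per year (immigrants excluded)."""
        out = np.zeros(self.T, dtype=np.int64)
        out[1:] = self.rec.sum(axis=1)
        out[0] = self.n0[6]  # year-0 first-time breeders counted as local
        return out

    def copy(self) -> "LatentState":
        return LatentState(*(np.copy(getattr(self, f)) for f in
                             ("n0", "ypois", "p2b", "rec", "stay", "bE", "bS", "I")))


def state_logprob(latent: LatentState, rates: DemographicRates) -> float:
    """Log-probability of the latent flows under the binomial/Poisson state
    process."""
    N = latent.counts()
    return float(K.state_logp_total(
        N, latent.ypois, latent.p2b, latent.rec, latent.stay, latent.bE, latent.bS,
        rates.phi0, rates.phi2, rates.rho_matrix(), rates.psi_b, rates.psi_s,
        rates.pi_f, rates.pi_e,
    ))


def joint_loglik(
    counts: pd.DataFrame | None,
    histories: HistoryMatrix | None,
    reproduction: pd.DataFrame | None,
    rates: DemographicRates,
    obs: ObservationModel,
    latent: LatentState,
) -> float:
    """Joint log-likelihood: exact sum of the three data components plus the
    state-process log-probability.  Any data stream may be None (omitted)."""
    N = latent.counts()
    total = state_logprob(latent, rates)
    if counts is not None and len(counts):
        B = N[np.asarray(counts["year"], dtype=int), 6] + N[np.asarray(counts["year"], dtype=int), 7]
        if np.any(B <= 0):
            return -np.inf
        total += loglik_counts(np.asarray(counts["count"], dtype=float), B, obs.sigma_obs)
    if histories is not None:
        total += forward_loglik_pooled(histories, rates, obs)
    if reproduction is not None and len(reproduction):
        total += loglik_reproduction(reproduction, rates.pi_f, rates.pi_e, N[:, 6], N[:, 7])
    return float(total)
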