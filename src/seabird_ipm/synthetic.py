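"""Synthetic study generator.

Emulates the four data streams the integrated analysis consumes:

1. annual breeder counts (twice the nest count, log-normal observation error),
2. capture-resighting histories of chicks ringed each year (status- and
   time-dependent resighting, no status misassignment),
3. annual reproduction tables for three pair categories (both-ringed
   first-time pairs, both-ringed experienced pairs, mixed/unknown),
4. per-year per-patch nest and fledgling counts whose spatial dispersion is
   negatively coupled to the population mean (bad years concentrate failure
   in many patches).

Defaults describe a colony of ~1,700 breeders followed for 28 years with
demographic rates at values typical of a long-lived cliff-nesting seabird:
adult survival ~0.81, first/second-year survival ~0.65, age-3..6 recruitment
0.13/0.41/0.53/0.67, breeding rates 0.90 (former breeders) and 0.69 (former
skippers), per-capita fledging 0.16 (first-time) and 0.36 (experienced), and
an immigrant pulse sized so that the population is stationary.  Rates vary
across years on the logit (probabilities) or log (fledging rates) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
import pandas as pd

from .model import (
    DemographicRates,
    ObservationModel,
    RateSlice,
    N_CLASSES,
    Y, P2, P3, P4, P5, P6, F, E, S,
    CODE_NOT_SEEN, CODE_PREBREEDER, CODE_BREEDER, CODE_SKIPPER,
)
from .projection import (
    Trajectory,
    expectation_matrix,
    simulate_trajectory,
    CHICK,
    ORIGIN_LOCAL,
)

_logit = lambda p: np.log(p / (1.0 - p))
_ilogit = lambda x: 1.0 / (1.0 + np.exp(-x))


def equilibrium_state(rates: RateSlice, immigration: float) -> np.ndarray:
    """Deterministic equilibrium of the expectation model with a constant
    immigrant pulse; requires the local dynamics to be subcritical."""
    A = expectation_matrix(rates)
    lam = np.max(np.abs(np.linalg.eigvals(A)))
    if lam >= 1.0:
        raise ValueError(f"local growth rate {lam:.3f} >= 1; no immigration-fed equilibrium")
    e = np.zeros(N_CLASSES)
    e[F] = max(immigration, 0.0)
    return np.linalg.solve(np.eye(N_CLASSES) - A, e)


def solve_immigration(rates: RateSlice, target_breeders: float) -> float:
    """Constant annual immigrant number that keeps ``F+E`` at the target."""
    unit = equilibrium_state(rates, 1.0)
    b_unit = unit[F] + unit[E]
    if b_unit <= 0:
        raise ValueError("degenerate life cycle: immigrants never breed")
    return target_breeders / b_unit


@dataclass
class SyntheticConfig:
    """Study conditions for :func:`generate_study`.

    Annual-variation SDs act on the logit scale for probabilities and the
    log scale for fledging rates.  ``dd_psi_*`` add density dependence of
    breeding rates on the standardized current number of breeders;
    ``quality_effect_psi_*`` make breeding rates respond to the previous
    year's population breeding success (both default to zero: no built-in
    behavioural couplings).
    """

    T: int = 28
    seed: int = 0
    # mean demographic rates
    phi0: float = 0.65
    phi2: float = 0.81
    rho3: float = 0.13
    rho4: float = 0.41
    rho5: float = 0.53
    rho6: float = 0.67
    psi_b: float = 0.90
    psi_s: float = 0.69
    pi_f: float = 0.16
    pi_e: float = 0.36
    # annual variation SDs (logit / log scale)
    sd_phi0: float = 0.20
    sd_phi2: float = 0.10
    sd_rho: float = 0.30
    sd_psi_b: float = 0.45
    sd_psi_s: float = 0.45
    sd_pi: float = 0.35
    # behavioural couplings (default off)
    dd_psi_b: float = 0.0
    dd_psi_s: float = 0.0
    quality_effect_psi_b: float = 0.0
    quality_effect_recruitment: float = 0.0
    # immigration
    target_breeders: float = 1700.0
    immigration_mean: float | None = None  # solved from target if None
    immigration_cv: float = 0.60
    # observation process (counts are a near-complete nest census, so the
    # log-scale error is small relative to the population's annual swings)
    sigma_obs: float = 0.03
    p_Y: float = 0.05
    p_P: float = 0.81
    p_R: float = 0.998
    sd_p_Y: float = 0.40
    sd_p_P: float = 0.30
    # marking and pairing
    n_ringed_per_year: int = 80
    ringed_fraction: float = 0.55
    assortment: float = 0.5
    # patch model
    n_patches: int = 30
    failure_link: float = 0.8
    failure_floor: float = 0.02
    patch_rate_sd: float = 0.25

    def __post_init__(self):
        if self.T < 3:
            raise ValueError("T must be >= 3")
        for name in ("phi0", "phi2", "rho3", "rho4", "rho5", "rho6", "psi_b",
                     "psi_s", "ringed_fraction", "assortment", "p_Y", "p_P", "p_R"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.sigma_obs <= 0:
            raise ValueError("sigma_obs must be > 0")

    def mean_rates(self, T: int | None = None) -> DemographicRates:
        T = T or self.T
        return DemographicRates.constant(
            T, phi0=self.phi0, phi2=self.phi2, rho3=self.rho3, rho4=self.rho4,
            rho5=self.rho5, rho6=self.rho6, psi_b=self.psi_b, psi_s=self.psi_s,
            pi_f=self.pi_f, pi_e=self.pi_e,
        )


@dataclass
class Study:
    """A synthetic study bundle: the four observable streams plus the truth
    record needed to verify any recovery claim analytically."""

    counts: pd.DataFrame
    histories: pd.DataFrame
    reproduction: pd.DataFrame
    patches: pd.DataFrame
    truth: dict
    config: SyntheticConfig


def _annual(rng: np.random.Generator, mean: float, sd: float, T: int, scale: str) -> np.ndarray:
    if sd == 0.0:
        return np.full(T, mean)
    z = rng.normal(0.0, sd, T)
    if scale == "logit":
        return _ilogit(_logit(mean) + z)
    return np.exp(np.log(mean) + z)


def _true_rates(cfg: SyntheticConfig, rng: np.random.Generator) -> DemographicRates:
    T = cfg.T
    return DemographicRates(
        T=T,
        phi0=_annual(rng, cfg.phi0, cfg.sd_phi0, T, "logit"),
        phi2=_annual(rng, cfg.phi2, cfg.sd_phi2, T, "logit"),
        rho3=_annual(rng, cfg.rho3, cfg.sd_rho, T, "logit"),
        rho4=_annual(rng, cfg.rho4, cfg.sd_rho, T, "logit"),
        rho5=_annual(rng, cfg.rho5, cfg.sd_rho, T, "logit"),
        rho6=_annual(rng, cfg.rho6, cfg.sd_rho, T, "logit"),
        psi_b=_annual(rng, cfg.psi_b, cfg.sd_psi_b, T, "logit"),
        psi_s=_annual(rng, cfg.psi_s, cfg.sd_psi_s, T, "logit"),
        pi_f=_annual(rng, cfg.pi_f, cfg.sd_pi, T, "log"),
        pi_e=_annual(rng, cfg.pi_e, cfg.sd_pi, T, "log"),
    )


def observe_counts(
    breeders: np.ndarray,
    sigma_obs: float,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Log-normal count observation: ``C[t] = exp(N(log B[t], sigma))``.

    Counts are breeder-equivalents, i.e. twice the number of nests.
    """
    breeders = np.asarray(breeders, dtype=float)
    if np.any(breeders <= 0):
        raise ValueError("latent breeder numbers must be positive to observe counts")
    if sigma_obs < 0:
        raise ValueError("sigma_obs must be >= 0")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    c = np.exp(np.log(breeders) + rng.normal(0.0, sigma_obs, breeders.size)) if sigma_obs > 0 else breeders.copy()
    return pd.DataFrame({"year": np.arange(breeders.size), "count": c})


_CLASS_TO_CODE = np.full(N_CLASSES, CODE_PREBREEDER, dtype=np.int8)
_CLASS_TO_CODE[F] = CODE_BREEDER
_CLASS_TO_CODE[E] = CODE_BREEDER
_CLASS_TO_CODE[S] = CODE_SKIPPER


def observe_histories(
    paths: np.ndarray,
    ring_year: np.ndarray,
    obs: ObservationModel,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Detection of ringed individuals: (n, T) matrix of observation codes.

    Every alive individual-year is detected with its class's resighting
    probability and, if detected, reports its true status.  Dead or absent
    individuals are never detected.  Paths must be contiguous: ringed as a
    chick, then census classes until death, never reappearing.
    """
    paths = np.asarray(paths)
    ring_year = np.asarray(ring_year)
    n, T = paths.shape
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    codes = np.zeros((n, T), dtype=np.int8)
    alive = (paths >= 0) & (paths < N_CLASSES)
    # validate: no gaps (alive years form one contiguous run after ringing)
    for i in range(n):
        yrs = np.flatnonzero(alive[i])
        if yrs.size:
            if yrs[0] != ring_year[i] + 1 or np.any(np.diff(yrs) != 1):
                raise ValueError(f"individual {i}: path has a gap or precedes ringing")
        bad = (paths[i] >= 0) & (paths[i] < N_CLASSES + 1) & ~alive[i] & (paths[i] != CHICK)
        if np.any(bad):
            raise ValueError(f"individual {i}: unknown class code")
    p_class = np.empty((N_CLASSES, T))
    p_class[Y] = obs.p_Y
    for c in (P2, P3, P4, P5, P6):
        p_class[c] = obs.p_P
    for c in (F, E, S):
        p_class[c] = obs.p_R
    u = rng.random((n, T))
    for c in range(N_CLASSES):
        mask = alive & (paths == c) & (u < p_class[c][None, :])
        codes[mask] = _CLASS_TO_CODE[c]
    return codes


def observe_reproduction(
    n_F: np.ndarray,
    n_E: np.ndarray,
    pi_f: np.ndarray,
    pi_e: np.ndarray,
    ringed_fraction: float,
    assortment: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Annual nest/fledgling table for the three pair categories.

    Nests (``(F+E)//2`` per year) are classified FF (both mates ringed
    first-time breeders), EE (both ringed experienced) or MIX (mixed or any
    unringed mate).  With probability ``assortment`` a pair is formed within
    an experience class; otherwise mates pair at random.  Fledgling totals
    are Poisson with per-nest rates ``2 pi_f``, ``2 pi_e`` and the
    experience-weighted population rate.
    """
    n_F = np.asarray(n_F, dtype=float)
    n_E = np.asarray(n_E, dtype=float)
    if np.any(n_F < 0) or np.any(n_E < 0):
        raise ValueError("breeder counts must be non-negative")
    T = n_F.size
    pi_f = np.broadcast_to(np.asarray(pi_f, dtype=float), (T,))
    pi_e = np.broadcast_to(np.asarray(pi_e, dtype=float), (T,))
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    r2 = ringed_fraction ** 2
    rows = []
    for t in range(T):
        b = n_F[t] + n_E[t]
        nests = int(b // 2)
        if nests == 0 or b == 0:
            for cat in ("FF", "EE", "MIX"):
                rows.append((t, cat, 0, 0))
            continue
        fshare = n_F[t] / b
        eshare = n_E[t] / b
        p_ff_pair = assortment * fshare + (1 - assortment) * fshare ** 2
        p_ee_pair = assortment * eshare + (1 - assortment) * eshare ** 2
        p = np.array([p_ff_pair * r2, p_ee_pair * r2, 0.0])
        p[2] = 1.0 - p[0] - p[1]
        n_ff, n_ee, n_mix = rng.multinomial(nests, p)
        wbar = 2.0 * (n_F[t] * pi_f[t] + n_E[t] * pi_e[t]) / b
        rows.append((t, "FF", int(n_ff), int(rng.poisson(2.0 * pi_f[t] * n_ff))))
        rows.append((t, "EE", int(n_ee), int(rng.poisson(2.0 * pi_e[t] * n_ee))))
        rows.append((t, "MIX", int(n_mix), int(rng.poisson(wbar * n_mix))))
    return pd.DataFrame(rows, columns=["year", "category", "n_nests", "n_fledglings"])


def generate_patch_table(
    T: int,
    n_patches: int,
    quality: np.ndarray,
    failure_link: float,
    rng: np.random.Generator | int | None = None,
    nests_per_year: np.ndarray | int = 1000,
    failure_floor: float = 0.02,
    patch_rate_sd: float = 0.25,
    failed_rate: float = 0.02,
) -> pd.DataFrame:
    """Per patch-year nests and fledglings with quality-linked failure.

    A patch-year fails (near-zero per-nest success) with probability
    ``clip(failure_floor + failure_link * (1 - quality[t]), 0, 0.95)``;
    otherwise its per-nest rate is centred on ``0.3 + 0.9 * quality[t]``
    with log-normal among-patch spread ``patch_rate_sd``.  Low-quality years
    therefore combine a low population mean with a highly unequal
    (high-Gini) distribution of success across patches.
    """
    if n_patches < 2:
        raise ValueError("need at least 2 patches")
    quality = np.asarray(quality, dtype=float)
    if quality.shape != (T,):
        raise ValueError("quality series must have length T")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    nests_per_year = np.broadcast_to(np.asarray(nests_per_year), (T,))
    sizes = rng.dirichlet(np.full(n_patches, 5.0))  # stable patch size profile
    rows = []
    for t in range(T):
        n_t = rng.multinomial(int(nests_per_year[t]), sizes)
        f_prob = float(np.clip(failure_floor + failure_link * (1.0 - quality[t]), 0.0, 0.95))
        failed = rng.random(n_patches) < f_prob
        base = 0.3 + 0.9 * quality[t]
        rate = base * np.exp(rng.normal(0.0, patch_rate_sd, n_patches))
        rate[failed] = failed_rate
        fled = rng.poisson(n_t * rate)
        for j in range(n_patches):
            rows.append((t, j, int(n_t[j]), int(fled[j])))
    return pd.DataFrame(rows, columns=["year", "patch", "n_nests", "n_fledglings"])


def flows_from_trajectory(traj: Trajectory):
    """Exact latent demographic flows of a simulated trajectory.

    Counts every individual transition in the truth record and returns the
    :class:`~seabird_ipm.likelihoods.LatentState` that the inference module
    parameterizes, so likelihoods and derived quantities can be evaluated at
    the exact simulated truth.
    """
    from .likelihoods import LatentState

    M = traj.states
    T = traj.population.T
    counts = traj.population.counts
    Tm1 = T - 1
    rec = np.zeros((Tm1, 5), dtype=np.int64)
    stay = np.zeros((Tm1, 4), dtype=np.int64)
    bE = np.zeros((Tm1, 3), dtype=np.int64)
    bS = np.zeros((Tm1, 3), dtype=np.int64)
    for t in range(Tm1):
        cur = M[:, t]
        nxt = M[:, t + 1]
        for i, src in enumerate((P2, P3, P4, P5, P6)):
            rec[t, i] = int(((cur == src) & (nxt == F)).sum())
            if i < 4:
                stay[t, i] = int(((cur == src) & (nxt == src + 1)).sum())
        for j, src in enumerate((F, E, S)):
            bE[t, j] = int(((cur == src) & (nxt == E)).sum())
            bS[t, j] = int(((cur == src) & (nxt == S)).sum())
    return LatentState(
        n0=counts[0].astype(np.int64).copy(),
        ypois=counts[1:, Y].astype(np.int64).copy(),
        p2b=counts[1:, P2].astype(np.int64).copy(),
        rec=rec, stay=stay, bE=bE, bS=bS,
        I=traj.immigrant_inflow.astype(float).copy(),
    )


def generate_study(config: SyntheticConfig) -> Study:
    """Generate all four data streams plus the full latent truth record.

    Deterministic under ``config.seed``: the same configuration always
    yields identical tables.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    rng_rates, rng_traj, rng_counts, rng_hist, rng_rep, rng_patch, rng_obs = (
        np.random.default_rng(s) for s in root.spawn(7)
    )

    rates = _true_rates(cfg, rng_rates)
    mean_slice = cfg.mean_rates().at(0)
    imm_mean = cfg.immigration_mean
    if imm_mean is None:
        imm_mean = solve_immigration(mean_slice, cfg.target_breeders)
    I_series = np.maximum(
        rng_rates.normal(imm_mean, cfg.immigration_cv * max(imm_mean, 1.0), cfg.T), 0.0
    )
    I_series[0] = 0.0  # year-0 immigrants are part of the initial state
    init = np.rint(equilibrium_state(mean_slice, imm_mean)).astype(np.int64)

    # behavioural couplings, applied year by year on the linear scale
    b_scale = 0.15 * cfg.target_breeders
    success_lag = {"value": None}

    def modifier(t: int, counts_t: np.ndarray, r: RateSlice) -> RateSlice:
        changes = {}
        b = counts_t[F] + counts_t[E]
        zb = (b - cfg.target_breeders) / b_scale
        if cfg.dd_psi_b != 0.0:
            changes["psi_b"] = float(_ilogit(_logit(r.psi_b) + cfg.dd_psi_b * zb))
        if cfg.dd_psi_s != 0.0:
            changes["psi_s"] = float(_ilogit(_logit(r.psi_s) + cfg.dd_psi_s * zb))
        q = success_lag["value"]
        if q is not None:
            zq = (q - (cfg.pi_f + cfg.pi_e)) / 0.2  # rough standardization of per-nest success
            if cfg.quality_effect_psi_b != 0.0:
                base = changes.get("psi_b", r.psi_b)
                changes["psi_b"] = float(_ilogit(_logit(base) + cfg.quality_effect_psi_b * zq))
            if cfg.quality_effect_recruitment != 0.0:
                for name in ("rho3", "rho4", "rho5", "rho6"):
                    changes[name] = float(
                        _ilogit(_logit(getattr(r, name)) + cfg.quality_effect_recruitment * zq)
                    )
        if b > 0:
            success_lag["value"] = 2.0 * (counts_t[F] * r.pi_f + counts_t[E] * r.pi_e) / b
        if not changes:
            return r
        from dataclasses import replace
        return replace(r, **changes)

    needs_modifier = any(
        v != 0.0 for v in (cfg.dd_psi_b, cfg.dd_psi_s,
                           cfg.quality_effect_psi_b, cfg.quality_effect_recruitment)
    )
    traj = simulate_trajectory(
        rates, I_series, init, cfg.T, rng_traj,
        modifier=modifier if needs_modifier else None,
    )
    rates_real = traj.rates if traj.rates is not None else rates

    B = traj.population.breeders
    nests_total = B // 2
    counts = observe_counts(np.maximum(2 * nests_total, 1), cfg.sigma_obs, rng_counts)

    obs = ObservationModel(
        T=cfg.T,
        sigma_obs=cfg.sigma_obs,
        p_Y=_annual(rng_obs, cfg.p_Y, cfg.sd_p_Y, cfg.T, "logit"),
        p_P=_annual(rng_obs, cfg.p_P, cfg.sd_p_P, cfg.T, "logit"),
        p_R=cfg.p_R,
    )

    # ring a sample of each year's chicks
    ringed_idx = []
    for t in range(cfg.T):
        cohort = np.flatnonzero(
            (traj.birth_year == t) & (traj.origin == ORIGIN_LOCAL) & (traj.states[:, t] == CHICK)
        )
        k = min(cfg.n_ringed_per_year, cohort.size)
        if k > 0:
            ringed_idx.append(rng_hist.choice(cohort, size=k, replace=False))
    ringed_idx = np.concatenate(ringed_idx) if ringed_idx else np.empty(0, dtype=np.int64)
    ring_year = traj.birth_year[ringed_idx]
    if ringed_idx.size:
        codes = observe_histories(traj.states[ringed_idx], ring_year, obs, rng_hist)
    else:
        codes = np.zeros((0, cfg.T), dtype=np.int8)
    hist_rows = []
    for i in range(ringed_idx.size):
        seen = np.flatnonzero(codes[i])
        if seen.size == 0:
            hist_rows.append((i, int(ring_year[i]), int(ring_year[i]), CODE_NOT_SEEN))
        for t in seen:
            hist_rows.append((i, int(ring_year[i]), int(t), int(codes[i, t])))
    histories = pd.DataFrame(hist_rows, columns=["id", "ring_year", "year", "code"])

    reproduction = observe_reproduction(
        traj.population.counts[:, F], traj.population.counts[:, E],
        rates_real.pi_f, rates_real.pi_e,
        cfg.ringed_fraction, cfg.assortment, rng_rep,
    )

    succ = 2.0 * (
        traj.population.counts[:, F] * rates_real.pi_f
        + traj.population.counts[:, E] * rates_real.pi_e
    ) / np.maximum(B, 1)
    lo, hi = succ.min(), succ.max()
    quality = (succ - lo) / (hi - lo) if hi > lo else np.full(cfg.T, 0.5)
    patches = generate_patch_table(
        cfg.T, cfg.n_patches, quality, cfg.failure_link, rng_patch,
        nests_per_year=np.maximum(nests_total, 2 * cfg.n_patches),
        failure_floor=cfg.failure_floor, patch_rate_sd=cfg.patch_rate_sd,
    )

    truth = {
        "seed": cfg.seed,
        "rates": {k: getattr(rates_real, k).tolist()
                  for k in ("phi0", "phi2", "rho3", "rho4", "rho5", "rho6",
                            "psi_b", "psi_s", "pi_f", "pi_e")},
        "I_series": I_series.tolist(),
        "immigrant_inflow": traj.immigrant_inflow.tolist(),
        "immigration_mean": float(imm_mean),
        "counts_latent": traj.population.counts.tolist(),
        "breeders": B.tolist(),
        "obs": {"sigma_obs": cfg.sigma_obs, "p_Y": obs.p_Y.tolist(),
                "p_P": obs.p_P.tolist(), "p_R": cfg.p_R},
        "population_success": succ.tolist(),
        "quality": quality.tolist(),
        "trajectory": traj,
        "observation_model": obs,
        "ringed_index": ringed_idx.tolist(),
        "config": asdict(cfg),
    }
    return Study(
        counts=counts,
        histories=histories,
        reproduction=reproduction,
        patches=patches,
        truth=truth,
        config=cfg,
    )
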