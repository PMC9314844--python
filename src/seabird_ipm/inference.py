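"""Bayesian estimation of the integrated population model.

The sampler is an adaptive Metropolis-within-Gibbs:

* demographic and observation parameters are updated in blocks on
  unconstrained scales (logit for probabilities, log for positive rates)
  with Haario-style adaptive random-walk proposals;
* time-varying rates (optional) are updated as random year-subsets with
  per-year adapted step sizes;
* the latent population states are parameterized by the demographic flows
  of each annual transition and updated by single-site integer random walks
  inside a compiled sweep (the capture-recapture likelihood is marginalized
  over individual paths, so it never depends on the latent states);
* immigrant numbers are continuous with a Uniform(-5, 1000) prior -- the
  negative tail makes "no immigration at all" a testable hypothesis -- and
  only their clamped, rounded value enters the integer states.

Vague priors with reasonable bounds: Uniform(0, 1) for probabilities,
Uniform(0, upper) for the fledging rates and the count-error SD, discrete
uniform for initial class sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels as K
from .draws import PosteriorDraws
from .likelihoods import HistoryMatrix, LatentState
from .model import DemographicRates, ObservationModel

logger = logging.getLogger(__name__)

_RATE_NAMES = ("phi0", "phi2", "rho3", "rho4", "rho5", "rho6", "psi_b", "psi_s")
_PI_NAMES = ("pi_f", "pi_e")
_DET_NAMES = ("p_Y", "p_P", "p_R")
_PROB_NAMES = _RATE_NAMES + _DET_NAMES
_ALL_NAMES = _RATE_NAMES + _PI_NAMES + _DET_NAMES + ("sigma_obs",)

# starting values informed by the biology of long-lived colonial seabirds
_INIT_VALUES = {
    "phi0": 0.6, "phi2": 0.8, "rho3": 0.15, "rho4": 0.4, "rho5": 0.5,
    "rho6": 0.65, "psi_b": 0.85, "psi_s": 0.65, "pi_f": 0.18, "pi_e": 0.33,
    "p_Y": 0.1, "p_P": 0.7, "p_R": 0.95, "sigma_obs": 0.05,
}


@dataclass
class PriorSpec:
    """Prior families and bounds (all vague uniforms)."""

    immigrant_low: float = -5.0
    immigrant_high: float = 1000.0
    pi_upper: float = 2.0
    sigma_upper: float = 1.0
    n0_upper: np.ndarray | int = 20000

    def __post_init__(self):
        if self.immigrant_low >= 0:
            raise ValueError("immigrant prior must extend below zero")
        if not np.isfinite(self.immigrant_high):
            raise ValueError("immigrant prior must be bounded")
        self.n0_upper = np.broadcast_to(np.asarray(self.n0_upper, dtype=np.int64), (9,)).copy()


@dataclass
class MCMCConfig:
    n_chains: int = 3
    n_iterations: int = 3000
    n_burnin: int = 1000
    thin: int = 2
    rng_seed: int = 0
    latent_sweeps_per_iter: int = 2
    max_init_attempts: int = 20

    def __post_init__(self):
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be smaller than n_iterations")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")


@dataclass
class ModelConfig:
    """Which rates get a year-specific (time-varying) parameterization."""

    time_varying: tuple[str, ...] = ()

    def __post_init__(self):
        bad = set(self.time_varying) - set(_RATE_NAMES + _PI_NAMES + ("p_Y", "p_P"))
        if bad:
            raise ValueError(f"cannot make {sorted(bad)} time-varying")


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _ilogit(z):
    return 1.0 / (1.0 + np.exp(-z))


class _Posterior:
    """Mutable sampler state for one chain: parameter arrays on both scales,
    latent flows, and cached log-likelihood pieces."""

    def __init__(self, bundle, prior: PriorSpec, model: ModelConfig,
                 params: dict[str, np.ndarray], latent: LatentState):
        self.T = latent.T
        self.prior = prior
        self.model = model
        self.hm: HistoryMatrix | None = bundle.histories if bundle.histories is not None and bundle.histories.codes.shape[0] else None
        self.has_counts = bundle.counts is not None and len(bundle.counts) > 0
        if self.has_counts:
            years = np.asarray(bundle.counts["year"], dtype=int)
            if not np.array_equal(np.sort(years), np.arange(self.T)):
                raise ValueError("count series must cover every study year exactly once")
            c = np.asarray(bundle.counts.sort_values("year")["count"], dtype=float)
            if np.any(c <= 0):
                raise ValueError("counts must be positive")
            self.logC = np.log(c)
        else:
            self.logC = np.zeros(self.T)
        self.has_rep = bundle.reproduction is not None and len(bundle.reproduction) > 0
        if self.has_rep:
            from .likelihoods import _reproduction_arrays
            self.nests, self.fled = _reproduction_arrays(bundle.reproduction, self.T)
        else:
            self.nests = np.zeros((self.T, 3), dtype=np.int64)
            self.fled = np.zeros((self.T, 3), dtype=np.int64)

        # full-length (T,) arrays for every parameter; scalars broadcast
        self.arr: dict[str, np.ndarray] = {}
        self.is_tv: dict[str, bool] = {}
        for name in _ALL_NAMES:
            v = params[name]
            tv = name in model.time_varying
            self.is_tv[name] = tv
            self.arr[name] = (np.full(self.T, float(np.asarray(v).ravel()[0]))
                              if not tv else np.asarray(v, dtype=float).copy())
        self.latent = latent
        self.N = latent.counts()
        self.Ic = latent.Ic
        self.ll: dict[str, float] = {}
        self.refresh_all()

    # --- likelihood pieces ------------------------------------------------
    def _rho(self):
        return np.ascontiguousarray(np.stack([self.arr["rho3"], self.arr["rho4"],
                                              self.arr["rho5"], self.arr["rho6"]]))

    def piece_cr(self) -> float:
        if self.hm is None:
            return 0.0
        keep = self.hm.first_state != -9
        return float(K.cr_forward_all(
            self.hm.codes[keep], self.hm.first_year[keep], self.hm.first_state[keep],
            self.hm.weights[keep],
            self.arr["phi0"], self.arr["phi2"], self._rho(),
            self.arr["psi_b"], self.arr["psi_s"],
            self.arr["p_Y"], self.arr["p_P"], float(self.arr["p_R"][0]),
        ))

    def piece_state(self) -> float:
        la = self.latent
        return float(K.state_logp_total(
            self.N, la.ypois, la.p2b, la.rec, la.stay, la.bE, la.bS,
            self.arr["phi0"], self.arr["phi2"], self._rho(),
            self.arr["psi_b"], self.arr["psi_s"], self.arr["pi_f"], self.arr["pi_e"],
        ))

    def piece_counts(self) -> float:
        if not self.has_counts:
            return 0.0
        return float(K.counts_logp_total(self.N, self.logC, float(self.arr["sigma_obs"][0])))

    def piece_rep(self) -> float:
        if not self.has_rep:
            return 0.0
        return float(K.rep_logp_total(self.N, self.nests, self.fled,
                                      self.arr["pi_f"], self.arr["pi_e"]))

    def refresh_all(self):
        self.ll = {"cr": self.piece_cr(), "st": self.piece_state(),
                   "cn": self.piece_counts(), "rp": self.piece_rep()}

    def joint(self) -> float:
        return sum(self.ll.values())

    # --- transformed-scale prior (bounds + Jacobians) ---------------------
    def log_prior_jac(self, name: str, values: np.ndarray) -> float:
        v = np.asarray(values, dtype=float)
        if name in _PROB_NAMES:
            if np.any(v <= 0) or np.any(v >= 1):
                return -np.inf
            return float(np.sum(np.log(v) + np.log1p(-v)))
        upper = self.prior.pi_upper if name in _PI_NAMES else self.prior.sigma_upper
        if np.any(v <= 0) or np.any(v >= upper):
            return -np.inf
        return float(np.sum(np.log(v)))


PIECES_BY_PARAM = {
    **{n: ("cr", "st") for n in _RATE_NAMES},
    **{n: ("st", "rp") for n in _PI_NAMES},
    "p_Y": ("cr",), "p_P": ("cr",), "p_R": ("cr",),
    "sigma_obs": ("cn",),
}


def _shift_trajectory(post: _Posterior, old: dict[str, np.ndarray],
                      new: dict[str, np.ndarray], rng: np.random.Generator) -> float:
    """Shift every latent flow by the change in its conditional expectation
    when the demographic rates move from ``old`` to ``new``.

    Processing years in ascending order, each flow from source class ``c``
    shifts by ``rint(p_new * N_new[t, c] - p_old * N_old[t, c])``, where
    ``N_old`` is the pre-move count trajectory (kept frozen) and ``N_new``
    the one being built; both rate changes and propagated source-count
    changes are tracked, so the flows' stochastic residuals are carried over
    essentially unchanged.  Applying the same map with old/new swapped
    exactly inverts it (the shift arguments negate, and integer rounding is
    antisymmetric), so a symmetric random walk on the rates yields a valid
    reversible joint proposal that takes marginal-scale steps instead of
    being pinned by the rates' tight full conditionals given the flows.

    ``old``/``new`` map rate names to per-year arrays (length T).
    """
    la = post.latent

    def rho_mat(d):
        return np.ascontiguousarray(np.stack([d["rho3"], d["rho4"], d["rho5"], d["rho6"]]))

    return float(K.shift_trajectory(
        la.ypois, la.p2b, la.rec, la.stay, la.bE, la.bS, post.N,
        la.I, post.Ic, post.prior.immigrant_low, post.prior.immigrant_high,
        2.0, rng.random(post.T - 1),
        old["phi0"], old["phi2"], rho_mat(old), old["psi_b"], old["psi_s"],
        old["pi_f"], old["pi_e"],
        new["phi0"], new["phi2"], rho_mat(new), new["psi_b"], new["psi_s"],
        np.asarray(new["pi_f"], dtype=float), np.asarray(new["pi_e"], dtype=float),
    ))


class _AdaptiveBlock:
    """Haario-style adaptive random-walk block on the transformed scale,
    optionally with matched latent-flow shifts (see _apply_flow_shifts)."""

    def __init__(self, names, post: _Posterior, rng: np.random.Generator,
                 couple: str | None = None, extra_pieces: tuple = (),
                 repeats: int = 1, period: int = 1, phase: int = 0):
        self.names = list(names)
        self.post = post
        self.rng = rng
        self.couple = couple
        self.repeats = repeats
        self.period = period   # update every `period`-th iteration
        self.phase = phase
        self.dim = len(self.names)
        self.target = 0.44 if self.dim == 1 else 0.25
        self.log_scale = np.log(0.1 / np.sqrt(self.dim))
        self.mean = np.zeros(self.dim)
        self.cov = np.eye(self.dim)
        self.n_seen = 0
        self.pieces = sorted({p for n in self.names for p in PIECES_BY_PARAM[n]}
                             | set(extra_pieces))

    def _get_z(self):
        z = np.empty(self.dim)
        for i, n in enumerate(self.names):
            v = float(self.post.arr[n][0])
            if n in _PROB_NAMES:
                z[i] = _logit(v)
            else:
                z[i] = np.log(v)
        return z

    def _snapshot(self):
        la = self.post.latent
        return (la.ypois.copy(), la.p2b.copy(), la.rec.copy(), la.stay.copy(),
                la.bE.copy(), la.bS.copy(), self.post.N.copy(),
                la.I.copy(), self.post.Ic.copy())

    def _restore(self, snap):
        la = self.post.latent
        la.ypois[:], la.p2b[:] = snap[0], snap[1]
        la.rec[:], la.stay[:] = snap[2], snap[3]
        la.bE[:], la.bS[:] = snap[4], snap[5]
        self.post.N[:] = snap[6]
        la.I[:], self.post.Ic[:] = snap[7], snap[8]

    def step(self, adapt: bool, it: int):
        if (it + self.phase) % self.period:
            return 0.0
        acc = 0.0
        for _ in range(self.repeats):
            acc += self._step_once(adapt, it)
        return acc / self.repeats

    def _step_once(self, adapt: bool, it: int):
        post = self.post
        z0 = self._get_z()
        lp0 = sum(post.log_prior_jac(n, post.arr[n][:1]) for n in self.names)
        ll0 = sum(post.ll[p] for p in self.pieces)
        scale = np.exp(self.log_scale)
        if self.n_seen > 5 * self.dim:
            try:
                step = self.rng.multivariate_normal(np.zeros(self.dim),
                                                    self.cov + 1e-8 * np.eye(self.dim))
            except np.linalg.LinAlgError:
                step = self.rng.standard_normal(self.dim)
        else:
            step = self.rng.standard_normal(self.dim)
        z1 = z0 + scale * step

        couple_names = _RATE_NAMES + _PI_NAMES
        old_vals = {n: post.arr[n].copy() for n in couple_names}
        old_param = {}
        for i, n in enumerate(self.names):
            old_param[n] = post.arr[n].copy()
            post.arr[n][:] = _ilogit(z1[i]) if n in _PROB_NAMES else np.exp(z1[i])
        new_vals = {n: post.arr[n] for n in couple_names}

        snap = None
        logq = 0.0
        if self.couple is not None:
            snap = self._snapshot()
            logq = _shift_trajectory(post, old_vals, new_vals, self.rng)

        lp1 = sum(post.log_prior_jac(n, post.arr[n][:1]) for n in self.names)
        accepted = False
        if np.isfinite(lp1):
            new_pieces = {p: getattr(post, {"cr": "piece_cr", "st": "piece_state",
                                            "cn": "piece_counts", "rp": "piece_rep"}[p])()
                          for p in self.pieces}
            ll1 = sum(new_pieces.values())
            if np.isfinite(ll1) and np.log(self.rng.random()) < (ll1 + lp1) - (ll0 + lp0) + logq:
                accepted = True
                post.ll.update(new_pieces)
        if not accepted:
            for n, v in old_param.items():
                post.arr[n][:] = v
            if snap is not None:
                self._restore(snap)
        if adapt:
            gamma = 1.0 / np.sqrt(it + 1.0)
            self.log_scale += gamma * ((1.0 if accepted else 0.0) - self.target)
            zc = self._get_z()
            self.n_seen += 1
            w = 1.0 / self.n_seen
            delta = zc - self.mean
            self.mean += w * delta
            self.cov = (1 - w) * self.cov + w * np.outer(delta, zc - self.mean)
        return accepted


class _TimeVaryingBlock:
    """Random year-subset updates of one time-varying parameter.

    Breeding rates (psi_b, psi_s) get the matched breeder/skipper exchange
    per proposed year, mirroring the coupled scalar move.
    """

    def __init__(self, name: str, post: _Posterior, rng: np.random.Generator,
                 subset: int | None = None):
        self.name = name
        self.post = post
        self.rng = rng
        T = post.T
        self.subset = subset or max(2, T // 4)
        self.log_scale = np.full(T, np.log(0.4))
        self.couple = name in (_RATE_NAMES + _PI_NAMES)
        self.pieces = sorted(set(PIECES_BY_PARAM[name])
                             | ({"st", "cn", "rp"} if self.couple else set()))

    def step(self, adapt: bool, it: int):
        post = self.post
        name = self.name
        T = post.T
        idx = self.rng.choice(T, size=min(self.subset, T), replace=False)
        arr = post.arr[name]
        old = arr.copy()
        is_prob = name in _PROB_NAMES
        z = _logit(arr[idx]) if is_prob else np.log(arr[idx])
        lp0 = post.log_prior_jac(name, arr[idx])
        ll0 = sum(post.ll[p] for p in self.pieces)
        z1 = z + np.exp(self.log_scale[idx]) * self.rng.standard_normal(idx.size)
        new_vals = _ilogit(z1) if is_prob else np.exp(z1)
        snap = None
        logq = 0.0
        couple_names = _RATE_NAMES + _PI_NAMES
        if self.couple:
            la = post.latent
            snap = (la.ypois.copy(), la.p2b.copy(), la.rec.copy(), la.stay.copy(),
                    la.bE.copy(), la.bS.copy(), post.N.copy(),
                    la.I.copy(), post.Ic.copy())
            old_vals = {n: post.arr[n].copy() for n in couple_names}
        arr[idx] = new_vals
        if self.couple:
            logq = _shift_trajectory(post, old_vals,
                                     {n: post.arr[n] for n in couple_names}, self.rng)
        lp1 = post.log_prior_jac(name, arr[idx])
        accepted = False
        if np.isfinite(lp1):
            new_pieces = {p: getattr(post, {"cr": "piece_cr", "st": "piece_state",
                                            "cn": "piece_counts", "rp": "piece_rep"}[p])()
                          for p in self.pieces}
            ll1 = sum(new_pieces.values())
            if np.isfinite(ll1) and np.log(self.rng.random()) < (ll1 + lp1) - (ll0 + lp0) + logq:
                accepted = True
                post.ll.update(new_pieces)
        if not accepted:
            arr[:] = old
            if snap is not None:
                la = post.latent
                la.ypois[:], la.p2b[:] = snap[0], snap[1]
                la.rec[:], la.stay[:] = snap[2], snap[3]
                la.bE[:], la.bS[:] = snap[4], snap[5]
                post.N[:] = snap[6]
                la.I[:], post.Ic[:] = snap[7], snap[8]
        if adapt:
            gamma = 1.0 / np.sqrt(it + 1.0)
            self.log_scale[idx] += gamma * ((1.0 if accepted else 0.0) - 0.25)
        return accepted


class _GibbsSigma:
    """Exact Gibbs draw of the count-error SD from its truncated
    inverse-gamma full conditional (flat prior on sigma over (0, upper))."""

    def __init__(self, post: _Posterior, rng: np.random.Generator):
        self.post = post
        self.rng = rng

    def step(self, adapt: bool, it: int):
        from scipy.special import gammainc, gammaincinv
        post = self.post
        if it < 600:
            # hold the count-error SD at its (small) starting value until the
            # latent trajectory and annual rates have adapted to the counts;
            # releasing it early lets an exact conditional draw inflate sigma
            # to match transient mismatch and strand the chain in a diffuse
            # count-decoupled mode
            return 0.0
        B = post.N[:, 6] + post.N[:, 7]
        if np.any(B <= 0):
            return 0.0
        resid = post.logC - np.log(B)
        S = float(np.sum(resid ** 2))
        n = resid.size
        # p(sigma | .) ~ sigma^-n exp(-S / (2 sigma^2)) on (0, upper);
        # sigma^2 is inverse-gamma(a, S/2), i.e. (S/2)/sigma^2 ~ Gamma(a, 1)
        a = (n - 1) / 2.0
        g_lo = float(gammainc(a, (S / 2.0) / post.prior.sigma_upper ** 2))
        u = self.rng.uniform(g_lo, 1.0)
        var = (S / 2.0) / float(gammaincinv(a, max(u, 1e-300)))
        post.arr["sigma_obs"][:] = np.sqrt(var)
        post.ll["cn"] = post.piece_counts()
        return 1.0


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

def _target_breeders(bundle, T: int) -> np.ndarray:
    if bundle.counts is not None and len(bundle.counts):
        c = bundle.counts.sort_values("year")["count"].to_numpy(float)
        return np.maximum(c, 10.0)
    return np.full(T, 300.0)


def initialize_state(bundle, prior: PriorSpec, model: ModelConfig,
                     seed: int | np.random.Generator = 0,
                     max_attempts: int = 20):
    """Deterministic-under-seed starting point with a finite joint density.

    Latent breeder totals are built to track the observed counts: flows are
    rounded expectations under jittered field-informed starting rates and
    the immigrant pulse absorbs the residual each year.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    T = bundle.T
    btar = _target_breeders(bundle, T)

    # moment estimates of the breeding rates from observed status transitions
    # (recruited birds are resighted almost surely, so these are nearly
    # unbiased); they anchor the latent skipper pool at a consistent level
    init_values = dict(_INIT_VALUES)
    hm = bundle.histories
    if hm is not None and hm.codes.shape[0]:
        codes = hm.codes
        w = hm.weights[:, None]
        for name, code in (("psi_b", 2), ("psi_s", 3)):
            src = codes[:, :-1] == code
            stay = src & (codes[:, 1:] == 2)
            either = src & ((codes[:, 1:] == 2) | (codes[:, 1:] == 3))
            n_e = float((either * w).sum())
            if n_e >= 20:
                est = float((stay * w).sum()) / n_e
                init_values[name] = float(np.clip(est, 0.05, 0.98))

    last_error = "no attempt"
    for attempt in range(max_attempts):
        params: dict[str, np.ndarray] = {}
        for name in _ALL_NAMES:
            base = init_values[name]
            if name in _PROB_NAMES:
                v = _ilogit(_logit(base) + rng.normal(0, 0.15))
            else:
                v = float(np.exp(np.log(base) + rng.normal(0, 0.15)))
                upper = prior.pi_upper if name in _PI_NAMES else prior.sigma_upper
                v = min(v, 0.9 * upper)
            size = T if name in model.time_varying else 1
            params[name] = np.full(size, v)

        g = {n: float(params[n][0]) for n in _ALL_NAMES}
        # initial composition: immigration-fed equilibrium of the starting
        # rates, scaled to the first count; crude fallback if supercritical
        try:
            from .synthetic import equilibrium_state, solve_immigration
            from .model import RateSlice
            rs = RateSlice(**{k: g[k] for k in _RATE_NAMES + _PI_NAMES})
            eq = equilibrium_state(rs, solve_immigration(rs, btar[0]))
            comp = eq / btar[0]
        except ValueError:
            comp = np.array([0.45, 0.30, 0.22, 0.14, 0.07, 0.03, 0.15, 0.85, 0.12])
        n0 = np.minimum(np.rint(comp * btar[0]).astype(np.int64), prior.n0_upper)
        n0 = np.maximum(n0, 1)

        Tm1 = T - 1
        la = LatentState(
            n0=n0,
            ypois=np.zeros(Tm1, dtype=np.int64),
            p2b=np.zeros(Tm1, dtype=np.int64),
            rec=np.zeros((Tm1, 5), dtype=np.int64),
            stay=np.zeros((Tm1, 4), dtype=np.int64),
            bE=np.zeros((Tm1, 3), dtype=np.int64),
            bS=np.zeros((Tm1, 3), dtype=np.int64),
            I=np.zeros(T),
        )
        N = np.zeros((T, 9), dtype=np.int64)
        N[0] = n0
        rho = [g["rho3"], g["rho4"], g["rho5"], g["rho6"], 1.0]
        for t in range(Tm1):
            la.ypois[t] = int(round(g["phi0"] * (N[t, 6] * g["pi_f"] + N[t, 7] * g["pi_e"])))
            la.p2b[t] = int(N[t, 0] * g["phi0"])
            for i in range(5):
                la.rec[t, i] = int(N[t, 1 + i] * g["phi2"] * rho[i])
                if i < 4:
                    la.stay[t, i] = int(N[t, 1 + i] * g["phi2"] * (1.0 - rho[i]))
            for j in range(3):
                psi = g["psi_b"] if j < 2 else g["psi_s"]
                la.bE[t, j] = int(N[t, 6 + j] * g["phi2"] * psi)
                la.bS[t, j] = int(N[t, 6 + j] * g["phi2"] * (1.0 - psi))
            flocal = int(la.rec[t].sum())
            e_next = int(la.bE[t].sum())
            gap = btar[t + 1] - (flocal + e_next)
            if gap < -0.5:
                # crash year: immigrants cannot be negative, so shift the
                # excess expected breeders to skippers instead
                deficit = int(min(-gap, e_next - 1))
                for j in range(3):
                    take = min(deficit, int(la.bE[t, j]))
                    la.bE[t, j] -= take
                    la.bS[t, j] += take
                    deficit -= take
                    if deficit <= 0:
                        break
                e_next = int(la.bE[t].sum())
                gap = btar[t + 1] - (flocal + e_next)
            la.I[t + 1] = float(np.clip(gap, 0.0, prior.immigrant_high - 1.0))
            N[t + 1, 0] = la.ypois[t]
            N[t + 1, 1] = la.p2b[t]
            N[t + 1, 2:6] = la.stay[t]
            N[t + 1, 6] = flocal + la.Ic[t + 1]
            N[t + 1, 7] = e_next
            N[t + 1, 8] = int(la.bS[t].sum())

        post = _Posterior(bundle, prior, model, params, la)
        j = post.joint()
        if np.isfinite(j):
            return params, la
        last_error = f"joint log-density {j} at attempt {attempt}"
        logger.debug("initialize_state retry: %s", last_error)
    raise RuntimeError(f"could not find a finite starting point: {last_error}")


# ---------------------------------------------------------------------------
# main driver
# ---------------------------------------------------------------------------

def run_mcmc(bundle, prior: PriorSpec | None = None,
             config: MCMCConfig | None = None,
             model: ModelConfig | None = None) -> PosteriorDraws:
    """Sample the joint posterior of parameters, latent states and immigrant
    numbers.  Chains are deterministic under ``config.rng_seed``."""
    prior = prior or PriorSpec()
    config = config or MCMCConfig()
    model = model or ModelConfig()
    T = bundle.T
    n_kept = (config.n_iterations - config.n_burnin) // config.thin
    if n_kept < 1:
        raise ValueError("no draws would be kept; check iterations/burnin/thin")

    root = np.random.SeedSequence(config.rng_seed)
    chain_seeds = root.spawn(config.n_chains)

    params_store: dict[str, np.ndarray] = {}
    latent_store: dict[str, np.ndarray] = {}
    accept_stats = []

    for c in range(config.n_chains):
        ss = chain_seeds[c]
        rng = np.random.default_rng(ss)
        K.seed_numba(int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31 - 1)))

        params, latent = initialize_state(bundle, prior, model, rng,
                                          max_attempts=config.max_init_attempts)
        post = _Posterior(bundle, prior, model, params, latent)

        blocks = []
        # demographic rates move with the matched whole-trajectory flow shift
        # (marginal-scale steps; see _shift_trajectory), in three blocks of
        # strongly related parameters
        for group, period, phase in ((("phi2", "psi_b", "psi_s"), 1, 0),
                                     (("rho3", "rho4", "rho5", "rho6"), 1, 0),
                                     (("phi0", "pi_f", "pi_e"), 1, 0),
                                     # solo refreshers for the slowest
                                     # directions, on alternating iterations
                                     (("phi2",), 1, 0),
                                     (("psi_b",), 2, 0), (("psi_s",), 2, 1)):
            names = [n for n in group if not post.is_tv[n]]
            if names:
                blocks.append(_AdaptiveBlock(names, post, rng, couple="trajectory",
                                             extra_pieces=("st", "cn", "rp"),
                                             period=period, phase=phase))
        det_scalar = [n for n in _DET_NAMES if not post.is_tv[n]]
        if det_scalar and post.hm is not None:
            blocks.append(_AdaptiveBlock(det_scalar, post, rng, period=2))
        if post.has_counts:
            blocks.append(_GibbsSigma(post, rng))
        for name in model.time_varying:
            blocks.append(_TimeVaryingBlock(name, post, rng))

        la = post.latent
        n0_scale = np.maximum(np.sqrt(la.n0.astype(float) + 1.0) / 2.0, 1.0)
        flow_mag = np.column_stack([
            la.ypois, la.p2b, la.rec, la.stay, la.bE, la.bS,
            np.zeros((T - 1, 2), dtype=np.int64),
        ]).astype(float)
        flow_scale = np.maximum(np.sqrt(flow_mag + 1.0) / 2.0, 1.5)
        i_scale = np.maximum(np.sqrt(np.abs(la.I[1:]) + 1.0), 10.0)
        n_acc_latent = 0
        n_acc_blocks = np.zeros(len(blocks))

        if c == 0:
            keep_idx = 0
            for name in _ALL_NAMES:
                size = (config.n_chains, n_kept, T) if post.is_tv[name] else (config.n_chains, n_kept)
                params_store[name] = np.zeros(size)
            latent_store = {
                "N": np.zeros((config.n_chains, n_kept, T, 9)),
                "Flocal": np.zeros((config.n_chains, n_kept, T)),
                "I": np.zeros((config.n_chains, n_kept, T)),
                "Ic": np.zeros((config.n_chains, n_kept, T)),
                "bE_FE": np.zeros((config.n_chains, n_kept, T - 1)),
                "bS_FE": np.zeros((config.n_chains, n_kept, T - 1)),
                "bE_S": np.zeros((config.n_chains, n_kept, T - 1)),
                "bS_S": np.zeros((config.n_chains, n_kept, T - 1)),
                "adult_survivors": np.zeros((config.n_chains, n_kept, T - 1)),
            }

        keep = 0
        for it in range(config.n_iterations):
            adapt = it < config.n_burnin
            for _ in range(config.latent_sweeps_per_iter):
                n_acc_latent += K.latent_sweep(
                    la.n0, la.ypois, la.p2b, la.rec, la.stay, la.bE, la.bS,
                    la.I, post.Ic, post.N,
                    post.arr["phi0"], post.arr["phi2"], post._rho(),
                    post.arr["psi_b"], post.arr["psi_s"],
                    post.arr["pi_f"], post.arr["pi_e"],
                    post.logC, float(post.arr["sigma_obs"][0]),
                    post.nests, post.fled, post.has_counts, post.has_rep,
                    n0_scale, flow_scale, i_scale,
                    prior.immigrant_low, prior.immigrant_high, prior.n0_upper,
                    adapt, it,
                )
            # latent-dependent pieces changed
            post.ll["st"] = post.piece_state()
            post.ll["cn"] = post.piece_counts()
            post.ll["rp"] = post.piece_rep()

            for b_i, block in enumerate(blocks):
                n_acc_blocks[b_i] += block.step(adapt, it)

            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0 and keep < n_kept:
                for name in _ALL_NAMES:
                    if post.is_tv[name]:
                        params_store[name][c, keep] = post.arr[name]
                    else:
                        params_store[name][c, keep] = float(post.arr[name][0])
                latent_store["N"][c, keep] = post.N
                flocal = np.zeros(T)
                flocal[0] = la.n0[6]
                flocal[1:] = la.rec.sum(axis=1)
                latent_store["Flocal"][c, keep] = flocal
                latent_store["I"][c, keep] = la.I
                latent_store["Ic"][c, keep] = post.Ic
                latent_store["bE_FE"][c, keep] = la.bE[:, 0] + la.bE[:, 1]
                latent_store["bS_FE"][c, keep] = la.bS[:, 0] + la.bS[:, 1]
                latent_store["bE_S"][c, keep] = la.bE[:, 2]
                latent_store["bS_S"][c, keep] = la.bS[:, 2]
                latent_store["adult_survivors"][c, keep] = (
                    la.rec.sum(axis=1) + la.stay.sum(axis=1)
                    + la.bE.sum(axis=1) + la.bS.sum(axis=1)
                )
                keep += 1

        accept_stats.append({
            "latent_accept_per_sweep": n_acc_latent / max(config.n_iterations, 1),
            "block_accept": (n_acc_blocks / config.n_iterations).tolist(),
        })

    return PosteriorDraws(
        params=params_store, latent=latent_store, T=T,
        meta={"seed": config.rng_seed, "n_chains": config.n_chains,
              "n_iterations": config.n_iterations, "n_burnin": config.n_burnin,
              "thin": config.thin, "time_varying": list(model.time_varying),
              "accept": accept_stats},
    )


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def convergence_report(draws: PosteriorDraws) -> pd.DataFrame:
    """Classic potential scale reduction factor (floored at 1, infinite when
    chains do not overlap) and rank-normalized effective sample size per
    scalar parameter."""
    import arviz as az

    if draws.n_chains < 2:
        raise ValueError("convergence diagnostics require at least 2 chains")
    rows = []
    for name, a in draws.params.items():
        if a.ndim != 2:
            continue
        m, n = a.shape
        means = a.mean(axis=1)
        vars_ = a.var(axis=1, ddof=1)
        W = float(vars_.mean())
        B_over_n = float(np.var(means, ddof=1))
        if W == 0.0:
            psrf = 1.0 if B_over_n == 0.0 else np.inf
        else:
            vhat = (n - 1) / n * W + B_over_n
            psrf = float(np.sqrt(max(1.0, vhat / W)))
        ess = float(az.ess(np.asarray(a)))
        if not np.isfinite(ess):
            ess = 0.0
        rows.append((name, psrf, ess))
    return pd.DataFrame(rows, columns=["parameter", "psrf", "ess"])


def posterior_predictive_check(
    draws: PosteriorDraws,
    bundle,
    seed: int = 0,
    max_draws: int = 200,
) -> dict[str, float]:
    """Bayesian p-values for the count and reproduction streams.

    Discrepancy: sum of squared Pearson residuals (log-scale standardized
    residuals for the log-normal counts).  For each posterior draw a
    replicate dataset is simulated and the p-value is the fraction of draws
    whose replicated discrepancy exceeds the observed one.
    """
    if draws.n_total == 0:
        raise ValueError("no posterior draws")
    rng = np.random.default_rng(seed)
    idx = rng.choice(draws.n_total, size=min(max_draws, draws.n_total), replace=False)
    out: dict[str, float] = {}

    if bundle.counts is not None and len(bundle.counts):
        c = bundle.counts.sort_values("year")["count"].to_numpy(float)
        logC = np.log(c)
        B = draws.breeders[idx]
        sigma = draws.flat_param("sigma_obs")[idx]
        z_obs = (logC[None, :] - np.log(B)) / sigma[:, None]
        d_obs = np.sum(z_obs ** 2, axis=1)
        z_rep = rng.standard_normal(z_obs.shape)
        d_rep = np.sum(z_rep ** 2, axis=1)
        out["counts"] = float(np.mean(d_rep > d_obs))

    if bundle.reproduction is not None and len(bundle.reproduction):
        from .likelihoods import _reproduction_arrays
        nests, fled = _reproduction_arrays(bundle.reproduction, draws.T)
        N = draws.flat_latent("N")[idx]
        pif = draws.param_series("pi_f")[idx]
        pie = draws.param_series("pi_e")[idx]
        B = N[:, :, 6] + N[:, :, 7]
        wbar = 2.0 * (N[:, :, 6] * pif + N[:, :, 7] * pie) / np.maximum(B, 1)
        lam = np.stack([2.0 * pif * nests[:, 0], 2.0 * pie * nests[:, 1],
                        wbar * nests[:, 2]], axis=-1)  # (draws, T, 3)
        mask = lam > 0
        obs = np.broadcast_to(fled[None], lam.shape)
        d_obs = np.where(mask, (obs - lam) ** 2 / np.where(mask, lam, 1.0), 0.0).sum(axis=(1, 2))
        rep = rng.poisson(np.where(mask, lam, 0.0))
        d_rep = np.where(mask, (rep - lam) ** 2 / np.where(mask, lam, 1.0), 0.0).sum(axis=(1, 2))
        out["reproduction"] = float(np.mean(d_rep > d_obs))
    if not out:
        raise ValueError("bundle has no stream suitable for posterior predictive checks")
    return out
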