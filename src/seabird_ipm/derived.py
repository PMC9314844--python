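"""Derived demographic quantities and posterior partial correlations.

Every derived series is computed per posterior draw and only then
summarized; evidence for an association is the sign-support statistic P,
the fraction of the posterior sample of a partial correlation sharing the
sign of its posterior mean (P near 1: strong evidence; near 0.5: none).

Two headline analyses:

* the growth-rate table -- partial correlations of the breeding population
  growth rate with adult survival, breeding rates of former breeders and
  former skippers, the integrative recruitment rate and the immigration
  rate, each controlling for the others;
* the propensity table -- status-specific breeding propensity at ``t``
  against population breeding success, number of breeders, and number of
  present non-breeders at ``t-1``, each controlling for the other two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .draws import PosteriorDraws

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-draw series
# ---------------------------------------------------------------------------

def growth_rate(B: np.ndarray) -> np.ndarray:
    """lambda[t] = B[t] / B[t-1] along the last axis (length T-1 output)."""
    B = np.asarray(B, dtype=float)
    if np.any(B[..., :-1] == 0):
        raise ValueError("zero breeder count: growth rate undefined")
    return B[..., 1:] / B[..., :-1]


def integrative_recruitment(local_recruits: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Age-pooled breeding propensity of pre-breeders.

    Local first-time breeders at ``t`` divided by all locals alive and
    available for recruitment at ``t`` (the recruits plus the surviving
    never-bred pre-breeders of ages 3-6).  Immigrants are excluded.  Year 0
    (no modelled recruitment event) and zero-denominator years are NaN.
    """
    local_recruits = np.asarray(local_recruits, dtype=float)
    N = np.asarray(N, dtype=float)
    avail = local_recruits + N[..., 2:6].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(avail > 0, local_recruits / np.where(avail > 0, avail, 1.0), np.nan)
    out[..., 0] = np.nan
    return out


def immigration_rate(I: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proportion of immigrants among breeders, using the *unclamped*
    continuous immigrant number (may be negative)."""
    I = np.asarray(I, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(B == 0):
        raise ValueError("zero breeders: immigration rate undefined")
    return I / B


def present_nonbreeders(N: np.ndarray, p_P: np.ndarray, p_R: float | np.ndarray) -> np.ndarray:
    """Non-breeders present at the colonies: pre-breeders of ages 2-6
    discounted by their resighting probability plus skippers discounted by
    the recruited resighting probability."""
    N = np.asarray(N, dtype=float)
    return N[..., 1:6].sum(axis=-1) * np.asarray(p_P) + N[..., 8] * np.asarray(p_R)


def breeder_composition(B: np.ndarray, former_breeders: np.ndarray,
                        former_skippers: np.ndarray, local_first: np.ndarray,
                        immigrants: np.ndarray) -> np.ndarray:
    """Among-breeder proportions (..., T, 4): former breeders, former
    skippers, local first-time breeders, immigrants.  Year 0 is NaN (origins
    unobserved).  Proportions sum to 1 exactly for every later year."""
    B = np.asarray(B, dtype=float)
    if np.any(B == 0):
        raise ValueError("zero breeders: composition undefined")
    comp = np.stack([
        np.asarray(former_breeders, dtype=float),
        np.asarray(former_skippers, dtype=float),
        np.asarray(local_first, dtype=float),
        np.asarray(immigrants, dtype=float),
    ], axis=-1) / B[..., None]
    comp[..., 0, :] = np.nan
    return comp


# ---------------------------------------------------------------------------
# partial correlations
# ---------------------------------------------------------------------------

def partial_correlation(y: np.ndarray, x: np.ndarray,
                        controls: np.ndarray | list | None = None) -> float:
    """Correlation of y and x after removing linear dependence on controls.

    Computed by correlating the residuals of the regressions of y and x on
    ``[1, controls]``; with no controls this is the plain product-moment
    correlation.  Returns NaN when a residual has (numerically) zero
    variance; raises on collinear controls.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = y.size
    if x.size != n:
        raise ValueError("series must be aligned")
    if controls is None or len(controls) == 0:
        Z = np.ones((n, 1))
    else:
        C = np.column_stack([np.asarray(c, dtype=float) for c in np.atleast_2d(np.asarray(controls, dtype=float))])
        if C.shape[0] != n:
            raise ValueError("controls must be aligned with y and x")
        Z = np.column_stack([np.ones(n), C])
    if n < Z.shape[1] + 2:
        raise ValueError("series too short for the number of controls")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("collinear controls")
    coef_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    coef_x, *_ = np.linalg.lstsq(Z, x, rcond=None)
    ry = y - Z @ coef_y
    rx = x - Z @ coef_x
    sy = float(np.sqrt(np.sum(ry ** 2)))
    sx = float(np.sqrt(np.sum(rx ** 2)))
    scale = max(float(np.sqrt(np.sum(y ** 2))), 1.0)
    if sy <= 1e-12 * scale or sx <= 1e-12 * max(float(np.sqrt(np.sum(x ** 2))), 1.0):
        return float("nan")
    return float(np.clip(np.dot(ry, rx) / (sy * sx), -1.0, 1.0))


def sign_support(samples: np.ndarray) -> float:
    """P: fraction of samples sharing the sign of the sample mean.

    Zero-valued samples match neither sign; a sample mean of exactly zero
    gives P = 0.5 by convention.
    """
    s = np.asarray(samples, dtype=float)
    s = s[~np.isnan(s)]
    if s.size == 0:
        raise ValueError("no samples")
    m = s.mean()
    if m == 0.0:
        return 0.5
    return float(np.mean(np.sign(s) == np.sign(m)))


@dataclass
class PartialCorrelationResult:
    mean: float
    ci_low: float
    ci_high: float
    P: float
    samples: np.ndarray
    response: str = ""
    predictor: str = ""
    controls: tuple = ()
    lag: int = 1
    n_dropped: int = 0

    def __repr__(self):
        return (f"PartialCorrelationResult({self.response} ~ {self.predictor} | "
                f"{','.join(self.controls)}: mean={self.mean:.3f} "
                f"[{self.ci_low:.3f}, {self.ci_high:.3f}], P={self.P:.3f})")


def posterior_partial_correlation(
    response: np.ndarray,
    predictor: np.ndarray,
    controls: list[np.ndarray] | None = None,
    lag: int = 1,
    start_year: int = 1,
    names: tuple[str, str, tuple] = ("response", "predictor", ()),
) -> PartialCorrelationResult:
    """Posterior distribution of a lagged partial correlation.

    ``response``, ``predictor`` and each control are (n_draws, T) per-draw
    series; the response at year ``t`` is aligned with predictor and
    controls at ``t - lag`` over the window from ``start_year`` on (the
    first year is excluded: latent numbers are poorly identified there).
    Draws whose aligned series contain NaN are dropped (count reported).
    """
    response = np.atleast_2d(np.asarray(response, dtype=float))
    predictor = np.atleast_2d(np.asarray(predictor, dtype=float))
    controls = [np.atleast_2d(np.asarray(c, dtype=float)) for c in (controls or [])]
    n, T = response.shape
    t_idx = np.arange(max(start_year + lag, lag), T)
    if t_idx.size < len(controls) + 3:
        raise ValueError("window too short for the number of controls")
    vals = np.full(n, np.nan)
    for d in range(n):
        y = response[d, t_idx]
        x = predictor[d, t_idx - lag]
        cs = [c[d, t_idx - lag] for c in controls]
        if np.any(np.isnan(y)) or np.any(np.isnan(x)) or any(np.any(np.isnan(c)) for c in cs):
            continue
        vals[d] = partial_correlation(y, x, cs)
    ok = ~np.isnan(vals)
    n_dropped = int(n - ok.sum())
    if n_dropped:
        logger.info("posterior_partial_correlation: dropped %d/%d draws", n_dropped, n)
    if not np.any(ok):
        raise ValueError("no draw yielded a defined partial correlation")
    good = vals[ok]
    lo, hi = np.percentile(good, [2.5, 97.5])
    return PartialCorrelationResult(
        mean=float(good.mean()), ci_low=float(lo), ci_high=float(hi),
        P=sign_support(good), samples=good,
        response=names[0], predictor=names[1], controls=tuple(names[2]), lag=lag,
        n_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# per-draw series extracted from PosteriorDraws
# ---------------------------------------------------------------------------

def _propensity_series(draws: PosteriorDraws, which: str) -> np.ndarray:
    """Breeding propensity *at year t* for former breeders/skippers.

    Uses the fitted annual rate when the parameter was time-varying;
    otherwise the realized annual proportion among surviving individuals of
    that status (which fluctuates even under a constant rate).  The rate
    governing the interval (t-1, t] is the propensity at t; year 0 is NaN.
    """
    T = draws.T
    name = "psi_b" if which == "breeder" else "psi_s"
    out = np.full((draws.n_total, T), np.nan)
    if draws.params[name].ndim == 3:  # time-varying fit
        series = draws.flat_param(name)
        out[:, 1:] = series[:, : T - 1]
        return out
    e = draws.flat_latent("bE_FE" if which == "breeder" else "bE_S")
    s = draws.flat_latent("bS_FE" if which == "breeder" else "bS_S")
    tot = e + s
    with np.errstate(invalid="ignore", divide="ignore"):
        out[:, 1:] = np.where(tot > 0, e / np.where(tot > 0, tot, 1.0), np.nan)
    return out


def derived_series(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """All per-draw annual series used by the headline analyses.

    Keys: lambda (index t = B[t]/B[t-1], NaN at 0), propensity_breeder,
    propensity_skipper, integrative_recruitment, immigration_rate,
    survival, breeders, present_nonbreeders, population_success,
    composition (n, T, 4).
    """
    N = draws.flat_latent("N")
    B = draws.breeders
    T = draws.T
    n = draws.n_total
    lam = np.full((n, T), np.nan)
    lam[:, 1:] = growth_rate(B)

    ir = integrative_recruitment(draws.flat_latent("Flocal"), N)
    imm = immigration_rate(draws.flat_latent("I"), B)
    imm[:, 0] = np.nan

    surv = np.full((n, T), np.nan)
    if draws.params["phi2"].ndim == 3:
        surv[:, 1:] = draws.flat_param("phi2")[:, : T - 1]
    else:
        adults = N[:, :-1, 1:9].sum(axis=-1)  # age-2+ sources of transition t-1
        survivors = draws.flat_latent("adult_survivors")
        with np.errstate(invalid="ignore", divide="ignore"):
            surv[:, 1:] = np.where(adults > 0, survivors / np.where(adults > 0, adults, 1.0), np.nan)

    pif = draws.param_series("pi_f")
    pie = draws.param_series("pi_e")
    with np.errstate(invalid="ignore", divide="ignore"):
        success = 2.0 * (N[:, :, 6] * pif + N[:, :, 7] * pie) / np.where(B > 0, B, 1.0)
    success[B == 0] = np.nan

    p_P = draws.param_series("p_P")
    p_R = draws.param_series("p_R")
    present = present_nonbreeders(N, p_P, p_R)

    comp = breeder_composition(
        B,
        np.concatenate([np.full((n, 1), np.nan), draws.flat_latent("bE_FE")], axis=1),
        np.concatenate([np.full((n, 1), np.nan), draws.flat_latent("bE_S")], axis=1),
        draws.flat_latent("Flocal"),
        draws.flat_latent("Ic"),
    )

    return {
        "lambda": lam,
        "propensity_breeder": _propensity_series(draws, "breeder"),
        "propensity_skipper": _propensity_series(draws, "skipper"),
        "integrative_recruitment": ir,
        "immigration_rate": imm,
        "survival": surv,
        "breeders": B.astype(float),
        "present_nonbreeders": present,
        "population_success": success,
        "composition": comp,
    }


GROWTH_ROWS = ("survival", "propensity_breeder", "propensity_skipper",
               "integrative_recruitment", "immigration_rate")
PROPENSITY_ROWS = ("propensity_breeder", "propensity_skipper",
                   "integrative_recruitment", "immigration_rate")
FEATURE_COLS = ("population_success", "breeders", "present_nonbreeders")


def analysis_tables(draws: PosteriorDraws,
                    observed_counts: np.ndarray | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The two headline tables as tidy DataFrames.

    1. growth table (5 rows): partial correlation of the breeding population
       growth rate at ``t`` with each demographic rate governing (t-1, t]
       (survival, the two breeding rates) or realized at ``t`` (integrative
       recruitment, immigration rate), controlling for the other four.
    2. propensity table (4 rows x 3 features): status-specific breeding
       propensity at ``t`` vs each population feature at ``t-1``,
       controlling for the other two features.

    ``observed_counts`` (length T, in breeder equivalents): when given, the
    "number of breeders" covariate of the propensity table is the counted
    value rather than the latent one.  Within a posterior draw the latent
    abundance and rate series co-fluctuate (they are jointly estimated from
    the same streams), which leaks spurious correlation into per-draw
    partials; the counted series is constant across draws and measures the
    same quantity up to census error, so it is preferred when available.
    """
    s = derived_series(draws)
    if observed_counts is not None:
        c = np.asarray(observed_counts, dtype=float)
        if c.shape != (draws.T,):
            raise ValueError(f"observed_counts must have length {draws.T}")
        s["breeders"] = np.tile(c, (draws.n_total, 1))

    # growth table: all five rates enter at lag 0 because each series is
    # already expressed "at year t" (governing the interval ending at t)
    rows = []
    for name in GROWTH_ROWS:
        controls = [s[c] for c in GROWTH_ROWS if c != name]
        res = posterior_partial_correlation(
            s["lambda"], s[name], controls, lag=0, start_year=1,
            names=("lambda", name, tuple(c for c in GROWTH_ROWS if c != name)),
        )
        rows.append((name, res.mean, res.ci_low, res.ci_high, res.P, res.n_dropped))
    growth = pd.DataFrame(rows, columns=["rate", "mean", "ci_low", "ci_high", "P", "n_dropped"])

    rows = []
    for rname in PROPENSITY_ROWS:
        for cname in FEATURE_COLS:
            controls = [s[c] for c in FEATURE_COLS if c != cname]
            res = posterior_partial_correlation(
                s[rname], s[cname], controls, lag=1, start_year=1,
                names=(rname, cname, tuple(c for c in FEATURE_COLS if c != cname)),
            )
            rows.append((rname, cname, res.mean, res.ci_low, res.ci_high, res.P, res.n_dropped))
    propensity = pd.DataFrame(
        rows, columns=["propensity", "feature", "mean", "ci_low", "ci_high", "P", "n_dropped"]
    )
    return growth, propensity
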