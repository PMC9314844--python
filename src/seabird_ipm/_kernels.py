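"""Numba kernels: CR forward recursion, state-process pmf, latent MH sweep.

The capture-recapture hidden-Markov state space merges first-time and
experienced breeders into one class "B" (they share survival, breeding rate
and resighting probability, so the marginal likelihood is unchanged):

    0 Y, 1 P2, 2 P3, 3 P4, 4 P5, 5 P6, 6 B, 7 S, 8 dead

The latent population process is parameterized by the demographic flows of
each annual transition (Poisson yearling inflow, binomial yearling survival,
one (recruit, stay, die) multinomial per pre-breeder class and one
(breed, skip, die) multinomial per breeder/skipper class); all class counts
are deterministic sums of flows plus the clamped immigrant pulse.
"""

import math

import numpy as np
from numba import njit

NEG_INF = -np.inf


@njit(cache=True)
def _lgamma1(x):
    return math.lgamma(x + 1.0)


@njit(cache=True)
def poisson_logpmf(k, lam):
    if k < 0:
        return NEG_INF
    if lam <= 0.0:
        return 0.0 if k == 0 else NEG_INF
    return k * math.log(lam) - lam - _lgamma1(k)


@njit(cache=True)
def binom_logpmf(k, n, p):
    if k < 0 or k > n or n < 0:
        return NEG_INF
    if p <= 0.0:
        return 0.0 if k == 0 else NEG_INF
    if p >= 1.0:
        return 0.0 if k == n else NEG_INF
    return (_lgamma1(n) - _lgamma1(k) - _lgamma1(n - k)
            + k * math.log(p) + (n - k) * math.log(1.0 - p))


@njit(cache=True)
def trinom_logpmf(n, k1, k2, p1, p2):
    """Multinomial over (k1, k2, n-k1-k2) with probabilities (p1, p2, rest)."""
    k3 = n - k1 - k2
    if k1 < 0 or k2 < 0 or k3 < 0 or n < 0:
        return NEG_INF
    p3 = 1.0 - p1 - p2
    out = _lgamma1(n) - _lgamma1(k1) - _lgamma1(k2) - _lgamma1(k3)
    for k, p in ((k1, p1), (k2, p2), (k3, p3)):
        if p <= 0.0:
            if k > 0:
                return NEG_INF
        else:
            out += k * math.log(p)
    return out


# ---------------------------------------------------------------------------
# capture-recapture forward recursion
# ---------------------------------------------------------------------------

@njit(cache=True)
def cr_forward_one(codes, t0, state0, T, phi0, phi2, rho, psib, psis, pY, pP, pR):
    """Log-likelihood of one history.

    ``state0 < 0`` means ringed as a chick in year ``t0`` (the first modelled
    occasion is ``t0+1``); ``state0 >= 0`` conditions on being in that CR
    state at ``t0`` (left-conditioning for birds marked before the window).
    """
    alpha = np.zeros(9)
    if state0 < 0:
        if t0 + 1 > T - 1:
            return 0.0
        alpha[0] = phi0[t0]
        alpha[8] = 1.0 - phi0[t0]
        t = t0 + 1
        emit_first = True
    else:
        alpha[state0] = 1.0
        t = t0
        emit_first = False

    loglik = 0.0
    while True:
        if emit_first:
            c = codes[t]
            s = 0.0
            if c == 0:
                alpha[0] *= 1.0 - pY[t]
                for j in range(1, 6):
                    alpha[j] *= 1.0 - pP[t]
                alpha[6] *= 1.0 - pR
                alpha[7] *= 1.0 - pR
                # dead: emission prob 1
            elif c == 1:
                alpha[0] *= pY[t]
                for j in range(1, 6):
                    alpha[j] *= pP[t]
                for j in range(6, 9):
                    alpha[j] = 0.0
            elif c == 2:
                b = alpha[6] * pR
                for j in range(9):
                    alpha[j] = 0.0
                alpha[6] = b
            else:  # skipper
                sk = alpha[7] * pR
                for j in range(9):
                    alpha[j] = 0.0
                alpha[7] = sk
            for j in range(9):
                s += alpha[j]
            if s <= 0.0:
                return NEG_INF
            loglik += math.log(s)
            for j in range(9):
                alpha[j] /= s
        emit_first = True
        if t >= T - 1:
            break
        # transition t -> t+1
        na = np.zeros(9)
        f0 = phi0[t]
        f2 = phi2[t]
        na[1] = alpha[0] * f0
        na[2] = alpha[1] * f2 * (1.0 - rho[0, t])
        na[3] = alpha[2] * f2 * (1.0 - rho[1, t])
        na[4] = alpha[3] * f2 * (1.0 - rho[2, t])
        na[5] = alpha[4] * f2 * (1.0 - rho[3, t])
        na[6] = f2 * (rho[0, t] * alpha[1] + rho[1, t] * alpha[2]
                      + rho[2, t] * alpha[3] + rho[3, t] * alpha[4] + alpha[5]
                      + psib[t] * alpha[6] + psis[t] * alpha[7])
        na[7] = f2 * ((1.0 - psib[t]) * alpha[6] + (1.0 - psis[t]) * alpha[7])
        na[8] = alpha[8] + (1.0 - f0) * alpha[0]
        for j in range(1, 8):
            na[8] += (1.0 - f2) * alpha[j]
        alpha = na
        t += 1
    return loglik


@njit(cache=True)
def cr_forward_all(codes, first_year, first_state, weights,
                   phi0, phi2, rho, psib, psis, pY, pP, pR):
    T = codes.shape[1]
    total = 0.0
    for i in range(codes.shape[0]):
        ll = cr_forward_one(codes[i], first_year[i], first_state[i], T,
                            phi0, phi2, rho, psib, psis, pY, pP, pR)
        if ll == NEG_INF:
            return NEG_INF
        total += weights[i] * ll
    return total


# ---------------------------------------------------------------------------
# state process
# ---------------------------------------------------------------------------

@njit(cache=True)
def build_counts(n0, ypois, p2b, rec, stay, bE, bS, Ic):
    """Derive the (T, 9) class-count matrix from flows and the clamped
    immigrant inflow."""
    Tm1 = ypois.shape[0]
    T = Tm1 + 1
    N = np.zeros((T, 9), dtype=np.int64)
    N[0] = n0
    for t in range(Tm1):
        N[t + 1, 0] = ypois[t]
        N[t + 1, 1] = p2b[t]
        for i in range(4):
            N[t + 1, 2 + i] = stay[t, i]
        rsum = 0
        for i in range(5):
            rsum += rec[t, i]
        N[t + 1, 6] = rsum + Ic[t + 1]
        N[t + 1, 7] = bE[t, 0] + bE[t, 1] + bE[t, 2]
        N[t + 1, 8] = bS[t, 0] + bS[t, 1] + bS[t, 2]
    return N


@njit(cache=True)
def trans_logp(t, N, ypois, p2b, rec, stay, bE, bS,
               phi0, phi2, rho, psib, psis, pif, pie):
    """log p(flows of transition t | N[t], rates[t])."""
    lp = 0.0
    lam = phi0[t] * (N[t, 6] * pif[t] + N[t, 7] * pie[t])
    lp += poisson_logpmf(ypois[t], lam)
    if lp == NEG_INF:
        return NEG_INF
    lp += binom_logpmf(p2b[t], N[t, 0], phi0[t])
    if lp == NEG_INF:
        return NEG_INF
    for i in range(5):
        n = N[t, 1 + i]
        r = rec[t, i]
        s = stay[t, i] if i < 4 else 0
        rr = rho[i, t] if i < 4 else 1.0
        lp += trinom_logpmf(n, r, s, phi2[t] * rr, phi2[t] * (1.0 - rr))
        if lp == NEG_INF:
            return NEG_INF
    for j in range(3):
        psi = psib[t] if j < 2 else psis[t]
        lp += trinom_logpmf(N[t, 6 + j], bE[t, j], bS[t, j],
                            phi2[t] * psi, phi2[t] * (1.0 - psi))
        if lp == NEG_INF:
            return NEG_INF
    return lp


@njit(cache=True)
def state_logp_total(N, ypois, p2b, rec, stay, bE, bS,
                     phi0, phi2, rho, psib, psis, pif, pie):
    total = 0.0
    for t in range(ypois.shape[0]):
        lp = trans_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                        phi0, phi2, rho, psib, psis, pif, pie)
        if lp == NEG_INF:
            return NEG_INF
        total += lp
    return total


@njit(cache=True)
def counts_logp_year(t, N, logC, sigma):
    """Exact log-normal count density for one year, including the 1/C
    change-of-variable term."""
    B = N[t, 6] + N[t, 7]
    if B <= 0:
        return NEG_INF
    z = (logC[t] - math.log(B)) / sigma
    return -0.5 * z * z - math.log(sigma) - 0.9189385332046727 - logC[t]


@njit(cache=True)
def counts_logp_total(N, logC, sigma):
    total = 0.0
    for t in range(logC.shape[0]):
        lp = counts_logp_year(t, N, logC, sigma)
        if lp == NEG_INF:
            return NEG_INF
        total += lp
    return total


@njit(cache=True)
def rep_logp_year(t, N, nests, fled, pif, pie):
    """Poisson reproduction likelihood for one year; columns FF, EE, MIX."""
    lp = 0.0
    lp += poisson_logpmf(fled[t, 0], 2.0 * pif[t] * nests[t, 0])
    if lp == NEG_INF:
        return NEG_INF
    lp += poisson_logpmf(fled[t, 1], 2.0 * pie[t] * nests[t, 1])
    if lp == NEG_INF:
        return NEG_INF
    if nests[t, 2] > 0:
        b = N[t, 6] + N[t, 7]
        if b <= 0:
            return NEG_INF
        wbar = 2.0 * (N[t, 6] * pif[t] + N[t, 7] * pie[t]) / b
        lp += poisson_logpmf(fled[t, 2], wbar * nests[t, 2])
    return lp


@njit(cache=True)
def rep_logp_total(N, nests, fled, pif, pie):
    total = 0.0
    for t in range(nests.shape[0]):
        lp = rep_logp_year(t, N, nests, fled, pif, pie)
        if lp == NEG_INF:
            return NEG_INF
        total += lp
    return total


@njit(cache=True)
def _obs_logp_year(t, N, logC, sigma, nests, fled, pif, pie, has_counts, has_rep):
    lp = 0.0
    if has_counts:
        v = counts_logp_year(t, N, logC, sigma)
        if v == NEG_INF:
            return NEG_INF
        lp += v
    if has_rep:
        v = rep_logp_year(t, N, nests, fled, pif, pie)
        if v == NEG_INF:
            return NEG_INF
        lp += v
    return lp


@njit(cache=True)
def _local_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                phi0, phi2, rho, psib, psis, pif, pie,
                logC, sigma, nests, fled, has_counts, has_rep):
    """Terms touched by a flow latent of transition t: transition t itself,
    transition t+1 (sources changed), observations of year t+1."""
    Tm1 = ypois.shape[0]
    lp = trans_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                    phi0, phi2, rho, psib, psis, pif, pie)
    if lp == NEG_INF:
        return NEG_INF
    if t + 1 < Tm1:
        v = trans_logp(t + 1, N, ypois, p2b, rec, stay, bE, bS,
                       phi0, phi2, rho, psib, psis, pif, pie)
        if v == NEG_INF:
            return NEG_INF
        lp += v
    v = _obs_logp_year(t + 1, N, logC, sigma, nests, fled, pif, pie, has_counts, has_rep)
    if v == NEG_INF:
        return NEG_INF
    return lp + v


@njit(cache=True)
def latent_sweep(n0, ypois, p2b, rec, stay, bE, bS, I, Ic, N,
                 phi0, phi2, rho, psib, psis, pif, pie,
                 logC, sigma, nests, fled, has_counts, has_rep,
                 n0_scale, flow_scale, i_scale,
                 i_lo, i_hi, n0_hi, adapt, step):
    """One Metropolis sweep over all latent quantities (in place).

    Scales are per-latent random-walk SDs, Robbins-Monro adapted toward an
    acceptance rate of 0.44 while ``adapt`` is true.  Returns the number of
    accepted proposals.
    """
    Tm1 = ypois.shape[0]
    gamma = 1.0 / math.sqrt(step + 1.0) if adapt else 0.0
    target = 0.44
    accepted = 0

    # --- initial state ---
    for c in range(9):
        old = n0[c]
        d = int(round(np.random.normal(0.0, n0_scale[c])))
        if d != 0:
            new = old + d
            if 0 <= new <= n0_hi[c]:
                lp0 = trans_logp(0, N, ypois, p2b, rec, stay, bE, bS,
                                 phi0, phi2, rho, psib, psis, pif, pie)
                v0 = _obs_logp_year(0, N, logC, sigma, nests, fled, pif, pie,
                                    has_counts, has_rep)
                n0[c] = new
                N[0, c] = new
                lp1 = trans_logp(0, N, ypois, p2b, rec, stay, bE, bS,
                                 phi0, phi2, rho, psib, psis, pif, pie)
                v1 = _obs_logp_year(0, N, logC, sigma, nests, fled, pif, pie,
                                    has_counts, has_rep)
                acc = False
                if lp1 > NEG_INF and v1 > NEG_INF:
                    if lp0 == NEG_INF or v0 == NEG_INF:
                        acc = True
                    else:
                        acc = math.log(np.random.random()) < (lp1 + v1) - (lp0 + v0)
                if acc:
                    accepted += 1
                else:
                    n0[c] = old
                    N[0, c] = old
                if adapt:
                    a = 1.0 if acc else 0.0
                    n0_scale[c] = max(0.3, n0_scale[c] * math.exp(gamma * (a - target)))

    # --- flows and immigrants ---
    for t in range(Tm1):
        for k in range(19):
            # k: 0 ypois, 1 p2b, 2..6 rec, 7..10 stay, 11..13 bE, 14..16 bS,
            #    17 immigrants I[t+1], 18 origin swap (see below)
            if k == 18:
                # swap d breeders' origin: former-breeder -> skipper while d
                # extra immigrants keep B fixed; mixes the weakly identified
                # skipper-pool level against psi_s and immigration
                j = 0 if np.random.random() < 0.5 else 1
                d = int(round(np.random.normal(0.0, flow_scale[t, 18])))
                if d == 0:
                    continue
                prop_i = I[t + 1] + d
                # stay clear of the clamp at zero so Ic tracks rint(I) exactly
                if (bE[t, j] - d < 0 or bS[t, j] + d < 0
                        or I[t + 1] < 0.0 or prop_i < 0.0 or prop_i > i_hi):
                    if adapt:
                        flow_scale[t, 18] = max(0.3, flow_scale[t, 18]
                                                * math.exp(gamma * (0.0 - target)))
                    continue
                lp0 = _local_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                                  phi0, phi2, rho, psib, psis, pif, pie,
                                  logC, sigma, nests, fled, has_counts, has_rep)
                bE[t, j] -= d
                bS[t, j] += d
                I[t + 1] = prop_i
                Ic[t + 1] += d
                N[t + 1, 7] -= d
                N[t + 1, 8] += d
                N[t + 1, 6] += d
                lp1 = _local_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                                  phi0, phi2, rho, psib, psis, pif, pie,
                                  logC, sigma, nests, fled, has_counts, has_rep)
                acc = False
                if lp1 > NEG_INF:
                    if lp0 == NEG_INF:
                        acc = True
                    else:
                        acc = math.log(np.random.random()) < lp1 - lp0
                if acc:
                    accepted += 1
                else:
                    bE[t, j] += d
                    bS[t, j] -= d
                    I[t + 1] -= d
                    Ic[t + 1] -= d
                    N[t + 1, 7] += d
                    N[t + 1, 8] -= d
                    N[t + 1, 6] -= d
                if adapt:
                    a = 1.0 if acc else 0.0
                    flow_scale[t, 18] = max(0.3, flow_scale[t, 18]
                                            * math.exp(gamma * (a - target)))
                continue
            if k == 17:
                old_i = I[t + 1]
                was_rw = np.random.random() >= 0.2
                if was_rw:
                    prop = old_i + np.random.normal(0.0, i_scale[t])
                else:
                    # independence draw from the uniform prior (jumps across
                    # the whole support; proposal density cancels)
                    prop = i_lo + np.random.random() * (i_hi - i_lo)
                if prop < i_lo or prop > i_hi:
                    if adapt and was_rw:
                        i_scale[t] = max(0.1, i_scale[t] * math.exp(gamma * (0.0 - target)))
                    continue
                new_ic = int(np.rint(prop)) if prop > 0.0 else 0
                old_ic = Ic[t + 1]
                if new_ic == old_ic:
                    I[t + 1] = prop  # same integer state: always accept
                    continue
                lp0 = _local_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                                  phi0, phi2, rho, psib, psis, pif, pie,
                                  logC, sigma, nests, fled, has_counts, has_rep)
                Ic[t + 1] = new_ic
                N[t + 1, 6] += new_ic - old_ic
                lp1 = _local_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                                  phi0, phi2, rho, psib, psis, pif, pie,
                                  logC, sigma, nests, fled, has_counts, has_rep)
                acc = False
                if lp1 > NEG_INF:
                    if lp0 == NEG_INF:
                        acc = True
                    else:
                        acc = math.log(np.random.random()) < lp1 - lp0
                if acc:
                    I[t + 1] = prop
                    accepted += 1
                else:
                    N[t + 1, 6] -= new_ic - old_ic
                    Ic[t + 1] = old_ic
                if adapt and was_rw:
                    a = 1.0 if acc else 0.0
                    i_scale[t] = max(0.1, i_scale[t] * math.exp(gamma * (a - target)))
                continue

            sc = flow_scale[t, k]
            d = int(round(np.random.normal(0.0, sc)))
            if d == 0:
                continue
            # apply the proposal
            ok = True
            if k == 0:
                if ypois[t] + d < 0:
                    ok = False
                else:
                    lp0 = _local_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                                      phi0, phi2, rho, psib, psis, pif, pie,
                                      logC, sigma, nests, fled, has_counts, has_rep)
                    ypois[t] += d
                    N[t + 1, 0] += d
            elif k == 1:
                if p2b[t] + d < 0:
                    ok = False
                else:
                    lp0 = _local_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                                      phi0, phi2, rho, psib, psis, pif, pie,
                                      logC, sigma, nests, fled, has_counts, has_rep)
                    p2b[t] += d
                    N[t + 1, 1] += d
            elif k < 7:
                i = k - 2
                if rec[t, i] + d < 0:
                    ok = False
                else:
                    lp0 = _local_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                                      phi0, phi2, rho, psib, psis, pif, pie,
                                      logC, sigma, nests, fled, has_counts, has_rep)
                    rec[t, i] += d
                    N[t + 1, 6] += d
            elif k < 11:
                i = k - 7
                if stay[t, i] + d < 0:
                    ok = False
                else:
                    lp0 = _local_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                                      phi0, phi2, rho, psib, psis, pif, pie,
                                      logC, sigma, nests, fled, has_counts, has_rep)
                    stay[t, i] += d
                    N[t + 1, 2 + i] += d
            elif k < 14:
                j = k - 11
                if bE[t, j] + d < 0:
                    ok = False
                else:
                    lp0 = _local_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                                      phi0, phi2, rho, psib, psis, pif, pie,
                                      logC, sigma, nests, fled, has_counts, has_rep)
                    bE[t, j] += d
                    N[t + 1, 7] += d
            else:
                j = k - 14
                if bS[t, j] + d < 0:
                    ok = False
                else:
                    lp0 = _local_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                                      phi0, phi2, rho, psib, psis, pif, pie,
                                      logC, sigma, nests, fled, has_counts, has_rep)
                    bS[t, j] += d
                    N[t + 1, 8] += d
            if not ok:
                if adapt:
                    flow_scale[t, k] = max(0.3, sc * math.exp(gamma * (0.0 - target)))
                continue
            lp1 = _local_logp(t, N, ypois, p2b, rec, stay, bE, bS,
                              phi0, phi2, rho, psib, psis, pif, pie,
                              logC, sigma, nests, fled, has_counts, has_rep)
            acc = False
            if lp1 > NEG_INF:
                if lp0 == NEG_INF:
                    acc = True
                else:
                    acc = math.log(np.random.random()) < lp1 - lp0
            if acc:
                accepted += 1
            else:
                # revert
                if k == 0:
                    ypois[t] -= d
                    N[t + 1, 0] -= d
                elif k == 1:
                    p2b[t] -= d
                    N[t + 1, 1] -= d
                elif k < 7:
                    rec[t, k - 2] -= d
                    N[t + 1, 6] -= d
                elif k < 11:
                    stay[t, k - 7] -= d
                    N[t + 1, 2 + (k - 7)] -= d
                elif k < 14:
                    bE[t, k - 11] -= d
                    N[t + 1, 7] -= d
                else:
                    bS[t, k - 14] -= d
                    N[t + 1, 8] -= d
            if adapt:
                a = 1.0 if acc else 0.0
                flow_scale[t, k] = max(0.3, sc * math.exp(gamma * (a - target)))
    return accepted


_SQRT2 = math.sqrt(2.0)
_LOG_SQRT_2PI = 0.9189385332046727


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


@njit(cache=True)
def _norm_ppf(p):
    """Acklam's rational approximation of the standard normal quantile
    (relative error ~1e-9; used consistently for sampling and density)."""
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    a = (-3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02,
         1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00)
    b = (-5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02,
         6.680131188771972e+01, -1.328068155288572e+01)
    c = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00,
         -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00)
    d = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00,
         3.754408661907416e+00)
    p_low = 0.02425
    if p < p_low:
        q = math.sqrt(-2.0 * math.log(p))
        return (((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
               ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    if p > 1.0 - p_low:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        return -(((((c[0] * q + c[1]) * q + c[2]) * q + c[3]) * q + c[4]) * q + c[5]) / \
               ((((d[0] * q + d[1]) * q + d[2]) * q + d[3]) * q + 1.0)
    q = p - 0.5
    r = q * q
    return (((((a[0] * r + a[1]) * r + a[2]) * r + a[3]) * r + a[4]) * r + a[5]) * q / \
           (((((b[0] * r + b[1]) * r + b[2]) * r + b[3]) * r + b[4]) * r + 1.0)


@njit(cache=True)
def _truncnorm_logpdf(x, mu, tau, lo, hi):
    za = _norm_cdf((lo - mu) / tau)
    zb = _norm_cdf((hi - mu) / tau)
    mass = zb - za
    if mass <= 0.0 or x < lo or x > hi:
        return NEG_INF
    z = (x - mu) / tau
    return -0.5 * z * z - math.log(tau) - _LOG_SQRT_2PI - math.log(mass)


@njit(cache=True)
def shift_trajectory(ypois, p2b, rec, stay, bE, bS, N, I, Ic, i_lo, i_hi, tau, u,
                     phi0_o, phi2_o, rho_o, psib_o, psis_o, pif_o, pie_o,
                     phi0_n, phi2_n, rho_n, psib_n, psis_n, pif_n, pie_n):
    """Shift every flow by the change in its conditional expectation when the
    rates move from old (_o) to new (_n), tracking both the frozen old count
    trajectory and the new one being built (see inference._shift_trajectory
    for the reversibility argument).

    The immigrant pulse absorbs the net change in breeder inflow so the B
    series barely moves and the count likelihood does not resist the rate
    move.  Each year's new immigrant value is drawn from a truncated normal
    centred on the fully compensated value (sd ``tau``, support the prior's
    [i_lo, i_hi]); ``u`` supplies the uniform variates.  Near the bounds the
    draw lands on the closest feasible values instead of forcing a
    rejection.  Returns the proposal-density correction
    ``log q(reverse) - log q(forward)`` for the acceptance ratio.
    """
    Tm1 = ypois.shape[0]
    N_old = N.copy()
    logq_corr = 0.0
    for t in range(Tm1):
        d_breeders = 0
        lam_n = phi0_n[t] * (N[t, 6] * pif_n[t] + N[t, 7] * pie_n[t])
        lam_o = phi0_o[t] * (N_old[t, 6] * pif_o[t] + N_old[t, 7] * pie_o[t])
        d = int(round(lam_n - lam_o))
        ypois[t] += d
        N[t + 1, 0] += d
        d = int(round(phi0_n[t] * N[t, 0] - phi0_o[t] * N_old[t, 0]))
        p2b[t] += d
        N[t + 1, 1] += d
        for i in range(5):
            ro = rho_o[i, t] if i < 4 else 1.0
            rn = rho_n[i, t] if i < 4 else 1.0
            d = int(round(phi2_n[t] * rn * N[t, 1 + i] - phi2_o[t] * ro * N_old[t, 1 + i]))
            rec[t, i] += d
            N[t + 1, 6] += d
            d_breeders += d
            if i < 4:
                d = int(round(phi2_n[t] * (1.0 - rn) * N[t, 1 + i]
                              - phi2_o[t] * (1.0 - ro) * N_old[t, 1 + i]))
                stay[t, i] += d
                N[t + 1, 2 + i] += d
        for j in range(3):
            po = psib_o[t] if j < 2 else psis_o[t]
            pn = psib_n[t] if j < 2 else psis_n[t]
            d = int(round(phi2_n[t] * pn * N[t, 6 + j] - phi2_o[t] * po * N_old[t, 6 + j]))
            bE[t, j] += d
            N[t + 1, 7] += d
            d_breeders += d
            d = int(round(phi2_n[t] * (1.0 - pn) * N[t, 6 + j]
                          - phi2_o[t] * (1.0 - po) * N_old[t, 6 + j]))
            bS[t, j] += d
            N[t + 1, 8] += d
        if d_breeders != 0:
            old_i = I[t + 1]
            old_ic = Ic[t + 1]
            mu_fwd = old_i - d_breeders
            za = _norm_cdf((i_lo - mu_fwd) / tau)
            zb = _norm_cdf((i_hi - mu_fwd) / tau)
            p = za + u[t] * (zb - za)
            new_i = mu_fwd + tau * _norm_ppf(p)
            if new_i < i_lo:
                new_i = i_lo
            elif new_i > i_hi:
                new_i = i_hi
            logq_corr -= _truncnorm_logpdf(new_i, mu_fwd, tau, i_lo, i_hi)
            # reverse proposal: from the new state the compensated centre is
            # new_i + d_breeders and it must produce exactly old_i
            logq_corr += _truncnorm_logpdf(old_i, new_i + d_breeders, tau, i_lo, i_hi)
            I[t + 1] = new_i
            new_ic = int(np.rint(new_i)) if new_i > 0.0 else 0
            Ic[t + 1] = new_ic
            N[t + 1, 6] += new_ic - old_ic
    return logq_corr


@njit(cache=True)
def seed_numba(seed):
    np.random.seed(seed)
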