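"""Derived demographic series, partial correlations and the headline tables."""

import numpy as np
import pytest

from seabird_ipm.derived import (
    growth_rate,
    integrative_recruitment,
    immigration_rate,
    present_nonbreeders,
    breeder_composition,
    partial_correlation,
    posterior_partial_correlation,
    sign_support,
    analysis_tables,
    derived_series,
)
from seabird_ipm.synthetic import flows_from_trajectory


def test_growth_rate_examples_and_telescoping(rng):
    assert growth_rate(np.array([100.0, 110.0]))[0] == pytest.approx(1.1)
    assert np.allclose(growth_rate(np.full(6, 42.0)), 1.0)
    B = rng.uniform(500, 2500, 15)
    lam = growth_rate(B)
    assert np.prod(lam) == pytest.approx(B[-1] / B[0], rel=1e-12)
    with pytest.raises(ValueError):
        growth_rate(np.array([10.0, 0.0, 5.0]))


def test_integrative_recruitment_definition():
    # 30 local recruits, 70 available non-recruited pre-breeders -> 0.30
    T = 3
    N = np.zeros((T, 9))
    N[1, 2:6] = [40, 20, 7, 3]  # P3..P6 sum to 70
    local = np.array([0.0, 30.0, 0.0])
    ir = integrative_recruitment(local, N)
    assert np.isnan(ir[0])
    assert ir[1] == pytest.approx(0.30)
    # no recruits and no available pre-breeders -> undefined
    assert np.isnan(ir[2])


def test_immigration_rate_sign_and_zero():
    B = np.array([1000.0, 1000.0])
    assert immigration_rate(np.zeros(2), B)[1] == 0.0
    # negative immigrant numbers are legitimate under the prior
    assert immigration_rate(np.array([0.0, -2.0]), B)[1] == pytest.approx(-0.002)
    with pytest.raises(ValueError):
        immigration_rate(np.array([1.0]), np.array([0.0]))


def test_present_nonbreeders_limits():
    N = np.zeros((2, 9))
    N[:, 1:6] = 10  # 50 pre-breeders of ages 2-6
    N[:, 8] = 20    # skippers
    full = present_nonbreeders(N, p_P=np.ones(2), p_R=1.0)
    assert np.allclose(full, 70.0)
    only_skippers = present_nonbreeders(N, p_P=np.zeros(2), p_R=0.9)
    assert np.allclose(only_skippers, 18.0)


def test_breeder_composition_sums_to_one():
    B = np.array([[100.0, 100.0]])
    comp = breeder_composition(B, np.array([[np.nan, 70.0]]), np.array([[np.nan, 10.0]]),
                               np.array([[20.0, 15.0]]), np.array([[0.0, 5.0]]))
    assert np.all(np.isnan(comp[:, 0]))
    assert comp[0, 1].sum() == pytest.approx(1.0)
    # a year fed only by surviving former breeders
    comp = breeder_composition(np.array([[50.0, 50.0]]), np.array([[np.nan, 50.0]]),
                               np.array([[np.nan, 0.0]]), np.zeros((1, 2)), np.zeros((1, 2)))
    assert comp[0, 1, 0] == pytest.approx(1.0)


def test_partial_correlation_reduces_to_pearson(rng):
    y = rng.standard_normal(30)
    x = rng.standard_normal(30)
    assert partial_correlation(y, x) == pytest.approx(np.corrcoef(y, x)[0, 1], abs=1e-12)


def test_partial_correlation_cross_oracle(rng):
    """Residual-regression value equals the inverse-correlation-matrix value."""
    for _ in range(25):
        n = int(rng.integers(12, 40))
        y = rng.standard_normal(n)
        x = 0.5 * y + rng.standard_normal(n)
        c1 = rng.standard_normal(n)
        c2 = 0.3 * x + rng.standard_normal(n)
        got = partial_correlation(y, x, [c1, c2])
        R = np.corrcoef(np.vstack([y, x, c1, c2]))
        P = np.linalg.inv(R)
        oracle = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        assert got == pytest.approx(oracle, abs=1e-10)


def test_partial_correlation_symmetry_and_affine_invariance(rng):
    for _ in range(10):
        y = rng.standard_normal(20)
        x = rng.standard_normal(20)
        c = [rng.standard_normal(20)]
        a = partial_correlation(y, x, c)
        assert partial_correlation(x, y, c) == pytest.approx(a, abs=1e-12)
        assert partial_correlation(3.2 * y - 7, 0.1 * x + 2, c) == pytest.approx(a, abs=1e-10)


def test_partial_correlation_degenerate_cases(rng):
    y = rng.standard_normal(20)
    x = rng.standard_normal(20)
    # response identical to a control: zero residual variance -> NaN
    assert np.isnan(partial_correlation(y, x, [y]))
    with pytest.raises(ValueError):
        partial_correlation(y, x, [np.ones(20), 2 * np.ones(20)])  # collinear


def test_sign_support():
    assert sign_support(np.array([0.2, 0.1, 0.3])) == 1.0
    assert sign_support(np.array([2.0, -1.0, 1.0])) == pytest.approx(2 / 3)
    assert sign_support(np.array([1.0, -1.0])) == 0.5  # mean exactly zero
    rng = np.random.default_rng(0)
    s = rng.standard_normal(1000) + 0.3
    direct = np.mean(np.sign(s) == np.sign(s.mean()))
    assert sign_support(s) == pytest.approx(direct)
    with pytest.raises(ValueError):
        sign_support(np.array([]))


def test_posterior_partial_correlation_limits(rng):
    n, T = 200, 20
    ctrl = rng.standard_normal((n, T))
    x = rng.standard_normal((n, T))
    y = np.empty((n, T))
    y[:, 1:] = 2.0 + 3.0 * x[:, :-1]  # exact positive function of lagged predictor
    y[:, 0] = 0.0
    res = posterior_partial_correlation(y, x, [ctrl], lag=1)
    assert res.mean == pytest.approx(1.0, abs=1e-6)
    assert res.P == 1.0

    # independently permuted predictor: no association, P concentrates near 0.5
    ps = []
    for k in range(10):
        xp = rng.permuted(x, axis=1)
        res = posterior_partial_correlation(rng.standard_normal((n, T)), xp, [ctrl], lag=1)
        ps.append(res.P)
    assert np.median(ps) < 0.9


def test_analysis_tables_shapes_and_consistency(default_fit):
    study, bundle, draws = default_fit
    counts = bundle.counts.sort_values("year")["count"].to_numpy(float)
    growth, propensity = analysis_tables(draws, observed_counts=counts)
    assert len(growth) == 5
    assert propensity.shape[0] == 12  # 4 statuses x 3 features
    for df in (growth, propensity):
        assert np.all(df["ci_low"] <= df["mean"])
        assert np.all(df["mean"] <= df["ci_high"])
        assert np.all((df["P"] >= 0.5) & (df["P"] <= 1.0))


def test_composition_sums_to_one_per_draw(default_fit):
    _, _, draws = default_fit
    comp = derived_series(draws)["composition"]
    sums = comp[:, 1:, :].sum(axis=2)
    assert np.allclose(sums, 1.0)


def test_derived_series_match_truth_record(default_fit):
    """Integrative recruitment and composition computed from the exact
    simulated flows agree with direct individual-level counts."""
    study, _, _ = default_fit
    traj = study.truth["trajectory"]
    la = flows_from_trajectory(traj)
    N = la.counts().astype(float)

    ir = integrative_recruitment(la.local_recruits.astype(float), N)
    # direct count from individual paths: locals entering F at t over those
    # plus surviving never-bred pre-breeders of ages 3-6
    M = traj.states
    for t in (5, 12, 20):
        recruits = int(((M[:, t] == 6)).sum() - traj.immigrant_inflow[t])
        avail = recruits + int(np.isin(M[:, t], (2, 3, 4, 5)).sum())
        assert ir[t] == pytest.approx(recruits / avail)

    B = N[:, 6] + N[:, 7]
    comp = breeder_composition(
        B,
        np.concatenate([[np.nan], la.bE[:, 0] + la.bE[:, 1]]),
        np.concatenate([[np.nan], la.bE[:, 2]]),
        la.local_recruits.astype(float),
        la.Ic.astype(float),
    )
    for t in (5, 12, 20):
        former_b = int(((M[:, t] == 7) & ((M[:, t - 1] == 6) | (M[:, t - 1] == 7))).sum())
        assert comp[t, 0] == pytest.approx(former_b / B[t])
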