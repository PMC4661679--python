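"""Logistic fitter: oracle agreement, offsets, separation, stability."""
import numpy as np
import pytest
import statsmodels.api as sm

from poolsim import (
    FitResult,
    ParameterError,
    RankDeficiencyError,
    classify_stability,
    fit_logistic,
    fit_population_truth,
)
from poolsim.pooling import PoolAllocation, pooled_design, sample_stratum_indices, stratum_indices


@pytest.fixture(scope="module")
def fixed_design():
    """A deterministic 20-row design with a nonzero offset."""
    rng = np.random.default_rng(2024)
    X = rng.standard_normal((20, 4))
    X[:, 2] = (X[:, 2] > 0).astype(float)  # binary column
    beta = np.array([0.3, 0.8, -0.4, 0.6, 0.2])
    off = np.where(X[:, 2] > 0, np.log(1.2), np.log(5 / 18))
    eta = beta[0] + X @ beta[1:] + off
    y = (rng.random(20) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y, off


def test_matches_statsmodels_irls_oracle(fixed_design):
    X, y, off = fixed_design
    fit = fit_logistic(X, y, off)
    ref = sm.GLM(
        y, sm.add_constant(X), family=sm.families.Binomial(), offset=off
    ).fit()
    np.testing.assert_allclose(fit.coef, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.se, ref.bse, atol=1e-6)
    assert fit.converged


def test_score_equations_satisfied(fixed_design):
    X, y, off = fixed_design
    fit = fit_logistic(X, y, off)
    Xf = np.column_stack([np.ones(len(y)), X])
    mu = 1 / (1 + np.exp(-(Xf @ fit.coef + off)))
    assert np.linalg.norm(Xf.T @ (y - mu)) < 1e-6


def test_null_design_gives_unit_or(rng):
    X = rng.standard_normal((200, 4))
    y = (rng.random(200) < 0.4).astype(float)
    fit = fit_logistic(X, np.zeros_like(y) + y, np.zeros(200))
    assert fit.or1 == pytest.approx(1.0, abs=0.5)
    assert fit.p1 > 0.001


def test_offset_constant_shifts_intercept_only(fixed_design):
    X, y, off = fixed_design
    a = fit_logistic(X, y, off)
    b = fit_logistic(X, y, off + 0.37)
    assert b.coef[0] == pytest.approx(a.coef[0] - 0.37, abs=1e-6)
    np.testing.assert_allclose(a.coef[1:], b.coef[1:], atol=1e-6)


def test_row_permutation_invariance(fixed_design, rng):
    X, y, off = fixed_design
    perm = rng.permutation(len(y))
    a = fit_logistic(X, y, off)
    b = fit_logistic(X[perm], y[perm], off[perm])
    np.testing.assert_allclose(a.coef, b.coef, atol=1e-8)


def test_separation_flagged_not_raised():
    gen = np.random.default_rng(50)
    X = gen.standard_normal((12, 4)) * 0.1
    X[:, 0] = np.arange(12.0)
    y = (X[:, 0] >= 6).astype(float)  # perfectly separable on column 0
    fit = fit_logistic(X, y, np.zeros(12))
    assert not fit.converged
    assert not fit.stable
    assert fit.or1 > 10 or fit.or1 < 0.1 or not np.isfinite(fit.or1)


def test_rank_deficient_design_raises(rng):
    X = rng.standard_normal((30, 4))
    X[:, 3] = 2 * X[:, 1]
    y = (rng.random(30) < 0.5).astype(float)
    with pytest.raises(RankDeficiencyError):
        fit_logistic(X, y, np.zeros(30))


def test_input_validation(rng):
    X = rng.standard_normal((4, 4))
    with pytest.raises(ParameterError):
        fit_logistic(X, np.zeros(4), np.zeros(4))  # too few rows
    X = rng.standard_normal((30, 4))
    with pytest.raises(ParameterError):
        fit_logistic(X, np.full(30, 0.5), np.zeros(30))  # non-binary outcome


@pytest.mark.parametrize(
    "converged,or1,or2,stable",
    [
        (True, 1.0, 1.0, True),
        (True, 10.0, 1.0, False),   # boundary is unstable
        (True, 1.0, 0.1, False),
        (True, 9.99, 0.11, True),
        (False, 1.0, 1.0, False),   # non-converged is never stable
    ],
)
def test_stability_rule(converged, or1, or2, stable):
    fit = FitResult(
        coef=np.zeros(5), se=np.ones(5), p1=0.5, p2=0.5,
        or1=or1, or2=or2, converged=converged, n_iter=3,
    )
    assert classify_stability(fit) is stable


def test_pool_size_one_equals_individual_fit(viable_population):
    """A g=1 'pooled' fit is numerically the individual-level fit."""
    alloc = PoolAllocation(g=1, scale=8)
    strata = stratum_indices(viable_population)
    sampled = sample_stratum_indices(strata, alloc, np.random.default_rng(31))
    cols = {c: viable_population[c].to_numpy(dtype=float)
            for c in ("w1", "w2", "z", "w_ga")}
    X, y, off = pooled_design(cols, sampled, alloc, np.random.default_rng(32))
    pooled = fit_logistic(X, y, off)

    idx = np.concatenate(list(sampled.values()))
    Xi = np.column_stack([cols[c][idx] for c in ("w1", "w2", "z", "w_ga")])
    yi = viable_population["y_case"].to_numpy(dtype=float)[idx]
    offi = np.where(Xi[:, 2] == 1, np.log(12 / 10), np.log(5 / 18))
    individual = fit_logistic(Xi, yi, offi)
    np.testing.assert_allclose(pooled.coef, individual.coef, atol=1e-6)


def test_population_truth_fit_null_when_no_effect():
    from poolsim import ScenarioSpec, build_population
    spec = ScenarioSpec(model_form="linear", beta1=0.0, sigma2_1=0.25,
                        n_pop=150_000, seed=6)
    pop = build_population(spec)
    fit = fit_population_truth(pop[pop["viable"]])
    assert fit.or1 == pytest.approx(1.0, abs=0.05)


def test_duplicating_population_leaves_coefficients_unchanged(viable_population):
    import pandas as pd
    sub = viable_population.head(4000)
    a = fit_population_truth(sub)
    b = fit_population_truth(pd.concat([sub, sub], ignore_index=True))
    np.testing.assert_allclose(a.coef, b.coef, atol=1e-6)
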