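"""Regression baselines, the metric suite, and the benchmark driver."""

import numpy as np
import pytest

from minepi import (
    ObservationSet,
    benchmark_curve,
    evaluate,
    fit_additive,
    fit_l1_threeway,
    fit_l2,
    interpolate,
    make_space,
    randomization_test_r2,
    summarize_benchmark,
)
from minepi.baselines import _r2, default_lambda_grid, one_hot_design
from minepi.simulate import crater_landscape, sample_observations

from conftest import random_additive


def full_obs(space, y):
    return ObservationSet(space, np.arange(space.n_genotypes), np.asarray(y, float))


def test_additive_fit_recovers_additive_truth(space33, rng):
    truth = random_additive(space33, rng)
    obs, held = sample_observations(space33, truth, 0.6, seed=1)
    fit = fit_additive(obs)
    rep = evaluate(space33, fit.predict(), truth, obs.in_sample_mask())
    assert rep.out_r2 == pytest.approx(1.0, abs=1e-8)


def test_additive_fit_closed_form(square):
    fit = fit_additive(full_obs(square, [0.0, 0.0, 0.0, 1.0]))
    assert np.allclose(fit.predict(), [-0.25, 0.25, 0.25, 0.75])
    const = fit_additive(full_obs(square, [2.0, 2.0, 2.0, 2.0]))
    assert np.allclose(const.predict(), 2.0)


def test_l2_on_additive_data_matches_additive_fit(space33, rng):
    truth = random_additive(space33, rng)
    obs, _ = sample_observations(space33, truth, 0.8, seed=2)
    fit = fit_l2(obs, max_order=2, seed=0, k_folds=5)
    assert np.allclose(fit.predict(), fit_additive(obs).predict(), atol=1e-4)
    assert np.linalg.norm(fit.gamma) < 1e-4


def test_l2_fixed_lambda_matches_penalized_normal_equations(space33, rng):
    """Spectral path solver vs the textbook ridge closed form."""
    truth = rng.standard_normal(27)
    obs, _ = sample_observations(space33, truth, 0.7, seed=3)
    lam = 0.37
    fit = fit_l2(obs, max_order=2, lambda_grid=[lam], k_folds=3, seed=0)
    phi = space33.interaction_basis([0, 1])[obs.indices]
    psi = space33.interaction_basis([2])[obs.indices]
    D = np.hstack([phi, psi])
    P = np.diag(np.concatenate([np.zeros(phi.shape[1]), np.full(psi.shape[1], lam)]))
    coef = np.linalg.solve(D.T @ D + P, D.T @ obs.y)
    assert np.allclose(np.concatenate([fit.beta, fit.gamma]), coef, atol=1e-8)


def test_l2_cv_is_reproducible(space33, rng):
    truth = rng.standard_normal(27)
    obs, _ = sample_observations(space33, truth, 0.8, seed=4)
    a = fit_l2(obs, max_order=2, seed=7, k_folds=5)
    b = fit_l2(obs, max_order=2, seed=7, k_folds=5)
    assert a.lam == b.lam
    assert np.array_equal(a.cv_table["cv_mse"], b.cv_table["cv_mse"])
    assert a.lam in set(a.cv_table["lambda"])


def test_l2_full_order_interpolates_at_zero_penalty(square, rng):
    """With Psi spanning all orders >= 2 and lambda -> 0 the model can
    reproduce complete data exactly (basis completeness)."""
    y = rng.standard_normal(4)
    fit = fit_l2(full_obs(square, y), max_order=2, lambda_grid=[1e-12], k_folds=2, seed=0)
    assert np.allclose(fit.predict(), y, atol=1e-6)


def test_l2_in_sample_error_monotone_in_lambda(space33, rng):
    truth = rng.standard_normal(27)
    obs, _ = sample_observations(space33, truth, 0.8, seed=5)
    sse = []
    for lam in [1e-6, 1e-2, 1.0, 100.0]:
        fit = fit_l2(obs, max_order=2, lambda_grid=[lam], k_folds=3, seed=0)
        resid = obs.y - fit.predict()[obs.indices]
        sse.append(float(resid @ resid))
    assert all(a <= b + 1e-10 for a, b in zip(sse, sse[1:]))


def test_l1_huge_penalty_gives_intercept_only(space33, rng):
    truth = rng.standard_normal(27)
    obs, _ = sample_observations(space33, truth, 0.8, seed=6)
    fit = fit_l1_threeway(obs, seed=0, k_folds=3, n_lambdas=[1e6])
    assert np.count_nonzero(fit.coef) == 0
    assert np.allclose(fit.predict(), obs.y.mean(), atol=1e-8)


def test_l1_recovers_sparse_low_order_signal(rng):
    """Data generated from a few <= 3-way one-hot terms is predicted well
    out of sample."""
    space = make_space(5, 2)
    X = one_hot_design(space, max_order=3)
    coef = np.zeros(X.shape[1])
    coef[rng.choice(X.shape[1], size=6, replace=False)] = rng.standard_normal(6) * 2
    truth = np.asarray(X @ coef) + 1.0
    obs, _ = sample_observations(space, truth, 0.8, seed=7)
    fit = fit_l1_threeway(obs, seed=0, k_folds=5)
    rep = evaluate(space, fit.predict(), truth, obs.in_sample_mask())
    assert rep.out_r2 > 0.9


def test_evaluate_basic_metrics(space33, rng):
    truth = rng.standard_normal(27)
    mask = np.zeros(27, dtype=bool)
    mask[:20] = True
    perfect = evaluate(space33, truth, truth, mask)
    assert perfect.out_r2 == pytest.approx(1.0)
    assert perfect.total_r2 == pytest.approx(1.0)
    assert perfect.fdr in (0.0, np.nan) or perfect.fdr == 0.0
    flat = evaluate(space33, np.full(27, truth.mean()), truth, mask)
    assert flat.total_r2 == pytest.approx(0.0, abs=1e-10)


def test_evaluate_fdr_hand_count(cube):
    """Top-50% calls: two out-of-sample genotypes predicted above the
    median, one of them truly below it -> FDR = 1/2."""
    truth = np.arange(8.0)  # median threshold (50th pct) = 3.5
    pred = truth.copy()
    mask = np.ones(8, dtype=bool)
    mask[[1, 6, 7]] = False  # out-of-sample: 1, 6, 7
    pred[1] = 5.0  # false call (truth 1 < 3.5)
    pred[6] = 6.0  # true call
    pred[7] = 2.0  # no call
    rep = evaluate(cube, pred, truth, mask, percentile=50.0)
    assert rep.fdr == pytest.approx(0.5)


def test_evaluate_requires_out_of_sample(cube, rng):
    with pytest.raises(ValueError):
        evaluate(cube, rng.standard_normal(8), rng.standard_normal(8), np.ones(8, bool))


def test_randomization_test_whole_space_is_null(space33, rng):
    f = rng.standard_normal(27)
    r2, p = randomization_test_r2(space33, f, np.arange(27), n_rand=20, seed=0)
    assert p == 1.0


def test_randomization_test_detects_additive_region(rng):
    """A sub-cube carrying an exactly additive signal inside an otherwise
    random landscape scores an exceptional additive R^2."""
    space = make_space(5, 2)
    f = rng.standard_normal(32) * 2
    sub = np.array([i for i in range(32) if space.digits(i)[0] == 0])
    effects = rng.standard_normal(space.l) * 3
    for i in sub:
        f[i] = float(space.digits(i) @ effects)
    r2, p = randomization_test_r2(space, f, sub, n_rand=200, seed=1)
    assert r2 > 0.99
    assert p < 0.05
    _, p1 = randomization_test_r2(space, f, sub, n_rand=200, seed=1, add_one=True)
    assert p1 == pytest.approx((p * 200 + 1) / 201)


def test_benchmark_curve_shape_and_orderings(rng):
    space = make_space(6, 2)
    truth = crater_landscape(space)
    table = benchmark_curve(
        space, truth, fractions=[0.3, 0.9], models=["interpolation", "additive"],
        replicates=2, seed=0,
    )
    assert len(table) == 2 * 2 * 2
    summary = summarize_benchmark(table)
    interp_r2 = summary.set_index(["fraction", "model"])["out_r2_mean"]
    # denser training helps interpolation; the additive model cannot
    # represent the crater shape at any density
    assert interp_r2[(0.9, "interpolation")] > interp_r2[(0.3, "interpolation")]
    assert interp_r2[(0.9, "interpolation")] > interp_r2[(0.9, "additive")]


def test_lambda_grid_spans_log_space():
    grid = default_lambda_grid(np.arange(10.0))
    assert len(grid) == 20
    ratios = grid[1:] / grid[:-1]
    assert np.allclose(ratios, ratios[0])


def test_r2_degenerate_reference():
    assert _r2(np.ones(4), np.ones(4)) == 1.0
    assert _r2(np.ones(4), np.zeros(4)) == -np.inf
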