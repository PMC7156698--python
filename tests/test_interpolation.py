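"""The constrained minimization: solvers, properties, noise propagation."""

import numpy as np
import pytest

from minepi import (
    IdentifiabilityError,
    ObservationSet,
    interpolate,
    interpolate_iterative_smoothing,
    make_space,
    mean_squared_epistasis,
    prediction_covariance,
    regularized_reconstruction,
    smooth_in_sample,
    smoother_apply,
)
from minepi.interpolation import cost_sparse
from minepi.simulate import sample_observations

from conftest import random_additive


def two_locus_obs(square):
    # observe wild type and both single mutants: y(aa)=0, y(aB)=2, y(Ab)=1
    return ObservationSet(square, np.array([0, 1, 2]), np.array([0.0, 2.0, 1.0]))


def kkt_oracle(space, obs):
    """Generic equality-constrained quadratic program solved via the full
    dense KKT system — independent of the block-elimination solver."""
    n = space.n_genotypes
    C = cost_sparse(space).toarray()
    m = obs.n_observed
    A = np.zeros((m, n))
    A[np.arange(m), obs.indices] = 1.0
    kkt = np.block([[2 * C, A.T], [A, np.zeros((m, m))]])
    rhs = np.concatenate([np.zeros(n), obs.y])
    sol = np.linalg.solve(kkt, rhs)
    return sol[:n]


def test_two_locus_additive_prediction(square):
    res = interpolate(two_locus_obs(square))
    assert res.f_hat[3] == pytest.approx(3.0)  # wild type + sum of single effects
    assert np.allclose(res.f_hat[:3], [0.0, 2.0, 1.0])


def test_two_locus_prediction_variance(square):
    var = prediction_covariance(two_locus_obs(square), sigma2=1.0)
    assert var == pytest.approx([3.0])
    assert np.allclose(prediction_covariance(two_locus_obs(square), sigma2=0.0), 0.0)


def test_additive_data_recovered_exactly(space33, rng):
    truth = random_additive(space33, rng)
    obs, _ = sample_observations(space33, truth, 0.6, seed=4)
    res = interpolate(obs)
    assert np.allclose(res.f_hat, truth, atol=1e-8)
    assert mean_squared_epistasis(space33, res.f_hat) == pytest.approx(0.0, abs=1e-12)


def test_direct_solver_matches_qp_oracle(space33, rng):
    f = rng.standard_normal(27)
    idx = rng.choice(27, size=20, replace=False)
    obs = ObservationSet(space33, idx, f[idx])
    res = interpolate(obs)
    assert np.allclose(res.f_hat, kkt_oracle(space33, obs), atol=1e-8)


def test_iterative_smoothing_agrees_with_direct(rng):
    space = make_space(4, 2)
    f = rng.standard_normal(16)
    obs, _ = sample_observations(space, f, 0.5, seed=9)
    direct = interpolate(obs)
    fixed_point = interpolate_iterative_smoothing(obs, tol=1e-10)
    assert np.max(np.abs(direct.f_hat - fixed_point.f_hat)) < 1e-6
    assert fixed_point.diagnostics["iterations"] > 0


def test_iterative_smoothing_from_any_start(square):
    obs = two_locus_obs(square)
    for init in (np.zeros(4), np.full(4, 100.0)):
        res = interpolate_iterative_smoothing(obs, initial=init)
        assert res.f_hat[3] == pytest.approx(3.0, abs=1e-8)


def test_full_observation_is_identity(square, rng):
    y = rng.standard_normal(4)
    obs = ObservationSet(square, np.arange(4), y)
    res = interpolate_iterative_smoothing(obs)
    assert res.diagnostics["iterations"] == 0
    assert np.allclose(res.f_hat, y)
    assert np.allclose(interpolate(obs).f_hat, y)


def test_cg_solver_matches_direct(space33, rng):
    f = rng.standard_normal(27)
    obs, _ = sample_observations(space33, f, 0.7, seed=2)
    assert np.allclose(
        interpolate(obs, solver="iterative_linear").f_hat,
        interpolate(obs).f_hat,
        atol=1e-6,
    )


def test_solution_is_harmonic_for_second_order_laplacian(space33, rng):
    """(L^2 - alpha L) f_hat = 0 at every unobserved genotype."""
    f = rng.standard_normal(27)
    obs, held = sample_observations(space33, f, 0.6, seed=5)
    res = interpolate(obs)
    L = space33.laplacian_apply
    resid = L(L(res.f_hat)) - space33.alpha * L(res.f_hat)
    assert np.max(np.abs(resid[held])) < 1e-8


def test_out_of_sample_values_equal_local_additive_prediction(space33, rng):
    f = rng.standard_normal(27)
    obs, held = sample_observations(space33, f, 0.6, seed=6)
    res = interpolate(obs)
    Mf = smoother_apply(space33, res.f_hat)
    assert np.max(np.abs(Mf[held] - res.f_hat[held])) < 1e-8
    assert np.max(np.abs(smooth_in_sample(res)[held] - res.f_hat[held])) < 1e-8


def test_optimality_against_random_perturbations(space33, rng):
    f = rng.standard_normal(27)
    obs, held = sample_observations(space33, f, 0.5, seed=7)
    res = interpolate(obs)
    base = mean_squared_epistasis(space33, res.f_hat)
    for _ in range(20):
        delta = np.zeros(27)
        delta[held] = rng.standard_normal(len(held))
        assert mean_squared_epistasis(space33, res.f_hat + delta) >= base - 1e-12


def test_linearity_in_data_and_constant_shift(space33, rng):
    idx = rng.choice(27, size=18, replace=False)
    y1, y2 = rng.standard_normal(18), rng.standard_normal(18)
    f1 = interpolate(ObservationSet(space33, idx, y1)).f_hat
    f2 = interpolate(ObservationSet(space33, idx, y2)).f_hat
    f12 = interpolate(ObservationSet(space33, idx, y1 + y2)).f_hat
    assert np.allclose(f12, f1 + f2, atol=1e-8)
    fshift = interpolate(ObservationSet(space33, idx, y1 + 5.0)).f_hat
    assert np.allclose(fshift, f1 + 5.0, atol=1e-8)


def test_unidentifiable_design_is_rejected():
    """Leaving an allele unobserved at some site makes the additive fit,
    hence the interpolation, non-unique."""
    space = make_space(3, 2)
    idx = np.array([i for i in range(8) if space.digits(i)[0] == 0])
    obs = ObservationSet(space, idx, np.zeros(len(idx)))
    with pytest.raises(IdentifiabilityError):
        interpolate(obs)


def test_observation_validation(square):
    with pytest.raises(ValueError, match="duplicate"):
        ObservationSet(square, np.array([0, 0, 1]), np.zeros(3))
    with pytest.raises(ValueError, match="outside"):
        ObservationSet(square, np.array([0, 9]), np.zeros(2))


def test_monte_carlo_variance_matches_formula(rng):
    """Empirical prediction variance over noise replicates agrees with the
    linear-propagation formula within 10% relative error."""
    space = make_space(3, 2)
    truth = random_additive(space, rng)
    idx = np.sort(rng.choice(8, size=5, replace=False))
    obs0 = ObservationSet(space, idx, truth[idx])
    interpolate(obs0)  # identifiability check; raises if the design is bad
    sigma = 0.5
    predicted = prediction_covariance(obs0, sigma**2)
    reps = np.empty((2000, 8 - len(idx)))
    held = np.setdiff1d(np.arange(8), idx)
    for r in range(2000):
        y = truth[idx] + sigma * rng.standard_normal(len(idx))
        reps[r] = interpolate(ObservationSet(space, idx, y)).f_hat[held]
    empirical = reps.var(axis=0, ddof=1)
    assert np.all(np.abs(empirical - predicted) <= 0.10 * predicted)


def test_noise_variance_is_reduced_in_dense_designs(rng):
    """With dense sampling the averaging over many faces shrinks the
    noise-induced prediction variance well below the input noise."""
    space = make_space(6, 2)  # l(alpha-1)/5 = 1.2 > 1
    f = rng.standard_normal(64)
    obs, _ = sample_observations(space, f, 0.9, seed=3)
    var = prediction_covariance(obs, sigma2=1.0)
    assert var.mean() < 1.0


def test_regularized_reconstruction_limits(square, rng):
    obs = two_locus_obs(square)
    near_exact = regularized_reconstruction(obs, mix=1 - 1e-9)
    assert np.allclose(near_exact, interpolate(obs).f_hat, atol=1e-5)
    assert np.allclose(regularized_reconstruction(obs, mix=1.0), interpolate(obs).f_hat)
    y = rng.standard_normal(4)
    full = ObservationSet(square, np.arange(4), y)
    assert np.allclose(regularized_reconstruction(full, mix=1e-9), y, atol=1e-6)
    with pytest.raises(ValueError):
        regularized_reconstruction(obs, mix=0.0)


def test_regularized_reconstruction_denoises_additive_data(rng):
    """An intermediate mix trades data fidelity for smoothness and lands
    closer to the noise-free additive truth than the no-smoothing limit."""
    space = make_space(4, 2)
    truth = random_additive(space, rng)
    noisy = truth + 0.5 * rng.standard_normal(16)
    obs = ObservationSet(space, np.arange(16), noisy)
    rough = regularized_reconstruction(obs, mix=1e-9)
    smooth = regularized_reconstruction(obs, mix=0.9)
    err_rough = np.linalg.norm(rough - truth)
    err_smooth = np.linalg.norm(smooth - truth)
    assert err_smooth < err_rough
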