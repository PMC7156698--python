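"""Regression baselines and the benchmark metric suite.

The comparison models are the standard alternatives to minimum-epistasis
interpolation for genotype-phenotype regression:

* additive (nonepistatic) ordinary least squares;
* L2-regularized pairwise / three-way regression in the orthonormal
  interaction eigenbasis,  f_hat = Phi beta + Psi gamma,  minimizing
  ||y - Phi beta - Psi gamma||^2 + lambda ||gamma||^2  with beta (the
  additive block) unpenalized and lambda chosen by 10-fold CV over a
  log10-spaced grid;
* L1-regularized three-way regression on the one-hot interaction design
  (lasso), which can exploit sparse interaction structure.

The metric suite covers out-of-sample and total R^2, the mean-squared
epistatic coefficient over held-out faces, local-maxima counts and their
out-of-sample enrichment, a percentile false-discovery rate for top
predictions, and a randomization test for the R^2 of local additive fits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.linear_model import LassoCV

from . import interpolation as interp
from .epistasis import local_maxima, mean_squared_epistasis_subset
from .interpolation import ObservationSet
from .spaces import GenotypeSpace


@dataclass
class ModelFit:
    """A fitted baseline model with enough state to reproduce predictions."""

    family: str
    space: GenotypeSpace
    beta: np.ndarray | None = None       # additive-block coefficients (order 0-1 basis)
    gamma: np.ndarray | None = None      # penalized interaction coefficients
    coef: np.ndarray | None = None       # one-hot coefficients (L1 family)
    intercept: float = 0.0
    lam: float | None = None
    cv_table: pd.DataFrame | None = None
    orders: tuple[int, ...] = ()
    fitted: np.ndarray | None = field(default=None, repr=False)

    def predict(self) -> np.ndarray:
        """Predicted phenotype for every genotype in the space."""
        if self.fitted is not None:
            return self.fitted
        raise RuntimeError("fit carries no cached predictions")


def _r2(reference: np.ndarray, predicted: np.ndarray) -> float:
    """R^2 = 1 - SSE/SST with SST about the mean of the reference values."""
    reference = np.asarray(reference, float)
    predicted = np.asarray(predicted, float)
    sst = float(np.sum((reference - reference.mean()) ** 2))
    sse = float(np.sum((reference - predicted) ** 2))
    if sst == 0:
        return 1.0 if sse == 0 else -np.inf
    return 1.0 - sse / sst


def fit_additive(obs: ObservationSet) -> ModelFit:
    """Ordinary least squares on the additive (order 0-1) eigenbasis."""
    space = obs.space
    interp.check_identifiability(obs)
    phi = space.interaction_basis([0, 1])
    beta, *_ = np.linalg.lstsq(phi[obs.indices], obs.y, rcond=None)
    return ModelFit(
        family="additive", space=space, beta=beta, orders=(0, 1), fitted=phi @ beta
    )


def default_lambda_grid(y: np.ndarray, n_points: int = 20) -> np.ndarray:
    """log10-spaced grid spanning [1e-4, 1e4] times the data's mean squared
    deviation (the natural scale of the squared-error term)."""
    y = np.asarray(y, float)
    scale = float(np.mean((y - y.mean()) ** 2)) or 1.0
    return np.logspace(-4, 4, n_points) * scale


def _ridge_path_solver(
    phi_t: np.ndarray, psi_t: np.ndarray, y_t: np.ndarray, grid: np.ndarray
):
    """Solve min ||y - Phi b - Psi g||^2 + lam ||g||^2 for every lam at the
    cost of one eigendecomposition.

    The unpenalized block is concentrated out (project y and Psi off the
    additive column span), leaving a plain ridge on the residualized Psi,
    solved spectrally via the Gram matrix.
    """
    Q, _ = np.linalg.qr(phi_t)
    psi_r = psi_t - Q @ (Q.T @ psi_t)
    y_r = y_t - Q @ (Q.T @ y_t)
    G = psi_r.T @ psi_r
    evals, V = np.linalg.eigh(G)
    b = V.T @ (psi_r.T @ y_r)
    gammas = []
    for lam in grid:
        gammas.append(V @ (b / (evals + lam)))
    betas = []
    for g in gammas:
        beta, *_ = np.linalg.lstsq(phi_t, y_t - psi_t @ g, rcond=None)
        betas.append(beta)
    return betas, gammas


def fit_l2(
    obs: ObservationSet,
    max_order: int = 2,
    lambda_grid: Sequence[float] | None = None,
    k_folds: int = 10,
    seed: int = 0,
) -> ModelFit:
    """L2-regularized interaction regression (pairwise for max_order=2,
    three-way for max_order=3) with CV-chosen penalty."""
    if max_order not in (2, 3):
        raise ValueError("max_order must be 2 or 3")
    space = obs.space
    m = obs.n_observed
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(obs.y)
    lambda_grid = np.asarray(list(lambda_grid), float)
    if lambda_grid.size == 0:
        raise ValueError("empty lambda grid")
    if k_folds > m:
        raise ValueError(f"k_folds={k_folds} exceeds the {m} observations")
    phi = space.interaction_basis([0, 1])
    psi = space.interaction_basis(range(2, max_order + 1))
    phi_B, psi_B = phi[obs.indices], psi[obs.indices]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(m)
    folds = np.array_split(perm, k_folds)
    cv_sse = np.zeros(len(lambda_grid))
    for val in folds:
        tr = np.setdiff1d(perm, val, assume_unique=False)
        betas, gammas = _ridge_path_solver(
            phi_B[tr], psi_B[tr], obs.y[tr], lambda_grid
        )
        for k, (beta, g) in enumerate(zip(betas, gammas)):
            pred = phi_B[val] @ beta + psi_B[val] @ g
            cv_sse[k] += float(np.sum((obs.y[val] - pred) ** 2))
    cv_mse = cv_sse / m
    best = int(np.argmin(cv_mse))
    lam = float(lambda_grid[best])
    betas, gammas = _ridge_path_solver(phi_B, psi_B, obs.y, np.array([lam]))
    beta, gamma = betas[0], gammas[0]
    table = pd.DataFrame({"lambda": lambda_grid, "cv_mse": cv_mse})
    return ModelFit(
        family=f"l2_{'pairwise' if max_order == 2 else 'threeway'}",
        space=space,
        beta=beta,
        gamma=gamma,
        lam=lam,
        cv_table=table,
        orders=tuple(range(max_order + 1)),
        fitted=phi @ beta + psi @ gamma,
    )


def one_hot_design(space: GenotypeSpace, max_order: int = 3) -> sp.csr_matrix:
    """Sparse one-hot interaction design with a column per allelic
    combination on each site subset of size 1..max_order (the duplicate
    intercept column is excluded; the fitter supplies its own)."""
    D = space.digits_matrix()
    n = space.n_genotypes
    cols_rows, cols_cols = [], []
    j = 0
    for k in range(1, max_order + 1):
        for subset in itertools.combinations(range(space.l), k):
            sub = D[:, subset]
            for combo in itertools.product(range(space.alpha), repeat=k):
                hit = np.nonzero((sub == np.asarray(combo)).all(axis=1))[0]
                cols_rows.append(hit)
                cols_cols.append(np.full(hit.size, j, dtype=np.int64))
                j += 1
    rows = np.concatenate(cols_rows)
    cols = np.concatenate(cols_cols)
    return sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(n, j))


def fit_l1_threeway(
    obs: ObservationSet,
    seed: int = 0,
    k_folds: int = 10,
    n_lambdas: int = 20,
    max_order: int = 3,
) -> ModelFit:
    """Lasso on the one-hot design up to three-way interactions, with the
    penalty chosen by cross-validation (coordinate descent via sklearn)."""
    space = obs.space
    X = one_hot_design(space, max_order=max_order)
    X_B = X[obs.indices]
    model = LassoCV(
        alphas=n_lambdas,  # size of the automatically scaled penalty path
        cv=min(k_folds, obs.n_observed),
        random_state=seed,
        fit_intercept=True,
        max_iter=3000,
        tol=1e-3,
        selection="random",
    )
    model.fit(X_B, obs.y)
    fitted = np.asarray(X @ model.coef_) + model.intercept_
    mse_path = np.atleast_2d(model.mse_path_)
    table = pd.DataFrame(
        {"lambda": np.atleast_1d(model.alphas_), "cv_mse": mse_path.mean(axis=-1)}
    )
    return ModelFit(
        family="l1_threeway",
        space=space,
        coef=model.coef_,
        intercept=float(model.intercept_),
        lam=float(model.alpha_),
        cv_table=table,
        orders=tuple(range(max_order + 1)),
        fitted=fitted,
    )


@dataclass
class EvaluationReport:
    """Metric suite for a completed/predicted landscape against a reference."""

    out_r2: float
    in_r2: float
    total_r2: float
    out_eps2: float
    out_eps2_n_faces: int
    n_local_maxima: int
    maxima_enrichment: float
    fdr: float
    percentile: float


def evaluate(
    space: GenotypeSpace,
    predictions: np.ndarray,
    reference: np.ndarray,
    in_sample: np.ndarray,
    percentile: float = 95.0,
    tie_policy: str = "strict",
) -> EvaluationReport:
    """Score predictions against the complete reference landscape.

    out/in/total R^2 split by the in-sample mask; out-of-sample
    mean-squared epistasis is averaged over faces whose four genotypes are
    all out of sample; the FDR is the fraction of out-of-sample genotypes
    predicted above the given percentile of the reference whose true value
    falls below it; maxima enrichment compares the out-of-sample share of
    predicted local maxima with the out-of-sample share of all genotypes.
    """
    predictions = space._check_vector(predictions)
    reference = space._check_vector(reference)
    in_sample = np.asarray(in_sample, bool)
    out = ~in_sample
    if not out.any():
        raise ValueError("no out-of-sample genotypes to evaluate")
    out_idx = np.nonzero(out)[0]
    out_r2 = _r2(reference[out], predictions[out])
    in_r2 = _r2(reference[in_sample], predictions[in_sample]) if in_sample.any() else np.nan
    total_r2 = _r2(reference, predictions)
    sub = mean_squared_epistasis_subset(space, predictions, out_idx)

    maxima = local_maxima(space, predictions, tie_policy=tie_policy)
    if maxima.size:
        enrich = (out[maxima].mean()) / (out.mean())
    else:
        enrich = np.nan

    thresh = float(np.percentile(reference, percentile))
    calls = out & (predictions > thresh)
    fdr = float((reference[calls] <= thresh).mean()) if calls.any() else np.nan
    return EvaluationReport(
        out_r2=out_r2,
        in_r2=in_r2,
        total_r2=total_r2,
        out_eps2=sub.value,
        out_eps2_n_faces=sub.n_faces,
        n_local_maxima=int(maxima.size),
        maxima_enrichment=float(enrich),
        fdr=fdr,
        percentile=percentile,
    )


def additive_r2_on_subset(space: GenotypeSpace, f: np.ndarray, subset: np.ndarray) -> float:
    """In-sample R^2 of an additive least-squares fit to a genotype subset."""
    subset = np.asarray(subset, dtype=np.int64)
    phi = space.interaction_basis([0, 1])[subset]
    y = np.asarray(f, float)[subset]
    beta, *_ = np.linalg.lstsq(phi, y, rcond=None)
    return _r2(y, phi @ beta)


def randomization_test_r2(
    space: GenotypeSpace,
    f: np.ndarray,
    subset: Sequence[int] | np.ndarray,
    n_rand: int = 1000,
    seed: int = 0,
    add_one: bool = False,
) -> tuple[float, float]:
    """Randomization test for the additive R^2 of a genotype region.

    Fits an additive model to the subset and to ``n_rand`` uniformly random
    subsets of the same size; the p-value is the fraction of random subsets
    whose R^2 is at least the observed one (``add_one`` applies the
    (k+1)/(n+1) correction).  Returns (observed R^2, p).
    """
    f = space._check_vector(f)
    subset = np.asarray(list(subset), dtype=np.int64)
    if subset.size < 2:
        raise ValueError("subset too small for an additive fit")
    observed = additive_r2_on_subset(space, f, subset)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_rand):
        rand = rng.choice(space.n_genotypes, size=subset.size, replace=False)
        if additive_r2_on_subset(space, f, rand) >= observed - 1e-12:
            count += 1
    p = (count + 1) / (n_rand + 1) if add_one else count / n_rand
    return observed, float(p)


def _model_predictions(
    name: str, obs: ObservationSet, seed: int
) -> np.ndarray:
    if name == "interpolation":
        return interp.interpolate(obs).f_hat
    if name == "interpolation_smoothed":
        return interp.smooth_in_sample(interp.interpolate(obs))
    if name == "additive":
        return fit_additive(obs).predict()
    if name == "l2_pairwise":
        return fit_l2(obs, max_order=2, seed=seed).predict()
    if name == "l2_threeway":
        return fit_l2(obs, max_order=3, seed=seed).predict()
    if name == "l1_threeway":
        return fit_l1_threeway(obs, seed=seed).predict()
    raise ValueError(f"unknown model {name!r}")


def benchmark_curve(
    space: GenotypeSpace,
    truth: np.ndarray,
    fractions: Sequence[float],
    models: Sequence[str],
    replicates: int = 3,
    seed: int = 0,
    noise_sigma: float = 0.0,
    scheme: str = "uniform_fraction",
    focal: int = 0,
) -> pd.DataFrame:
    """Train/evaluate each model at each training fraction, replicated.

    Returns a tidy table with one row per (fraction, model, replicate) and
    the full metric suite; replicate means and standard errors come from
    :func:`summarize_benchmark`.
    """
    truth = space._check_vector(truth)
    rows = []
    rng = np.random.default_rng(seed)
    for fraction in fractions:
        for rep in range(replicates):
            split_seed = int(rng.integers(2**31 - 1))
            observed = truth if noise_sigma == 0 else add_noise_seeded(
                truth, noise_sigma, split_seed + 1
            )
            obs, _ = _sample(space, observed, fraction, scheme, focal, split_seed)
            for model in models:
                pred = _model_predictions(model, obs, seed=split_seed)
                report = evaluate(space, pred, truth, obs.in_sample_mask())
                rows.append(
                    {
                        "fraction": fraction,
                        "model": model,
                        "replicate": rep,
                        "out_r2": report.out_r2,
                        "in_r2": report.in_r2,
                        "total_r2": report.total_r2,
                        "out_eps2": report.out_eps2,
                        "n_local_maxima": report.n_local_maxima,
                        "maxima_enrichment": report.maxima_enrichment,
                        "fdr": report.fdr,
                    }
                )
    return pd.DataFrame(rows)


def summarize_benchmark(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of each metric over replicates."""
    metrics = [c for c in table.columns if c not in ("fraction", "model", "replicate")]
    grouped = table.groupby(["fraction", "model"])[metrics]
    mean = grouped.mean().add_suffix("_mean")
    sem = grouped.sem().add_suffix("_sem")
    return mean.join(sem).reset_index()


# local aliases to avoid an import cycle with simulate
def add_noise_seeded(f: np.ndarray, sigma: float, seed: int) -> np.ndarray:
    from .simulate import add_noise

    return add_noise(f, sigma, seed)


def _sample(space, f, fraction, scheme, focal, seed):
    from .simulate import sample_observations

    return sample_observations(space, f, fraction, scheme=scheme, focal=focal, seed=seed)
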