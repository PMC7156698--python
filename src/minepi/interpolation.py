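"""Minimum-epistasis interpolation: complete a partially observed landscape.

Given phenotypes y on a genotype subset B, the reconstruction f_hat matches
the data exactly on B and assigns the unobserved genotypes I the values
minimizing the mean-squared epistatic coefficient  eps2_bar(f) = f' C f.
The minimizer solves the linear system

    C_II f_I = -C_IB y,

which exists and is unique exactly when the additive least-squares fit on B
is unique.  Equivalently f_hat is the solution of the boundary-value problem
(L^2 - alpha L) f = 0 on I with f = y on B, the discrete analog of
thin-plate-spline interpolation; at every unobserved genotype the solution
equals its average local additive prediction, f_hat(i) = (M f_hat)(i).

Because f_I is linear in y, i.i.d. observation noise of variance sigma^2
propagates to the predictions with covariance

    cov(f_I) = sigma^2 C_II^{-1} C_IB C_BI C_II^{-1}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .epistasis import apply_cost_operator, smoother_apply
from .spaces import GenotypeSpace


class IdentifiabilityError(ValueError):
    """The observed genotypes do not pin down a unique reconstruction."""


@dataclass
class ObservationSet:
    """Phenotype observations y on a genotype subset B.

    ``noise_variance`` (optional, per observation) is used only by
    :func:`regularized_reconstruction`; exact interpolation matches the
    data regardless of noise.
    """

    space: GenotypeSpace
    indices: np.ndarray
    y: np.ndarray
    noise_variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=float)
        if self.indices.ndim != 1 or self.indices.shape != self.y.shape:
            raise ValueError("indices and y must be 1-D arrays of equal length")
        if len(np.unique(self.indices)) != len(self.indices):
            raise ValueError("duplicate genotypes in observation set")
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= self.space.n_genotypes
        ):
            raise ValueError("observation outside the genotype space")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("non-finite phenotype values")
        if self.noise_variance is not None:
            self.noise_variance = np.asarray(self.noise_variance, dtype=float)
            if self.noise_variance.shape != self.y.shape:
                raise ValueError("noise_variance must align with y")
            if np.any(self.noise_variance < 0):
                raise ValueError("noise_variance must be non-negative")

    @property
    def n_observed(self) -> int:
        return len(self.indices)

    def in_sample_mask(self) -> np.ndarray:
        mask = np.zeros(self.space.n_genotypes, dtype=bool)
        mask[self.indices] = True
        return mask


@dataclass
class InterpolationResult:
    """A completed landscape with solver diagnostics."""

    space: GenotypeSpace
    f_hat: np.ndarray
    in_sample: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    prediction_variance: np.ndarray | None = None  # full length, 0 on B


@lru_cache(maxsize=4)
def cost_sparse(space: GenotypeSpace) -> sp.csr_matrix:
    """Sparse cost matrix C (nonzeros only at Hamming distance <= 2),
    assembled from the Laplacian via 2 s C = L^2 - alpha L."""
    L = space.laplacian_sparse()
    C = (L @ L - space.alpha * L) / (2.0 * space.n_faces)
    C.eliminate_zeros()
    return C.tocsr()


def check_identifiability(obs: ObservationSet) -> None:
    """The system C_II f_I = -C_IB y is solvable iff the additive
    least-squares fit on B is unique: the order-{0,1} design restricted
    to B must have full column rank."""
    space = obs.space
    k = 1 + space.l * (space.alpha - 1)
    if obs.n_observed < k:
        raise IdentifiabilityError(
            f"{obs.n_observed} observations cannot identify the {k} additive "
            "degrees of freedom; the reconstruction is not unique"
        )
    phi = space.interaction_basis([0, 1])[obs.indices]
    rank = np.linalg.matrix_rank(phi.T @ phi, hermitian=True)
    if rank < k:
        raise IdentifiabilityError(
            f"additive design on the observed genotypes has rank {rank} < {k}; "
            "the constrained minimum is not unique (e.g. some site/allele "
            "combination is unrepresented)"
        )


def interpolate(
    obs: ObservationSet,
    solver: str = "direct",
    rtol: float = 1e-8,
    max_iter: int | None = None,
) -> InterpolationResult:
    """Minimum-epistasis completion of the observed landscape.

    solver='direct' factorizes the sparse C_II block; 'iterative_linear'
    runs conjugate gradients with the matrix-free cost operator.
    """
    space = obs.space
    check_identifiability(obs)
    mask = obs.in_sample_mask()
    f_hat = np.zeros(space.n_genotypes)
    f_hat[obs.indices] = obs.y
    I = np.nonzero(~mask)[0]
    diagnostics: dict = {"solver": solver, "n_unobserved": len(I)}
    if len(I) == 0:
        diagnostics["residual"] = 0.0
        return InterpolationResult(space, f_hat, mask, diagnostics)

    # right-hand side -C_IB y via one matrix-free application
    rhs = -apply_cost_operator(space, f_hat)[I]
    if solver == "direct":
        C = cost_sparse(space)
        C_II = C[np.ix_(I, I)].tocsc()
        f_I = spla.spsolve(C_II, rhs)
        diagnostics["iterations"] = None
    elif solver == "iterative_linear":
        def matvec(x: np.ndarray) -> np.ndarray:
            full = np.zeros(space.n_genotypes)
            full[I] = x
            return apply_cost_operator(space, full)[I]

        op = spla.LinearOperator((len(I), len(I)), matvec=matvec)
        if max_iter is None:
            max_iter = max(100, 10 * int(math.isqrt(len(I))) + 10)
        iters = 0

        def cb(_):
            nonlocal iters
            iters += 1

        f_I, info = spla.cg(op, rhs, rtol=rtol, maxiter=max_iter, callback=cb)
        diagnostics["iterations"] = iters
        if info != 0:
            raise RuntimeError(
                f"conjugate gradient did not converge in {max_iter} iterations "
                f"(info={info})"
            )
    else:
        raise ValueError(f"unknown solver {solver!r}")

    f_hat[I] = f_I
    resid = np.linalg.norm(apply_cost_operator(space, f_hat)[I])
    diagnostics["residual"] = float(resid)
    return InterpolationResult(space, f_hat, mask, diagnostics)


def interpolate_iterative_smoothing(
    obs: ObservationSet,
    initial: np.ndarray | None = None,
    tol: float | None = None,
    max_iter: int = 100_000,
    damping: float | None = None,
) -> InterpolationResult:
    """Fixed-point route to the same reconstruction: repeatedly apply the
    smoother M, clamp the observed genotypes back to their data values,
    and relax toward the update with weight ``damping``.

    The interpolation solution is the unique fixed point.  The undamped
    update (damping=1) is a Jacobi sweep for the constrained system and
    can diverge, because M has eigenvalue 1 - k(k-1) alpha^2 / (2p) on
    order-k components, which drops below -1 for high orders.  The
    default damping (alpha-1)^2 / alpha^2 places the iteration matrix's
    spectrum inside [0, 1), guaranteeing convergence whenever the
    solution is identifiable.
    """
    space = obs.space
    check_identifiability(obs)
    mask = obs.in_sample_mask()
    if initial is None:
        f = np.full(space.n_genotypes, float(np.mean(obs.y)))
    else:
        f = np.array(initial, dtype=float)
        space._check_vector(f)
    f[obs.indices] = obs.y
    I = ~mask
    if damping is None:
        damping = (space.alpha - 1) ** 2 / space.alpha**2
    if not 0 < damping <= 1:
        raise ValueError("damping must lie in (0, 1]")
    if tol is None:
        span = float(np.ptp(obs.y)) or 1.0
        tol = 1e-9 * span
    if not I.any():
        return InterpolationResult(
            space, f, mask, {"solver": "iterative_smoothing", "iterations": 0, "residual": 0.0}
        )
    for it in range(1, max_iter + 1):
        f_new = (1.0 - damping) * f + damping * smoother_apply(space, f)
        f_new[obs.indices] = obs.y
        delta = float(np.max(np.abs(f_new[I] - f[I])))
        f = f_new
        if delta < tol:
            resid = float(np.linalg.norm(apply_cost_operator(space, f)[I]))
            return InterpolationResult(
                space, f, mask,
                {"solver": "iterative_smoothing", "iterations": it, "residual": resid},
            )
    raise RuntimeError(
        f"iterative smoothing did not converge in {max_iter} iterations "
        f"(last max change {delta:.3e}, tol {tol:.3e})"
    )


def prediction_covariance(
    obs: ObservationSet, sigma2: float, full: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Noise-induced variance of the out-of-sample predictions under
    homoscedastic observation noise of variance sigma2.

    Returns the variance vector over the unobserved genotypes (in index
    order); with ``full=True`` also the full covariance matrix.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    space = obs.space
    check_identifiability(obs)
    mask = obs.in_sample_mask()
    I = np.nonzero(~mask)[0]
    if len(I) == 0:
        return (np.zeros(0), np.zeros((0, 0))) if full else np.zeros(0)
    C = cost_sparse(space)
    C_II = C[np.ix_(I, I)].tocsc()
    C_IB = C[np.ix_(I, obs.indices)].toarray()
    A = spla.spsolve(sp.csc_matrix(C_II), C_IB)
    A = np.atleast_2d(np.asarray(A))
    var = sigma2 * np.einsum("ij,ij->i", A, A)
    var = np.maximum(var, 0.0)
    if full:
        return var, sigma2 * (A @ A.T)
    return var


def smooth_in_sample(result: InterpolationResult) -> np.ndarray:
    """Apply the smoother M to a completed landscape: out-of-sample
    predictions are unchanged, in-sample values are replaced by their
    average local additive prediction (noise filtering)."""
    return smoother_apply(result.space, result.f_hat)


def regularized_reconstruction(
    obs: ObservationSet,
    mix: float,
    use_noise_weights: bool = True,
) -> np.ndarray:
    """Convex-combination reconstruction between data fidelity and smoothness:

        minimize  (1 - mix) * weighted-MSE_B(f)  +  mix * eps2_bar(f).

    mix -> 1 recovers exact interpolation (and mix == 1 dispatches to it);
    mix -> 0 with full coverage returns the data unchanged.  Observation
    weights are 1/noise_variance when the observation set carries
    heteroscedastic variances and ``use_noise_weights`` is set.
    """
    if not 0 < mix <= 1:
        raise ValueError("mix must lie in (0, 1]")
    space = obs.space
    if mix == 1.0:
        return interpolate(obs).f_hat
    m = obs.n_observed
    if use_noise_weights and obs.noise_variance is not None:
        if np.any(obs.noise_variance == 0):
            raise ValueError("zero noise variance gives a degenerate weight; "
                             "use exact interpolation for noise-free rows")
        w = 1.0 / obs.noise_variance
    else:
        w = np.ones(m)
    C = cost_sparse(space)
    n = space.n_genotypes
    diag = np.zeros(n)
    diag[obs.indices] = (1.0 - mix) * w / m
    A = (mix * C + sp.diags(diag)).tocsc()
    b = np.zeros(n)
    b[obs.indices] = (1.0 - mix) * w * obs.y / m
    return spla.spsolve(A, b)
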