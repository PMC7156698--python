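"""Weak-mutation evolutionary dynamics and diffusion-style embedding.

Under weak mutation a population occupies a single genotype and hops to a
Hamming neighbor at each fixation event.  With phenotype f converted to
scaled fitness by a factor c, the continuous-time rate from i to a
neighbor j is proportional to the classical fixation rate

    Q(i, j) = (1 / (alpha - 1)) * S / (1 - exp(-S)),   S = c (f(j) - f(i)),

with time scaled so the total mutation rate per site is 1 (each specific
substitution is attempted at rate 1/(alpha-1)).  The chain is reversible
with stationary distribution pi proportional to exp(c f).

The conversion factor c is calibrated so that the stationary mean
phenotype equals the wild-type phenotype; since the stationary mean is
strictly increasing in c this is a one-dimensional root find.

For visualization, genotypes are embedded using the right eigenvectors of
Q for the eigenvalues closest to zero (excluding the stationary zero
mode), each scaled by 1/sqrt(|lambda|) — diffusion coordinates in units
of square-root expected neutral substitutions per site.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import brentq

from .spaces import GenotypeSpace


def stationary_distribution(f: np.ndarray, c: float) -> np.ndarray:
    """pi proportional to exp(c f), computed stably."""
    z = c * np.asarray(f, float)
    z -= z.max()
    w = np.exp(z)
    return w / w.sum()


def stationary_mean(f: np.ndarray, c: float) -> float:
    return float(stationary_distribution(f, c) @ np.asarray(f, float))


def calibrate_c(
    space: GenotypeSpace,
    f: np.ndarray,
    wild_type: int,
    tol: float = 1e-10,
    max_bracket: float = 1e6,
) -> float:
    """Conversion factor c with stationary mean phenotype = f(wild_type)."""
    f = space._check_vector(f)
    target = float(f[wild_type])
    if np.ptp(f) == 0:
        # degenerate: every c gives the same (constant) stationary mean
        return 0.0
    lo_val, hi_val = float(f.min()), float(f.max())
    if not lo_val < target < hi_val:
        raise ValueError(
            f"wild-type phenotype {target} is outside the open achievable range "
            f"({lo_val}, {hi_val}) of the stationary mean"
        )

    def g(c: float) -> float:
        return stationary_mean(f, c) - target

    if abs(g(0.0)) <= tol:
        return 0.0
    lo, hi = -1.0, 1.0
    while g(lo) > 0:
        lo *= 2.0
        if -lo > max_bracket:
            raise ValueError("no bracketing interval found for c (target too extreme)")
    while g(hi) < 0:
        hi *= 2.0
        if hi > max_bracket:
            raise ValueError("no bracketing interval found for c (target too extreme)")
    return float(brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200))


def _fixation_factor(S: np.ndarray) -> np.ndarray:
    """rho(S) = S / (1 - exp(-S)) with stable limits (rho(0) = 1)."""
    S = np.asarray(S, float)
    out = np.empty_like(S)
    small = np.abs(S) < 1e-8
    big_pos = S > 500
    big_neg = S < -500
    mid = ~(small | big_pos | big_neg)
    out[small] = 1.0 + S[small] / 2.0
    out[big_pos] = S[big_pos]
    out[big_neg] = -S[big_neg] * np.exp(S[big_neg])
    out[mid] = S[mid] / (-np.expm1(-S[mid]))
    return out


def rate_matrix(space: GenotypeSpace, f: np.ndarray, c: float) -> sp.csr_matrix:
    """Sparse generator Q of the weak-mutation chain on the landscape."""
    f = space._check_vector(f)
    A = space.adjacency_sparse().tocoo()
    S = c * (f[A.col] - f[A.row])
    rates = _fixation_factor(S) / (space.alpha - 1)
    Q = sp.coo_matrix((rates, (A.row, A.col)), shape=A.shape).tocsr()
    diag = -np.asarray(Q.sum(axis=1)).ravel()
    return (Q + sp.diags(diag)).tocsr()


def embed(
    space: GenotypeSpace,
    Q: sp.spmatrix,
    pi: np.ndarray,
    n_coords: int = 2,
    scale: str = "diffusion",
    degeneracy_rtol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Low-dimensional coordinates from the subleading spectrum of Q.

    Returns (coords, eigenvalues) with coords of shape (n_genotypes,
    n_coords).  Q is symmetrized by the stationary distribution, so the
    spectrum is real and non-positive; the n_coords eigenvalues closest to
    zero (excluding 0) supply right eigenvectors of Q, pi-normalized, with
    a deterministic sign (first entry of magnitude > 1e-12 positive) and,
    under the default diffusion scaling, multiplied by 1/sqrt(|lambda|).
    A warning is issued if the spectral cut falls inside a degenerate
    eigenvalue cluster (coordinates then depend on basis choice).
    """
    pi = np.asarray(pi, float)
    n = space.n_genotypes
    if Q.shape != (n, n) or pi.shape != (n,):
        raise ValueError("Q and pi must match the genotype space")
    root = np.sqrt(pi)
    Dh = sp.diags(root)
    Dih = sp.diags(1.0 / root)
    Ssym = (Dh @ Q @ Dih).tocsr()
    Ssym = (Ssym + Ssym.T) / 2.0
    k = n_coords + 1
    if n <= 2048:
        evals, evecs = np.linalg.eigh(Ssym.toarray())
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order[:k + 1]], evecs[:, order[:k + 1]]
    else:
        evals, evecs = spla.eigsh(Ssym, k=min(k + 1, n - 1), which="LA")
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
    # drop the zero mode (largest eigenvalue)
    lam = evals[1 : n_coords + 1]
    vecs = evecs[:, 1 : n_coords + 1]
    tail = evals[1 : n_coords + 2]  # selected eigenvalues plus the next one
    gaps = np.abs(np.diff(tail))
    if gaps.size and np.any(gaps <= degeneracy_rtol * np.maximum(np.abs(tail[1:]), 1e-300)):
        warnings.warn(
            "degenerate eigenvalues among the embedding coordinates: they are "
            "only defined up to rotation within the degenerate eigenspace",
            RuntimeWarning,
        )
    coords = np.empty((n, n_coords))
    for j in range(n_coords):
        r = vecs[:, j] / root  # right eigenvector of Q, pi-weighted unit norm
        nz = np.nonzero(np.abs(r) > 1e-12)[0]
        if nz.size and r[nz[0]] < 0:
            r = -r
        if scale == "diffusion":
            r = r / np.sqrt(max(abs(lam[j]), 1e-300))
        elif scale != "raw":
            raise ValueError("scale must be 'diffusion' or 'raw'")
        coords[:, j] = r
    return coords, lam
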