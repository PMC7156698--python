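"""Synthetic sequence-function landscapes and sampling schemes.

Two landscape families drive the package's benchmarks:

* **Global-epistasis (distance-profile) models** assign each genotype a
  phenotype that depends only on its Hamming distance ``d`` to a focal
  sequence.  The headline member is the *crater* model of transcription
  factor binding, where fitness peaks at an intermediate mismatch count
  because weak binders are also less likely to bind spuriously:

      f(d) = s_on / (1 + exp(eps (d - rho_on)))
           - s_on / (1 + exp(eps (d - rho_off))),

  with defaults eps = 1, rho_on = 6, rho_off = 1, s_on = 1 on a binary
  space of l = 16 sites.  Hamming-ball (threshold), quadratic and
  sinusoidal profiles round out the family.

* **Sparse interaction models** draw a coefficient for every allelic
  combination on every site subset (an all-order one-hot design with
  (alpha+1)^l columns), zero 90% of them at random, and sample the
  survivors from a standard normal.  The result has specific epistasis of
  all orders with sparse support.

Noise is additive i.i.d. Gaussian.  Sampling schemes mirror the benchmark
protocol: a uniformly random training fraction, optionally forcing at
least one held-out genotype in every distance class so the full distance
profile stays assessable.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .interpolation import ObservationSet
from .spaces import GenotypeSpace

CRATER_DEFAULTS = {"eps": 1.0, "rho_on": 6.0, "rho_off": 1.0, "s_on": 1.0}


def crater_profile(
    d: np.ndarray | float,
    eps: float = 1.0,
    rho_on: float = 6.0,
    rho_off: float = 1.0,
    s_on: float = 1.0,
) -> np.ndarray:
    """Crater fitness as a function of mismatch count d."""
    d = np.asarray(d, dtype=float)
    on = s_on / (1.0 + np.exp(eps * (d - rho_on)))
    off = s_on / (1.0 + np.exp(eps * (d - rho_off)))
    return on - off


def crater_landscape(
    space: GenotypeSpace,
    focal: int = 0,
    eps: float = 1.0,
    rho_on: float = 6.0,
    rho_off: float = 1.0,
    s_on: float = 1.0,
) -> np.ndarray:
    d = space.hamming_distances_from(focal)
    return crater_profile(d, eps=eps, rho_on=rho_on, rho_off=rho_off, s_on=s_on)


def distance_profile_landscape(
    space: GenotypeSpace,
    family: str,
    focal: int = 0,
    *,
    threshold: int | None = None,
    high: float = 1.0,
    low: float = 0.0,
    curvature: float = 1.0,
    optimum: float = 0.0,
    offset: float = 0.0,
    amplitude: float = 1.0,
    period: float = 4.0,
    phase: float = 0.0,
    **crater_params,
) -> np.ndarray:
    """Distance-profile (global epistasis) landscapes.

    family 'hamming_ball': f(d) = high for d <= threshold else low.
    family 'quadratic':    f(d) = curvature * (d - optimum)^2 + offset.
    family 'sinusoidal':   f(d) = amplitude * sin(2 pi d / period + phase).
    family 'crater':       the crater model (see :func:`crater_landscape`).
    """
    d = space.hamming_distances_from(focal).astype(float)
    if family == "crater":
        return crater_profile(d, **{**CRATER_DEFAULTS, **crater_params})
    if family == "hamming_ball":
        if threshold is None:
            threshold = space.l // 2
        return np.where(d <= threshold, high, low)
    if family == "quadratic":
        return curvature * (d - optimum) ** 2 + offset
    if family == "sinusoidal":
        return amplitude * np.sin(2.0 * np.pi * d / period + phase)
    raise ValueError(f"unknown distance-profile family {family!r}")


# ----------------------------------------------------------------------
# sparse all-order interaction model
# ----------------------------------------------------------------------

def n_interaction_terms(space: GenotypeSpace) -> int:
    """(alpha+1)^l: one coefficient per allelic combination on each site
    subset, summed over all subsets (sum_k C(l,k) alpha^k)."""
    return (space.alpha + 1) ** space.l


def one_hot_apply(space: GenotypeSpace, theta: np.ndarray) -> np.ndarray:
    """f = X theta without materializing the alpha^l x (alpha+1)^l design.

    theta is indexed in mixed radix base alpha+1 (site 0 most significant):
    digit 0 at a site means the site is outside the interacting subset,
    digit a in 1..alpha requires allele a-1.  A genotype picks up every
    coefficient whose required alleles it carries, which factorizes per
    site into the alpha x (alpha+1) membership matrix E with E[a, 0] = 1
    and E[a, a+1] = 1.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (n_interaction_terms(space),):
        raise ValueError(
            f"theta must have length (alpha+1)^l = {n_interaction_terms(space)}"
        )
    a = space.alpha
    E = np.zeros((a, a + 1))
    E[:, 0] = 1.0
    E[np.arange(a), np.arange(1, a + 1)] = 1.0
    t = theta.reshape((a + 1,) * space.l)
    for _ in range(space.l):
        # contract the trailing site axis; tensordot moves the new axis to
        # the front, so l applications restore site order
        t = np.tensordot(E, t, axes=(1, t.ndim - 1))
    return t.reshape(-1)


def theta_term_orders(space: GenotypeSpace) -> np.ndarray:
    """Interaction order (subset size) of each one-hot coefficient."""
    idx = np.arange(n_interaction_terms(space), dtype=np.int64)
    base = space.alpha + 1
    w = base ** np.arange(space.l - 1, -1, -1, dtype=np.int64)
    digits = (idx[:, None] // w[None, :]) % base
    return (digits > 0).sum(axis=1)


def sparse_interaction_landscape(
    space: GenotypeSpace,
    sparsity: float = 0.9,
    seed: int | np.random.Generator = 0,
    exact_fraction: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw theta (each entry zeroed with probability ``sparsity``,
    survivors standard normal) and return (landscape, theta).

    ``exact_fraction`` zeroes exactly round(sparsity * n_terms) entries
    without replacement instead of i.i.d. Bernoulli.
    """
    if not 0 <= sparsity <= 1:
        raise ValueError("sparsity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_terms = n_interaction_terms(space)
    theta = rng.standard_normal(n_terms)
    if exact_fraction:
        n_zero = round(sparsity * n_terms)
        zero_idx = rng.choice(n_terms, size=n_zero, replace=False)
        theta[zero_idx] = 0.0
    else:
        theta[rng.random(n_terms) < sparsity] = 0.0
    return one_hot_apply(space, theta), theta


# ----------------------------------------------------------------------
# noise and sampling
# ----------------------------------------------------------------------

def add_noise(
    f: np.ndarray, sigma: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Add i.i.d. Gaussian measurement noise of standard deviation sigma."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    f = np.asarray(f, dtype=float)
    if sigma == 0:
        return f.copy()
    rng = np.random.default_rng(seed)
    return f + sigma * rng.standard_normal(f.shape)


def sample_observations(
    space: GenotypeSpace,
    f: np.ndarray,
    fraction: float,
    scheme: str = "uniform_fraction",
    focal: int = 0,
    seed: int | np.random.Generator = 0,
) -> tuple[ObservationSet, np.ndarray]:
    """Split the landscape into a training ObservationSet and held-out set.

    'uniform_fraction' samples exactly round(fraction * alpha^l) training
    genotypes uniformly without replacement.  'per_distance_class'
    additionally guarantees at least one held-out genotype in every
    distance class around ``focal`` (so model fits can be inspected at
    every distance).
    """
    f = space._check_vector(f)
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = space.n_genotypes
    m = round(fraction * n)
    if m == 0 or m == n:
        raise ValueError(
            f"fraction {fraction} leaves an empty training or test set for n={n}"
        )
    rng = np.random.default_rng(seed)
    train = rng.choice(n, size=m, replace=False)
    if scheme == "per_distance_class":
        in_train = np.zeros(n, dtype=bool)
        in_train[train] = True
        dist = space.hamming_distances_from(focal)
        for d in range(space.l + 1):
            members = np.nonzero(dist == d)[0]
            if members.size and in_train[members].all():
                evict = rng.choice(members)
                in_train[evict] = False
        train = np.nonzero(in_train)[0]
    elif scheme != "uniform_fraction":
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    train = np.sort(train)
    held_out = np.setdiff1d(np.arange(n), train, assume_unique=True)
    obs = ObservationSet(space=space, indices=train, y=f[train])
    return obs, held_out
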