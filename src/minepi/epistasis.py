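"""Epistasis functionals on complete landscapes.

The local epistatic coefficient of a face (wild type ab, single mutants
Ab and aB, double mutant AB) is

    eps = (f_AB - f_aB) - (f_Ab - f_ab),

the change in the effect of one mutation across the two backgrounds
defined by the other.  Averaging eps^2 over all s faces of the Hamming
graph gives the mean-squared epistasis  eps2_bar(f) = f' C f,  a positive
semi-definite quadratic form whose coefficients depend only on Hamming
distance and whose null space is exactly the additive (order <= 1)
landscapes.  C is tied to the graph Laplacian by  2 s C = L^2 - alpha L,
which lets every functional here be evaluated matrix-free.

The smoother  M = I - (s/p) C  replaces each genotype's value by the mean
of the p local additive predictions obtained from the faces through it.
"""

from __future__ import annotations

import itertools
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .spaces import Face, GenotypeSpace


def face_epistasis(f: np.ndarray, face: Face) -> float:
    """Epistatic coefficient eps of a single face; sign depends on the
    labeling of the two mutations, eps**2 does not."""
    f = np.asarray(f, dtype=float)
    return float((f[face.dm] - f[face.m2]) - (f[face.m1] - f[face.wt]))


def cost_coefficient(space: GenotypeSpace, d: int) -> float:
    """Unnormalized cost-form coefficient c(i,j) for Hamming distance d."""
    l, a = space.l, space.alpha
    if d == 0:
        return l * (l - 1) * (a - 1) ** 2 / 2.0
    if d == 1:
        return -(l - 1) * (a - 1)
    if d == 2:
        return 1.0
    return 0.0


def apply_cost_operator(space: GenotypeSpace, f: np.ndarray) -> np.ndarray:
    """Matrix-free C f via the identity 2 s C = L^2 - alpha L."""
    f = space._check_vector(f)
    Lf = space.laplacian_apply(f)
    return (space.laplacian_apply(Lf) - space.alpha * Lf) / (2.0 * space.n_faces)


def mean_squared_epistasis(space: GenotypeSpace, f: np.ndarray) -> float:
    """eps2_bar(f) = f' C f, the average of eps^2 over all s faces."""
    f = space._check_vector(f)
    return float(f @ apply_cost_operator(space, f))


def iter_face_index_batches(
    space: GenotypeSpace,
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    """Vectorized enumeration of all s faces.

    Yields one batch of index arrays (wt, m1, m2, dm) per combination of
    site pair and unordered allele pairs; each batch has alpha^(l-2)
    faces (one per background at the remaining sites).
    """
    a = space.alpha
    for s1, s2 in itertools.combinations(range(space.l), 2):
        w1, w2 = int(space._weights[s1]), int(space._weights[s2])
        bg = space._backgrounds(s1, s2)
        for x, y in itertools.combinations(range(a), 2):
            for u, v in itertools.combinations(range(a), 2):
                wt = bg + x * w1 + u * w2
                yield (wt, wt + (y - x) * w1, wt + (v - u) * w2,
                       wt + (y - x) * w1 + (v - u) * w2)


def mean_squared_epistasis_faces(space: GenotypeSpace, f: np.ndarray) -> float:
    """Brute-force eps2_bar by explicit face enumeration (test oracle for
    the operator route; identical value, O(s) work)."""
    f = space._check_vector(f)
    total = 0.0
    for wt, m1, m2, dm in iter_face_index_batches(space):
        eps = (f[dm] - f[m2]) - (f[m1] - f[wt])
        total += float(eps @ eps)
    return total / space.n_faces


class SubsetEpistasis(NamedTuple):
    """Mean of eps^2 over faces fully contained in a genotype subset.

    ``value`` is NaN when the subset spans no complete face; check
    ``n_faces`` before using it.
    """

    value: float
    n_faces: int


def mean_squared_epistasis_subset(
    space: GenotypeSpace, f: np.ndarray, genotype_subset: Sequence[int] | np.ndarray
) -> SubsetEpistasis:
    """Average eps^2 over faces whose four genotypes all lie in the subset."""
    f = space._check_vector(f)
    mask = np.zeros(space.n_genotypes, dtype=bool)
    mask[np.asarray(list(genotype_subset), dtype=np.int64)] = True
    total, count = 0.0, 0
    for wt, m1, m2, dm in iter_face_index_batches(space):
        keep = mask[wt] & mask[m1] & mask[m2] & mask[dm]
        if not keep.any():
            continue
        eps = (f[dm[keep]] - f[m2[keep]]) - (f[m1[keep]] - f[wt[keep]])
        total += float(eps @ eps)
        count += int(keep.sum())
    if count == 0:
        return SubsetEpistasis(float("nan"), 0)
    return SubsetEpistasis(total / count, count)


def smoother_apply(space: GenotypeSpace, f: np.ndarray) -> np.ndarray:
    """M f with M = I - (s/p) C: each value becomes the mean of the p local
    additive predictions through that genotype."""
    f = space._check_vector(f)
    return f - (space.n_faces / space.faces_per_genotype) * apply_cost_operator(space, f)


def distance_class_means(
    space: GenotypeSpace, f: np.ndarray, i: int, ks: Sequence[int] = (1, 2)
) -> tuple[float, ...]:
    """Mean of f over genotypes at Hamming distance k from i, for each k.

    The smoother satisfies (M f)(i) = 2 d1(i) - d2(i), a discrete
    Taylor-like correction of the nearest-neighbor mean.
    """
    f = space._check_vector(f)
    dist = space.hamming_distances_from(i)
    out = []
    for k in ks:
        if k > space.l:
            raise ValueError(f"distance class {k} undefined for l={space.l}")
        sel = dist == k
        out.append(float(f[sel].mean()))
    return tuple(out)


def _neighbor_max(space: GenotypeSpace, f: np.ndarray) -> np.ndarray:
    """Max of f over the Hamming neighbors of each genotype, vectorized."""
    t = f.reshape((space.alpha,) * space.l)
    nmax = np.full_like(t, -np.inf)
    arange = np.arange(space.alpha)
    for axis in range(space.l):
        tm = np.moveaxis(t, axis, 0)
        srt = np.sort(tm, axis=0)
        m1, m2 = srt[-1], srt[-2]
        am = np.argmax(tm, axis=0)
        shape = (space.alpha,) + (1,) * (space.l - 1)
        per_digit = np.where(am[None, ...] == arange.reshape(shape), m2[None, ...], m1[None, ...])
        nmax = np.maximum(nmax, np.moveaxis(per_digit, 0, axis))
    return nmax.reshape(-1)


def local_maxima(
    space: GenotypeSpace,
    f: np.ndarray,
    tie_policy: str = "strict",
    tolerance: float = 0.0,
) -> np.ndarray:
    """Indices of local maxima of the landscape.

    strict: f(i) > f(j) + tolerance for every neighbor j.
    weak:   f(i) >= f(j) - tolerance for every neighbor j (plateau
            genotypes count; a constant landscape is all weak maxima).
    """
    f = space._check_vector(f)
    nmax = _neighbor_max(space, f)
    if tie_policy == "strict":
        hits = f > nmax + tolerance
    elif tie_policy == "weak":
        hits = f >= nmax - tolerance
    else:
        raise ValueError(f"tie_policy must be 'strict' or 'weak', got {tie_policy!r}")
    return np.nonzero(hits)[0]
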