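"""Hamming-graph combinatorics for complete sequence spaces.

A sequence space with ``l`` sites and ``alpha`` alleles per site is the
Hamming graph on ``alpha**l`` genotypes, with an edge between any two
genotypes differing at exactly one site.  Every pair of mutations at two
distinct sites, applied on a shared background, spans a *face*: a 4-cycle
(wild type, two single mutants, double mutant).  All epistasis functionals
in this package are built from faces, the graph Laplacian, and its
interaction-order eigenspaces.

Genotypes are indexed by a big-endian mixed-radix code: the leftmost site
is the most significant digit, so ``"ba"`` over the alphabet ``["a", "b"]``
has index ``1 * 2 + 0 = 2``.  This convention is fixed across the package.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import scipy.sparse as sp

DEFAULT_GENOTYPE_CAP = 2**20
DEFAULT_DENSE_MATRIX_CAP = 2**14


class Face(NamedTuple):
    """A 4-genotype face: wild type, the two single mutants, the double mutant."""

    wt: int
    m1: int
    m2: int
    dm: int


@dataclass(frozen=True)
class GenotypeSpace:
    """The complete combinatorial space of ``alpha**l`` genotypes.

    Parameters
    ----------
    l : int
        Number of sites (>= 1).
    alpha : int
        Number of alleles per site (>= 2), shared across sites.
    alphabet : tuple of str
        Ordered allele symbols; allele ``k`` at a site is ``alphabet[k]``.
    """

    l: int
    alpha: int
    alphabet: tuple[str, ...]
    genotype_cap: int = DEFAULT_GENOTYPE_CAP
    dense_matrix_cap: int = DEFAULT_DENSE_MATRIX_CAP
    # site weights alpha^(l-1-s), cached for index arithmetic
    _weights: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        w = self.alpha ** np.arange(self.l - 1, -1, -1, dtype=np.int64)
        object.__setattr__(self, "_weights", w)

    @property
    def n_genotypes(self) -> int:
        return self.alpha**self.l

    @property
    def n_faces(self) -> int:
        """Total number of faces s = C(l,2) C(alpha,2)^2 alpha^(l-2)."""
        l, a = self.l, self.alpha
        if l < 2:
            return 0
        return math.comb(l, 2) * math.comb(a, 2) ** 2 * a ** (l - 2)

    @property
    def faces_per_genotype(self) -> int:
        """Faces through any genotype in the wild-type role, p = C(l,2)(alpha-1)^2."""
        return math.comb(self.l, 2) * (self.alpha - 1) ** 2

    @property
    def degree(self) -> int:
        """Number of Hamming neighbors of every genotype, l(alpha-1)."""
        return self.l * (self.alpha - 1)

    # ------------------------------------------------------------------
    # encoding
    # ------------------------------------------------------------------

    def seq_to_index(self, sequence: str | Sequence[str]) -> int:
        if len(sequence) != self.l:
            raise ValueError(
                f"sequence {sequence!r} has length {len(sequence)}, expected l={self.l}"
            )
        idx = 0
        lookup = {sym: k for k, sym in enumerate(self.alphabet)}
        for pos, sym in enumerate(sequence):
            try:
                digit = lookup[sym]
            except KeyError:
                raise ValueError(
                    f"unknown symbol {sym!r} at position {pos} of {sequence!r}; "
                    f"alphabet is {''.join(self.alphabet)}"
                ) from None
            idx = idx * self.alpha + digit
        return idx

    def index_to_seq(self, i: int) -> str:
        self._check_index(i)
        out = []
        for w in self._weights:
            d, i = divmod(i, int(w))
            out.append(self.alphabet[d])
        return "".join(out)

    def digits(self, i: int) -> np.ndarray:
        """Mixed-radix digits of ``i``, site 0 first (most significant)."""
        self._check_index(i)
        return (i // self._weights) % self.alpha

    def digits_matrix(self) -> np.ndarray:
        """(n_genotypes, l) matrix of allele digits for every genotype."""
        idx = np.arange(self.n_genotypes, dtype=np.int64)
        return (idx[:, None] // self._weights[None, :]) % self.alpha

    def hamming_distances_from(self, i: int) -> np.ndarray:
        """Hamming distance from genotype ``i`` to every genotype."""
        return (self.digits_matrix() != self.digits(i)[None, :]).sum(axis=1)

    def _check_index(self, i: int) -> None:
        if not 0 <= i < self.n_genotypes:
            raise IndexError(f"genotype index {i} outside [0, {self.n_genotypes})")

    def _check_vector(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        if f.shape != (self.n_genotypes,):
            raise ValueError(
                f"landscape vector has shape {f.shape}, expected ({self.n_genotypes},)"
            )
        return f

    # ------------------------------------------------------------------
    # adjacency
    # ------------------------------------------------------------------

    def neighbors(self, i: int) -> list[int]:
        """Genotypes at Hamming distance 1, site-major then allele order."""
        d = self.digits(i)
        out = []
        for s in range(self.l):
            w = int(self._weights[s])
            base = i - int(d[s]) * w
            for a in range(self.alpha):
                if a != d[s]:
                    out.append(base + a * w)
        return out

    def faces_through(self, i: int) -> Iterator[Face]:
        """All p faces with ``i`` in the wild-type role.

        Canonical order: lexicographic by site pair, then by the two
        alternative alleles (allele at the first site varying slowest).
        """
        d = self.digits(i)
        for s1, s2 in itertools.combinations(range(self.l), 2):
            w1, w2 = int(self._weights[s1]), int(self._weights[s2])
            for a1 in range(self.alpha):
                if a1 == d[s1]:
                    continue
                j1 = i + (a1 - int(d[s1])) * w1
                for a2 in range(self.alpha):
                    if a2 == d[s2]:
                        continue
                    j2 = i + (a2 - int(d[s2])) * w2
                    yield Face(i, j1, j2, j1 + (a2 - int(d[s2])) * w2)

    def iter_faces(self) -> Iterator[Face]:
        """Each of the s faces exactly once, in canonical order.

        The wild-type role is assigned to the face member carrying the
        lower allele at both mutated sites.
        """
        for s1, s2 in itertools.combinations(range(self.l), 2):
            w1, w2 = int(self._weights[s1]), int(self._weights[s2])
            for a, b in itertools.combinations(range(self.alpha), 2):
                for c, e in itertools.combinations(range(self.alpha), 2):
                    for bg in self._backgrounds(s1, s2):
                        wt = bg + a * w1 + c * w2
                        yield Face(wt, bg + b * w1 + c * w2, bg + a * w1 + e * w2, bg + b * w1 + e * w2)

    def _backgrounds(self, s1: int, s2: int) -> np.ndarray:
        """Indices with digit 0 at sites s1 and s2, all combinations elsewhere."""
        other = [s for s in range(self.l) if s not in (s1, s2)]
        if not other:
            return np.array([0], dtype=np.int64)
        idx = np.zeros(1, dtype=np.int64)
        for s in other:
            w = self._weights[s]
            idx = (idx[:, None] + w * np.arange(self.alpha, dtype=np.int64)[None, :]).ravel()
        return idx

    # ------------------------------------------------------------------
    # operators
    # ------------------------------------------------------------------

    def adjacency_apply(self, f: np.ndarray) -> np.ndarray:
        """Matrix-free neighbor sum (Af)(i) = sum over Hamming neighbors of f."""
        f = self._check_vector(f)
        t = f.reshape((self.alpha,) * self.l)
        out = np.zeros_like(t)
        for axis in range(self.l):
            out += t.sum(axis=axis, keepdims=True) - t
        return out.reshape(-1)

    def laplacian_apply(self, f: np.ndarray) -> np.ndarray:
        """(Lf)(i) = l(alpha-1) f(i) - sum of f over Hamming neighbors."""
        f = self._check_vector(f)
        return self.degree * f - self.adjacency_apply(f)

    def adjacency_sparse(self) -> sp.csr_matrix:
        """Sparse adjacency matrix of the Hamming graph."""
        n = self.n_genotypes
        D = self.digits_matrix()
        rows, cols = [], []
        idx = np.arange(n, dtype=np.int64)
        for s in range(self.l):
            w = int(self._weights[s])
            base = idx - D[:, s] * w
            for a in range(self.alpha):
                j = base + a * w
                keep = D[:, s] != a
                rows.append(idx[keep])
                cols.append(j[keep])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        return sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )

    def laplacian_sparse(self) -> sp.csr_matrix:
        n = self.n_genotypes
        return sp.identity(n, format="csr") * self.degree - self.adjacency_sparse()

    # ------------------------------------------------------------------
    # interaction eigenbasis
    # ------------------------------------------------------------------

    def site_contrasts(self) -> np.ndarray:
        """Orthonormal per-site basis: column 0 constant, columns 1..alpha-1
        Helmert contrasts (orthogonal to the constant)."""
        a = self.alpha
        V = np.zeros((a, a))
        V[:, 0] = 1.0 / math.sqrt(a)
        for k in range(1, a):
            V[:k, k] = 1.0 / math.sqrt(k * (k + 1))
            V[k, k] = -k / math.sqrt(k * (k + 1))
        return V

    def interaction_basis(self, orders: Sequence[int]) -> np.ndarray:
        """Orthonormal columns spanning the requested interaction-order
        eigenspaces of the graph Laplacian.

        Order-k columns are eigenvectors of L with eigenvalue ``k * alpha``;
        the order-k block has dimension C(l,k)(alpha-1)^k.  Columns are tensor
        products of per-site Helmert contrasts (sites outside the interacting
        subset carry the normalized constant).
        """
        orders = sorted(set(int(k) for k in orders))
        if orders and (orders[0] < 0 or orders[-1] > self.l):
            raise ValueError(f"orders must lie in [0, {self.l}], got {orders}")
        n = self.n_genotypes
        n_cols = sum(
            math.comb(self.l, k) * (self.alpha - 1) ** k for k in orders
        )
        if n * n_cols > self.genotype_cap * 64:
            raise ValueError(
                f"dense basis of shape ({n}, {n_cols}) exceeds the size cap; "
                "raise genotype_cap to override"
            )
        V = self.site_contrasts()
        const = V[:, 0]
        cols = np.empty((n, n_cols))
        j = 0
        for k in orders:
            for subset in itertools.combinations(range(self.l), k):
                for contrasts in itertools.product(range(1, self.alpha), repeat=k):
                    vecs = []
                    it = dict(zip(subset, contrasts))
                    for s in range(self.l):
                        vecs.append(V[:, it[s]] if s in it else const)
                    col = vecs[0]
                    for v in vecs[1:]:
                        col = np.kron(col, v)
                    cols[:, j] = col
                    j += 1
        return cols


NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical one-letter codes


def default_alphabet(alpha: int) -> tuple[str, ...]:
    if alpha == 4:
        return tuple(NUCLEOTIDES)
    if alpha == 20:
        return tuple(AMINO_ACIDS)
    if alpha <= 26:
        return tuple("abcdefghijklmnopqrstuvwxyz"[:alpha])
    return tuple(str(k) for k in range(alpha))


def make_space(
    l: int,
    alpha: int,
    alphabet: Sequence[str] | None = None,
    genotype_cap: int = DEFAULT_GENOTYPE_CAP,
) -> GenotypeSpace:
    """Construct the complete space of ``alpha**l`` genotypes.

    Raises
    ------
    ValueError
        If parameters are out of range, the alphabet does not have exactly
        ``alpha`` distinct symbols, or the space exceeds ``genotype_cap``
        (dense per-genotype vectors would not be workable above it).
    """
    if l < 1:
        raise ValueError(f"l must be a positive integer, got {l}")
    if alpha < 2:
        raise ValueError(f"alpha must be >= 2, got {alpha}")
    n = alpha**l  # exact integer arithmetic, no overflow possible in Python
    if n > genotype_cap:
        raise ValueError(
            f"space of alpha^l = {n} genotypes exceeds the cap of {genotype_cap}; "
            "pass a larger genotype_cap if you really want dense operations at this size"
        )
    if alphabet is None:
        alphabet = default_alphabet(alpha)
    alphabet = tuple(str(s) for s in alphabet)
    if len(alphabet) != alpha or len(set(alphabet)) != alpha:
        raise ValueError(
            f"alphabet must contain exactly alpha={alpha} distinct symbols, got {alphabet}"
        )
    return GenotypeSpace(l=l, alpha=alpha, alphabet=alphabet, genotype_cap=genotype_cap)
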