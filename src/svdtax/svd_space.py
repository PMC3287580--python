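"""Rank-k SVD reduction of the trigram matrix and Euclidean species distances.

The trigram matrix A (8000 x n) is factorized A = U diag(sigma) V^T.  The
reduced species representation keeps the k strongest singular directions:

    D_k = diag(sigma[:k]) @ Vt[:k]        (k coordinates per species)

the latent-semantic-indexing document representation.  Because U is
orthonormal, distances between D_r columns at full numerical rank r equal
distances between the raw columns of A; truncating k < r discards the
weakest directions — the "noise" whose removal is the method's point — and
can only shrink pairwise distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform

from .species_io import ValidationError
from .trigram import TrigramMatrix


class ParameterError(ValueError):
    """A tuning parameter outside its valid range."""


@dataclass(frozen=True)
class SvdFactors:
    """Thin SVD of A: A = U @ diag(sigma) @ Vt, sigma descending."""

    U: np.ndarray          # (m, min(m, n))
    sigma: np.ndarray      # (min(m, n),) non-increasing, >= 0
    Vt: np.ndarray         # (min(m, n), n)
    species_order: tuple[str, ...]

    @property
    def rank(self) -> int:
        """Numerical rank: singular values above 1e-10 * sigma[0]."""
        if self.sigma.size == 0 or self.sigma[0] == 0:
            return 0
        return int(np.sum(self.sigma > 1e-10 * self.sigma[0]))


@dataclass(frozen=True)
class ReducedSpace:
    """Species coordinates in the rank-k latent space (columns of Dk)."""

    k: int
    Dk: np.ndarray         # (k, n)
    species_order: tuple[str, ...]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric Euclidean distances between species in a reduced space."""

    values: np.ndarray     # (n, n), zero diagonal
    k_used: int
    species_order: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.species_order)

    def max_distance(self) -> float:
        return float(self.values.max())


def decompose(A: TrigramMatrix, normalize: bool = False) -> SvdFactors:
    """Thin SVD of the trigram matrix (optionally L1-normalized columns)."""
    M = A.normalized() if normalize else A.counts.astype(float)
    if not np.any(M):
        raise ValidationError("all-zero trigram matrix: nothing to decompose")
    if M.shape[1] < 2:
        raise ValidationError("need at least 2 species to decompose")
    U, sigma, Vt = scipy.linalg.svd(M, full_matrices=False)
    return SvdFactors(U, sigma, Vt, A.species_order)


def reduce(factors: SvdFactors, k: int) -> ReducedSpace:
    """Keep the k strongest singular directions: Dk = diag(sigma[:k]) Vt[:k]."""
    r = factors.rank
    if not 1 <= k <= r:
        raise ParameterError(f"k={k} outside valid range [1, {r}]")
    Dk = factors.sigma[:k, None] * factors.Vt[:k]
    return ReducedSpace(k, Dk, factors.species_order)


def distances(space: ReducedSpace) -> DistanceMatrix:
    """Pairwise Euclidean distances between species columns of Dk."""
    vals = squareform(pdist(space.Dk.T, metric="euclidean"))
    return DistanceMatrix(vals, space.k, space.species_order)


def sigma_table(factors: SvdFactors) -> str:
    """Singular-value spectrum as TSV (index, sigma) for scree inspection."""
    lines = ["index\tsigma"]
    lines += [f"{i + 1}\t{s:.10g}" for i, s in enumerate(factors.sigma)]
    return "\n".join(lines) + "\n"
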