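"""ASAP ("As Simple As Possible") threshold agglomerative clustering.

ASAP resembles single linkage stripped to its bones: take a pivot species,
sweep up every remaining species closer than a threshold d, remove the new
cluster from the matrix, repeat.  Merged clusters are never re-inserted
into the distance matrix, so a run is a single pass.  Its two boundary laws
anchor the threshold search: d = 0 yields n singletons (strict inequality)
and any d above the maximum pairwise distance yields one cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .svd_space import DistanceMatrix


@dataclass(frozen=True)
class Partition:
    """Disjoint clusters covering every species, with clustering provenance."""

    clusters: tuple[frozenset[str], ...]
    k_used: int
    d: float
    pivot_order: str  # "fixed" or "seed=<int>"

    @property
    def c(self) -> int:
        return len(self.clusters)

    @property
    def n_singletons(self) -> int:
        return sum(1 for cl in self.clusters if len(cl) == 1)

    def member_index(self) -> dict[str, int]:
        return {sid: i for i, cl in enumerate(self.clusters) for sid in cl}


def _pivot_sequence(n: int, pivot_order: str | int) -> np.ndarray:
    if pivot_order == "fixed":
        return np.arange(n)
    rng = np.random.default_rng(int(pivot_order))
    return rng.permutation(n)


def asap_cluster(
    matrix: DistanceMatrix, d: float, pivot_order: str | int = "fixed"
) -> Partition:
    """Single-pass threshold clustering at distance ``d``.

    ``pivot_order="fixed"`` uses the matrix's species order (the reference
    pipeline orders species deterministically, so the first remaining column
    is the first alphabetically remaining species); an integer seeds a
    random pivot permutation.
    """
    if d < 0:
        raise ValueError("threshold d must be non-negative")
    n = matrix.n
    order = _pivot_sequence(n, pivot_order)
    remaining = np.ones(n, dtype=bool)
    clusters: list[frozenset[str]] = []
    ids = matrix.species_order
    for pivot in order:
        if not remaining[pivot]:
            continue
        members = remaining & (matrix.values[pivot] < d)
        members[pivot] = True
        clusters.append(frozenset(ids[i] for i in np.nonzero(members)[0]))
        remaining &= ~members
    tag = "fixed" if pivot_order == "fixed" else f"seed={int(pivot_order)}"
    return Partition(tuple(clusters), matrix.k_used, float(d), tag)


def threshold_grid(matrix: DistanceMatrix) -> np.ndarray:
    """Every threshold at which ASAP's behaviour can change, plus the endpoints.

    ASAP's decisions depend only on comparisons ``value < d``, so the cluster
    count is constant between consecutive distinct matrix values; midpoints
    of consecutive sorted unique values (the diagonal contributes 0), plus 0
    itself and a point above the maximum, exhaust all distinct outcomes.
    """
    uniq = np.unique(matrix.values)
    grid = [0.0]
    if uniq.size > 1:
        grid.extend((uniq[:-1] + uniq[1:]) / 2.0)
    top = uniq[-1]
    eps = max(1e-9, 1e-9 * top)
    grid.append(float(top + eps))
    return np.asarray(grid)


def cluster_count_profile(
    matrix: DistanceMatrix, pivot_order: str | int = "fixed"
) -> dict[float, int]:
    """Map each grid threshold to the cluster count ASAP produces there.

    Always contains count n at threshold 0 and count 1 above the maximum
    distance.
    """
    return {
        float(d): asap_cluster(matrix, float(d), pivot_order).c
        for d in threshold_grid(matrix)
    }


def profile_with_stability(
    matrix: DistanceMatrix, pivot_order: str | int = "fixed"
) -> list[tuple[float, int, float]]:
    """(threshold, cluster count, width of its constant-count interval).

    Each grid threshold represents the open interval between the two matrix
    values it bisects; the interval width measures how far d can move before
    the clustering changes, i.e. the partition's stability to perturbation.
    The interval above the maximum distance is unbounded (width inf).
    """
    uniq = np.unique(matrix.values)
    grid = threshold_grid(matrix)
    widths = []
    if uniq.size > 1:
        widths.append(float(uniq[1] - uniq[0]))          # [0, smallest positive)
        widths.extend(float(w) for w in (uniq[1:] - uniq[:-1]))
    else:
        widths.append(float("inf"))
    widths.append(float("inf"))                          # above the maximum
    widths = widths[: len(grid)]
    return [
        (float(d), asap_cluster(matrix, float(d), pivot_order).c, w)
        for d, w in zip(grid, widths)
    ]


def profile_table(profile: dict[float, int]) -> str:
    lines = ["threshold\tcluster_count"]
    lines += [f"{d:.10g}\t{c}" for d, c in sorted(profile.items())]
    return "\n".join(lines) + "\n"
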