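"""Reference Lloyd k-means and the rank-comparison harness.

A deliberately small, seeded k-means over the columns of a reduced space,
so the algorithm-comparison table (threshold clustering vs. centroid
clustering, reduced rank vs. full rank) runs self-contained.  Externally
produced assignments (from other clustering packages) can be imported as
TSV and scored with the same Linnaean statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .asap import Partition, asap_cluster, cluster_count_profile
from .linnaean import quality_report, report_row
from .svd_space import DistanceMatrix, ParameterError, ReducedSpace, distances


@dataclass(frozen=True)
class KMeansResult:
    assignment: dict[str, int]
    centroids: np.ndarray      # (c, k)
    n_iter: int
    inertia: float

    def partition(self, k_used: int) -> Partition:
        clusters: dict[int, set[str]] = {}
        for sid, c in self.assignment.items():
            clusters.setdefault(c, set()).add(sid)
        return Partition(
            tuple(frozenset(clusters[i]) for i in sorted(clusters)),
            k_used, float("nan"), "kmeans",
        )


def kmeans(space: ReducedSpace, c: int, seed: int,
           max_iter: int = 300, tol: float = 1e-6) -> KMeansResult:
    """Seeded Lloyd iterations over the species columns of Dk.

    Initial centroids are c distinct species columns drawn uniformly at
    random; empty clusters are re-seeded from the point farthest from its
    centroid; iteration stops when the largest centroid shift drops below
    ``tol``.  Deterministic for a fixed seed; inertia never increases.
    """
    X = space.Dk.T  # (n, k)
    n = X.shape[0]
    if not 1 <= c <= n:
        raise ParameterError(f"c={c} outside [1, {n}]")
    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n, size=c, replace=False)].copy()

    prev_inertia = np.inf
    inertia = np.inf
    labels = np.zeros(n, dtype=int)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        # re-seed empty clusters from the currently worst-fitted point
        for j in range(c):
            if not np.any(labels == j):
                far = int(d2[np.arange(n), labels].argmax())
                labels[far] = j
                d2[far, :] = np.inf
        new_centroids = np.stack([X[labels == j].mean(axis=0) for j in range(c)])
        shift = float(np.abs(new_centroids - centroids).max())
        centroids = new_centroids
        # inertia measured post-update, where Lloyd (with re-seeding) is monotone
        d2c = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        inertia = float(d2c[np.arange(n), labels].sum())
        assert inertia <= prev_inertia + 1e-9, "inertia increased"
        prev_inertia = inertia
        if shift < tol:
            break
    assignment = {sid: int(labels[i]) for i, sid in enumerate(space.species_order)}
    return KMeansResult(assignment, centroids, n_iter, inertia)


def best_of_seeds(space: ReducedSpace, c: int, seeds: Sequence[int]) -> KMeansResult:
    """Lowest-inertia result over several initialization seeds."""
    results = [kmeans(space, c, s) for s in seeds]
    return min(results, key=lambda r: r.inertia)


def _asap_at_count(matrix: DistanceMatrix, c: int) -> Partition | None:
    profile = cluster_count_profile(matrix)
    realizing = [d for d, count in profile.items() if count == c]
    if not realizing:
        return None
    return asap_cluster(matrix, max(realizing))


def compare_algorithms(
    space_k: ReducedSpace,
    space_full: ReducedSpace,
    c: int,
    taxonomy: Mapping[str, Sequence[str]],
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
) -> pd.DataFrame:
    """Score ASAP and k-means on a reduced and a full-rank space at c clusters.

    One row per (algorithm, rank); reduced-rank rows carry the quality gain
    100*(Lcq_reduced/Lcq_full - 1).  An ASAP row is absent when no threshold
    realizes exactly c clusters on its space.
    """
    if space_k.species_order != space_full.species_order:
        raise ParameterError("spaces must cover the same species in the same order")
    rows = []
    lcq_by_alg: dict[str, dict[str, float | None]] = {}
    for label, space in (("reduced", space_k), ("full", space_full)):
        matrix = distances(space)
        part = _asap_at_count(matrix, c)
        if part is not None:
            rep = quality_report(part, taxonomy)
            rows.append({"algorithm": "ASAP", "rank": space.k, "space": label,
                         **report_row(rep)})
            lcq_by_alg.setdefault("ASAP", {})[label] = rep.lcq
        km = best_of_seeds(space, c, seeds)
        rep = quality_report(km.partition(space.k), taxonomy)
        rows.append({"algorithm": "k-means", "rank": space.k, "space": label,
                     **report_row(rep)})
        lcq_by_alg.setdefault("k-means", {})[label] = rep.lcq
    df = pd.DataFrame(rows)
    gains = []
    for _, row in df.iterrows():
        pair = lcq_by_alg.get(row["algorithm"], {})
        if (row["space"] == "reduced" and pair.get("full") and pair.get("reduced")):
            gains.append(round(100.0 * (pair["reduced"] / pair["full"] - 1.0), 2))
        else:
            gains.append(np.nan)
    df["lcq_gain_pct"] = gains
    return df


def read_assignment_tsv(text: str, k_used: int = 0) -> Partition:
    """Import an externally produced (species_id, cluster) assignment TSV."""
    clusters: dict[str, set[str]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("species_id"):
            continue
        sid, cl, *_ = line.split("\t")
        clusters.setdefault(cl, set()).add(sid)
    return Partition(
        tuple(frozenset(v) for _, v in sorted(clusters.items())),
        k_used, float("nan"), "external",
    )
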