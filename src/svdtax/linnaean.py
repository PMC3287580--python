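"""Linnaean cluster-quality statistics.

A partition is scored against a fixed 14-rank Linnaean taxonomy.  The
per-cluster quality is the *common Linnaean taxonomy level frequency*,

    cLtlf = |cluster| x shared_levels(cluster),

where shared_levels is the depth of the deepest rank (longest lineage
prefix, Superregnum -> Species) shared by every member; distinct species
cap this at 13 (a shared genus), and a singleton scores 13 by convention.
Partition-level summaries are the sum, mean, sample standard deviation,
median of the per-cluster cLtlf values, and the Linnaean clusters quality

    Lcq = sum(cLtlf) / sigma,

undefined when sigma = 0.  Lcq discriminates configurations well while the
positive control is still mixed with other species; the median is the
better ranking statistic once it is isolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .asap import Partition
from .species_io import N_RANKS, ValidationError

MAX_SHARED_LEVELS = 13  # distinct species can share at most the genus
SINGLETON_LEVELS = 13


@dataclass(frozen=True)
class ClusterScore:
    cluster_index: int
    n_species: int
    shared_levels: int
    cltlf: int


@dataclass(frozen=True)
class QualityReport:
    """Per-cluster cLtlf scores with their summary statistics."""

    per_cluster: tuple[ClusterScore, ...]
    sum_cltlf: int
    mean_cltlf: float
    std_cltlf: float          # sample (n-1) standard deviation; 0.0 if n < 2
    lcq: float | None         # None when std is 0 or undefined
    median_cltlf: float
    n_clusters: int

    @property
    def min_cltlf(self) -> int:
        return min(s.cltlf for s in self.per_cluster)

    @property
    def max_cltlf(self) -> int:
        return max(s.cltlf for s in self.per_cluster)


def shared_levels(lineages: Sequence[Sequence[str]]) -> int:
    """Depth of the deepest Linnaean rank common to all ``lineages``.

    Computed as the longest common prefix in rank order; two lineages that
    agree through Subclassis but split at Ordo share 10 levels.  A single
    lineage scores the singleton convention of 13.
    """
    if not lineages:
        raise ValidationError("shared_levels needs at least one lineage")
    for lin in lineages:
        if len(lin) != N_RANKS:
            raise ValidationError(f"lineage has {len(lin)} ranks, expected {N_RANKS}")
    if len(lineages) == 1:
        return SINGLETON_LEVELS
    depth = 0
    for rank in range(N_RANKS):
        names = {lin[rank] for lin in lineages}
        if len(names) > 1:
            break
        depth = rank + 1
    return min(depth, MAX_SHARED_LEVELS)


def cltlf(cluster: Iterable[str], taxonomy: Mapping[str, Sequence[str]]) -> int:
    """cluster size x shared Linnaean levels of its members."""
    members = list(cluster)
    if not members:
        raise ValidationError("empty cluster")
    lineages = []
    for sid in members:
        if sid not in taxonomy or taxonomy[sid] is None:
            raise ValidationError(f"species {sid!r} has no lineage")
        lineages.append(taxonomy[sid])
    return len(members) * shared_levels(lineages)


def summarize_cltlf(values: Sequence[int | float]) -> QualityReport:
    """Summary statistics over externally supplied per-cluster cLtlf values."""
    scores = tuple(
        ClusterScore(i + 1, 0, 0, int(v)) for i, v in enumerate(values)
    )
    return _summaries(scores)


def _summaries(scores: tuple[ClusterScore, ...]) -> QualityReport:
    vals = np.array([s.cltlf for s in scores], dtype=float)
    total = int(vals.sum())
    std = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    lcq = total / std if std > 0 else None
    return QualityReport(
        per_cluster=scores,
        sum_cltlf=total,
        mean_cltlf=float(vals.mean()),
        std_cltlf=std,
        lcq=lcq,
        median_cltlf=float(np.median(vals)),
        n_clusters=len(scores),
    )


def quality_report(
    partition: Partition, taxonomy: Mapping[str, Sequence[str]]
) -> QualityReport:
    """Score every cluster of ``partition`` and summarize.

    The sample (n-1) standard deviation is used throughout; the median of an
    even count is the mean of the two central order statistics.  A
    single-cluster partition is valid but its sigma and Lcq are undefined.
    """
    scores = []
    for idx, cluster in enumerate(partition.clusters, start=1):
        members = sorted(cluster)
        for sid in members:
            if sid not in taxonomy:
                raise ValidationError(f"species {sid!r} has no lineage")
        lv = shared_levels([taxonomy[sid] for sid in members])
        scores.append(ClusterScore(idx, len(members), lv, len(members) * lv))
    return _summaries(tuple(scores))


def control_isolation(partition: Partition, control: frozenset[str] | set[str],
                      taxonomy: Mapping[str, Sequence[str]] | None = None) -> dict:
    """Did the partition isolate the positive control integrally and alone?

    ``isolated`` is true iff some cluster equals the control set exactly.
    Otherwise the cluster holding the most control members is characterized:
    its cLtlf (when a taxonomy is given), how many non-control species it
    contains, and how many control members sit elsewhere.
    """
    control = frozenset(control)
    if not control:
        raise ValidationError("empty control set")
    best, best_hits = None, -1
    for cluster in partition.clusters:
        hits = len(cluster & control)
        if hits > best_hits:
            best, best_hits = cluster, hits
    isolated = best == control
    ccltlf = 0
    if taxonomy is not None and best:
        ccltlf = cltlf(best, taxonomy)
    return {
        "isolated": isolated,
        "control_cluster_cltlf": ccltlf,
        "n_foreign": len(best - control),
        "n_missing": len(control - best),
    }


def report_row(report: QualityReport) -> dict:
    """Flat Table-shaped row: N, min, max, mean, sum, sigma, Lcq, median."""
    return {
        "N": report.n_clusters,
        "min_cltlf": report.min_cltlf,
        "max_cltlf": report.max_cltlf,
        "mean_cltlf": round(report.mean_cltlf, 2),
        "sum_cltlf": report.sum_cltlf,
        "std_cltlf": round(report.std_cltlf, 2),
        "lcq": round(report.lcq, 2) if report.lcq is not None else None,
        "median_cltlf": round(report.median_cltlf, 2),
    }
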