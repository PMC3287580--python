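"""Recursive kdc parameter search.

The search sweeps the rank k of the SVD reduction; for each k it derives,
from the cluster-count profile of the resulting distance matrix, the
thresholds d that realize each target cluster count c, giving (k, d, c)
triads.  Every triad's partition is scored against the taxonomy.  A triad
is *valid* when it isolates the positive control group integrally in its
own cluster.  If no triad at the current depth is valid, the species
trapped in singleton clusters of the best available partition are dropped
and the search recurses on the remainder; once valid triads exist, they
are ranked (``finalize``): configurations that also isolate the secondary
control group come first, then descending median per-cluster cLtlf — the
statistic that, unlike Lcq, keeps rewarding configurations after the
control is isolated — with singleton-poor partitions and small ranks
breaking ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from . import svd_space
from .asap import Partition, asap_cluster, profile_with_stability
from .linnaean import QualityReport, control_isolation, quality_report
from .species_io import Dataset, ValidationError
from .trigram import TrigramMatrix, build_matrix

logger = logging.getLogger(__name__)


def default_edrd(n: int) -> int:
    """Empirical Dimensional Range Division: the k/c grid step, ~ n/25.

    n = 76 species gives step 3, hence the c grid 3, 6, ..., 75.
    """
    return max(1, round(n / 25))


@dataclass
class SearchConfig:
    """Grids and gates for the kdc sweep.

    Defaults derive both grids from EDRD: ranks 3, 3+EDRD, ... <= n (ranks
    below 3 are degenerate projections) and cluster counts EDRD, 2*EDRD, ...
    < n.  ``dense`` replaces both with an exhaustive 1..n sweep.
    """

    control: frozenset[str] = frozenset()
    secondary_control: frozenset[str] | None = None
    ranks_to_try: list[int] | None = None
    cluster_counts_to_try: list[int] | None = None
    edrd: int | None = None
    max_recursions: int = 3
    dense: bool = False
    normalize: bool = False

    def resolve(self, n: int) -> tuple[list[int], list[int], int]:
        edrd = self.edrd if self.edrd is not None else default_edrd(n)
        if self.dense:
            ranks = list(range(1, n + 1))
            counts = list(range(1, n + 1))
        else:
            ranks = self.ranks_to_try or list(range(3, n + 1, edrd))
            counts = self.cluster_counts_to_try or list(range(edrd, n, edrd))
        ranks = [k for k in ranks if 1 <= k <= n]
        counts = [c for c in counts if 1 <= c <= n]
        if not ranks or not counts:
            raise ValidationError("empty k or c grid after bounding to [1, n]")
        return ranks, counts, edrd


@dataclass
class KdcResult:
    """One scored (k, d, c) triad."""

    k: int
    d: float
    c: int
    partition: Partition
    report: QualityReport
    control_isolated: bool
    secondary_isolated: bool
    n_singletons: int
    control_cluster_cltlf: int = 0


@dataclass
class SearchOutcome:
    """Ranked valid triads plus the recursion trace that produced them."""

    ranked: list[KdcResult]
    dataset: Dataset                 # the (possibly reduced) dataset scored
    depth: int
    dropped: list[list[str]] = field(default_factory=list)  # per-depth drops
    all_results: list[KdcResult] = field(default_factory=list)


def kdc_sweep(A: TrigramMatrix, taxonomy, config: SearchConfig) -> list[KdcResult]:
    """Score every realizable (k, d, c) triad on the given trigram matrix.

    For each rank k the ASAP cluster-count profile is a step function of d;
    for each target c the realizing threshold sitting in the *widest*
    constant-count interval is used — the realization most stable to
    perturbation of d (ties broken toward the larger threshold).  Targets no
    threshold realizes are skipped.
    """
    n = A.n_species
    ranks, counts, _ = config.resolve(n)
    factors = svd_space.decompose(A, normalize=config.normalize)
    results: list[KdcResult] = []
    for k in ranks:
        if k > factors.rank:
            logger.debug("skipping k=%d beyond numerical rank %d", k, factors.rank)
            continue
        matrix = svd_space.distances(svd_space.reduce(factors, k))
        profile = profile_with_stability(matrix)
        by_count: dict[int, tuple[float, float]] = {}   # c -> (width, d)
        for d, c, width in profile:
            if c not in by_count or (width, d) > by_count[c]:
                by_count[c] = (width, d)
        for c in counts:
            if c not in by_count:
                logger.debug("no threshold realizes c=%d at k=%d", c, k)
                continue
            d = by_count[c][1]
            partition = asap_cluster(matrix, d)
            report = quality_report(partition, taxonomy)
            iso = control_isolation(partition, config.control, taxonomy)
            sec = False
            if config.secondary_control:
                sec = control_isolation(partition, config.secondary_control)["isolated"]
            results.append(
                KdcResult(
                    k=k, d=d, c=partition.c, partition=partition, report=report,
                    control_isolated=iso["isolated"], secondary_isolated=sec,
                    n_singletons=partition.n_singletons,
                    control_cluster_cltlf=iso["control_cluster_cltlf"],
                )
            )
    return results


def select_best_nonisolating(results: list[KdcResult]) -> KdcResult:
    """The triad to recurse from: control cluster with maximal cLtlf, then
    fewest singleton clusters (keep as many species as possible grouped)."""
    return max(results, key=lambda r: (r.control_cluster_cltlf, -r.n_singletons))


def recurse_step(best: KdcResult, dataset: Dataset) -> tuple[Dataset, list[str]]:
    """Drop species isolated in singleton clusters of ``best``'s partition.

    Control members are never dropped.  Aborts if the reduced dataset would
    fall below |control| + 2 species.
    """
    control = dataset.positive_control
    drop = {
        sid
        for cl in best.partition.clusters
        if len(cl) == 1
        for sid in cl
        if sid not in control
    }
    keep = [sid for sid in dataset.species_ids if sid not in drop]
    if len(keep) < len(control) + 2:
        raise ValidationError(
            f"recursion would leave {len(keep)} species "
            f"(< |control| + 2 = {len(control) + 2}); aborting"
        )
    return dataset.subset(keep), sorted(drop)


def finalize(results: list[KdcResult]) -> list[KdcResult]:
    """Rank control-isolating triads, best first.

    When a secondary control group is configured, configurations isolating
    it rank above those that do not: the median rewards coarse partitions
    that merge informative groups, and a second, deeper control group is
    what disambiguates them (it is how the 8-cluster/rank-9 configuration
    was preferred over two higher-median ones on the mitochondrial corpus).
    Within each stratum: descending median cLtlf; ties broken by fewer
    singleton clusters, then smaller rank k, then more multi-member clusters
    (a good separation keeps the largest possible number of species together
    in informative groups).
    """
    if not results:
        raise ValidationError("no isolating configuration to finalize")
    if not all(r.control_isolated for r in results):
        raise ValidationError("finalize requires control-isolated results only")
    return sorted(
        results,
        key=lambda r: (
            not r.secondary_isolated,
            -r.report.median_cltlf,
            r.n_singletons,
            r.k,
            -(r.c - r.n_singletons),
        ),
    )


def kdc_search(dataset: Dataset, taxonomy, config: SearchConfig | None = None) -> SearchOutcome:
    """Run the full recursive search on a dataset with lineages attached.

    At each depth: sweep all triads; if any isolates the positive control,
    finalize and stop.  Otherwise prune singleton species from the best
    partition and recurse, up to ``max_recursions`` extra depths.
    """
    if config is None:
        config = SearchConfig(control=dataset.positive_control,
                              secondary_control=dataset.secondary_control)
    if not config.control:
        raise ValidationError("kdc_search needs a non-empty positive control")
    if not set(config.control) <= set(dataset.species_ids):
        raise ValidationError("control is not a subset of the dataset species")

    current = dataset
    dropped: list[list[str]] = []
    last_results: list[KdcResult] = []
    for depth in range(config.max_recursions + 1):
        A = build_matrix(current)
        results = kdc_sweep(A, taxonomy, config)
        last_results = results
        isolating = [r for r in results if r.control_isolated]
        if isolating:
            return SearchOutcome(finalize(isolating), current, depth, dropped, results)
        if depth == config.max_recursions or not results:
            break
        best = select_best_nonisolating(results)
        current, drop = recurse_step(best, current)
        logger.info("depth %d: dropped %d singleton species", depth, len(drop))
        dropped.append(drop)
    return SearchOutcome([], current, len(dropped), dropped, last_results)


def ranking_table(ranked: list[KdcResult]) -> str:
    """Ranked triads as TSV shaped like the finalize statistics table."""
    header = ("rank_position\tclusters\tk\td\tN\tmin_cltlf\tmax_cltlf\tmean_cltlf"
              "\tsum_cltlf\tstd_cltlf\tlcq\tmedian_cltlf\tn_singletons"
              "\tcontrol_isolated\tsecondary_isolated")
    lines = [header]
    for pos, r in enumerate(ranked, start=1):
        rep = r.report
        lcq = f"{rep.lcq:.2f}" if rep.lcq is not None else "NA"
        lines.append(
            f"{pos}\t{r.c:02d}clusters\tK{r.k:02d}\t{r.d:.6g}\t{rep.n_clusters}"
            f"\t{rep.min_cltlf}\t{rep.max_cltlf}\t{rep.mean_cltlf:.2f}"
            f"\t{rep.sum_cltlf}\t{rep.std_cltlf:.2f}\t{lcq}"
            f"\t{rep.median_cltlf:.2f}\t{r.n_singletons}"
            f"\t{r.control_isolated}\t{r.secondary_isolated}"
        )
    return "\n".join(lines) + "\n"
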