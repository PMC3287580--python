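import numpy as np
import pytest

from svdtax.asap import Partition
from svdtax.kdc import (
    KdcResult,
    SearchConfig,
    default_edrd,
    finalize,
    kdc_search,
    kdc_sweep,
    recurse_step,
    select_best_nonisolating,
)
from svdtax.linnaean import summarize_cltlf
from svdtax.species_io import ValidationError
from svdtax.synthetic import SimSpec, planted_partition, simulate, taxonomy_of
from svdtax.trigram import build_matrix

# Printed per-cluster cLtlf columns of the nine control-isolating
# configurations from the finalize sample-data table (negative-control
# columns excluded, as in the source).
FINALIZE_COLUMNS = {
    ("06clusters", 3): [100, 243, 45, 96, 13, 40],
    ("06clusters", 6): [100, 243, 64, 100, 13, 40],
    ("08clusters", 6): [100, 200, 56, 13, 100, 45, 24, 40],
    ("08clusters", 9): [100, 225, 56, 56, 24, 40, 48, 13],
    ("08clusters", 45): [100, 243, 13, 136, 22, 13, 13, 13],
    ("12clusters", 12): [100, 216, 13, 64, 22, 13, 13, 16, 24, 40, 48, 13],
    ("14clusters", 18): [100, 240, 13, 90, 22, 13, 16, 24, 40, 13, 13, 13, 13, 13],
    ("14clusters", 21): [100, 250, 13, 88, 22, 13, 13, 13, 30, 13, 13, 13, 13, 13],
    ("14clusters", 60): [100, 220, 13, 112, 22, 20, 13, 24, 13, 13, 13, 13, 13, 13],
}


def result_from_cltlf(label, k, values, n_singletons=None, secondary=False):
    """A KdcResult carrying only what finalize ranks on."""
    report = summarize_cltlf(values)
    singles = sum(1 for v in values if v == 13) if n_singletons is None else n_singletons
    dummy = Partition((frozenset({"x"}),), k, 0.0, "fixed")
    return KdcResult(
        k=k, d=0.0, c=len(values), partition=dummy, report=report,
        control_isolated=True, secondary_isolated=secondary,
        n_singletons=singles,
    )


class TestGrids:
    def test_edrd_instance(self):
        assert default_edrd(76) == 3

    def test_default_grids_for_76_species(self):
        ranks, counts, edrd = SearchConfig(control=frozenset({"x"})).resolve(76)
        assert edrd == 3
        assert counts == list(range(3, 76, 3))  # c3, c6, ..., c75
        assert ranks[0] == 3 and ranks[-1] <= 76 and ranks[1] - ranks[0] == 3

    def test_small_n_step_one(self):
        ranks, counts, edrd = SearchConfig(control=frozenset({"x"})).resolve(20)
        assert edrd == 1
        assert counts == list(range(1, 20))
        assert ranks == list(range(3, 21))


@pytest.fixture(scope="module")
def sweep():
    spec = SimSpec(n_clades=3, species_per_clade=4, seq_length=600,
                   seed=5, secondary_clade=None)
    ds = simulate(spec)
    tax = taxonomy_of(ds)
    cfg = SearchConfig(control=ds.positive_control)
    return spec, ds, kdc_sweep(build_matrix(ds), tax, cfg)


class TestSweep:
    def test_c_equals_n_realized_at_zero_threshold(self, sweep):
        spec, ds, results = sweep
        n = len(ds.records)
        # c = n is not in the default grid (< n), so request it explicitly
        cfg = SearchConfig(control=ds.positive_control,
                           cluster_counts_to_try=[n])
        res = kdc_sweep(build_matrix(ds), taxonomy_of(ds), cfg)
        assert res and all(r.c == n for r in res)
        # realized below the smallest pairwise distance: all singletons
        assert all(len(cl) == 1 for r in res for cl in r.partition.clusters)

    def test_planted_clades_recovered_at_c3(self, sweep):
        spec, ds, results = sweep
        planted = set(planted_partition(spec, ds).clusters)
        hits = [r for r in results if r.c == 3 and set(r.partition.clusters) == planted]
        assert hits, "no (k, d, c=3) triad recovered the planted clades"

    def test_reports_attached_and_consistent(self, sweep):
        _, _, results = sweep
        for r in results:
            assert r.c == len(r.partition.clusters)
            assert r.report.n_clusters == r.c
            assert r.n_singletons == r.partition.n_singletons

    def test_sweep_deterministic(self, sweep):
        spec, ds, results = sweep
        again = kdc_sweep(build_matrix(ds), taxonomy_of(ds),
                          SearchConfig(control=ds.positive_control))
        assert [(r.k, r.d, r.c) for r in results] == [(r.k, r.d, r.c) for r in again]


class TestRecursion:
    def test_outliers_dropped_then_control_isolated(self):
        spec = SimSpec(n_clades=3, species_per_clade=4, seq_length=600,
                       n_outliers=2, seed=9, secondary_clade=None)
        ds = simulate(spec)
        out = kdc_search(ds, taxonomy_of(ds))
        assert out.ranked, "control never isolated"
        top = out.ranked[0]
        members = {sid for cl in top.partition.clusters for sid in cl}
        assert ds.positive_control <= members

    def test_isolated_at_depth_zero_returns_unchanged(self):
        spec = SimSpec(n_clades=3, species_per_clade=4, seq_length=600,
                       seed=5, secondary_clade=None)
        ds = simulate(spec)
        out = kdc_search(ds, taxonomy_of(ds))
        assert out.depth == 0
        assert out.dataset.species_ids == ds.species_ids

    def test_best_nonisolating_prefers_control_cltlf_then_fewer_singletons(self):
        a = result_from_cltlf("a", 3, [80, 13], n_singletons=1)
        a.control_cluster_cltlf = 60
        b = result_from_cltlf("b", 3, [90, 26], n_singletons=0)
        b.control_cluster_cltlf = 80
        c = result_from_cltlf("c", 3, [90, 13], n_singletons=2)
        c.control_cluster_cltlf = 80
        assert select_best_nonisolating([a, b, c]) is b

    def test_recurse_step_drops_singletons_not_control(self):
        ids = [f"s{i}" for i in range(6)]
        part = Partition(
            (frozenset(ids[:3]), frozenset({ids[3]}), frozenset({ids[4]}),
             frozenset({ids[5]})),
            3, 1.0, "fixed",
        )
        from svdtax.species_io import Dataset, SpeciesRecord

        ds = Dataset([SpeciesRecord(i, "MKVA") for i in ids],
                     frozenset({ids[0], ids[5]}))
        best = result_from_cltlf("x", 3, [30, 13, 13, 13])
        best = KdcResult(**{**best.__dict__, "partition": part})
        reduced, dropped = recurse_step(best, ds)
        assert dropped == ["s3", "s4"]
        assert "s5" in reduced.species_ids  # control member kept

    def test_recursion_abort_when_too_few_left(self):
        ids = [f"s{i}" for i in range(4)]
        part = Partition(tuple(frozenset({i}) for i in ids), 3, 1.0, "fixed")
        from svdtax.species_io import Dataset, SpeciesRecord

        ds = Dataset([SpeciesRecord(i, "MKVA") for i in ids], frozenset({ids[0]}))
        best = result_from_cltlf("x", 3, [13, 13, 13, 13])
        best = KdcResult(**{**best.__dict__, "partition": part})
        with pytest.raises(ValidationError):
            recurse_step(best, ds)


class TestFinalize:
    def test_printed_columns_rank_by_median(self):
        results = [
            result_from_cltlf(label, k, vals)
            for (label, k), vals in FINALIZE_COLUMNS.items()
        ]
        ranked = finalize(results)
        top3 = [(r.c, r.k) for r in ranked[:3]]
        assert top3 == [(6, 6), (6, 3), (8, 9)]
        assert ranked[0].report.median_cltlf == pytest.approx(82.00)
        assert ranked[1].report.median_cltlf == pytest.approx(70.50)
        assert ranked[2].report.median_cltlf == pytest.approx(52.00)

    def test_single_candidate(self):
        r = result_from_cltlf("solo", 4, [100, 40])
        assert finalize([r]) == [r]

    def test_equal_medians_fewer_singletons_first(self):
        a = result_from_cltlf("a", 5, [100, 40, 13], n_singletons=1)
        b = result_from_cltlf("b", 5, [100, 40, 26], n_singletons=0)
        assert finalize([a, b])[0] is b

    def test_secondary_isolation_outranks_median(self):
        low = result_from_cltlf("low", 9, [100, 52, 40], secondary=True)
        high = result_from_cltlf("high", 6, [100, 120, 80], secondary=False)
        assert finalize([high, low])[0] is low

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            finalize([])

    def test_non_isolating_input_rejected(self):
        r = result_from_cltlf("x", 3, [100])
        r.control_isolated = False
        with pytest.raises(ValidationError):
            finalize([r])


def test_full_search_is_reproducible():
    spec = SimSpec(n_clades=3, species_per_clade=4, seq_length=600, seed=2)
    ds = simulate(spec)
    tax = taxonomy_of(ds)
    a, b = kdc_search(ds, tax), kdc_search(ds, tax)
    assert [(r.k, r.d, r.c) for r in a.ranked] == [(r.k, r.d, r.c) for r in b.ranked]
    assert a.ranked[0].partition == b.ranked[0].partition


def test_gate_soundness():
    spec = SimSpec(n_clades=3, species_per_clade=4, seq_length=600, seed=5)
    ds = simulate(spec)
    tax = taxonomy_of(ds)
    out = kdc_search(ds, tax)
    from svdtax.linnaean import cltlf

    for r in out.ranked:
        assert frozenset(ds.positive_control) in set(r.partition.clusters)
        expected = cltlf(ds.positive_control, tax)
        assert r.control_cluster_cltlf == expected
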