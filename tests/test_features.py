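import itertools

import numpy as np
import pytest

from conftest import make_bins
from oracles import brute_force_cluster_runs
from ssrscape.features import (
    call_clusters,
    call_elrs,
    call_peaks,
    cluster_level,
    peak_level,
)
from ssrscape.ssr_detect import SSRRecord, canonical_class


def make_class_records(classes, seg="S1", gap=10, length=12):
    """Fabricate a sorted SSR list whose rotation classes follow `classes`."""
    motif_for = {"AT": "AT", "CT": "CT", "C": "C", "AC": "AC", "AAAG": "GAAA", "AG": "AG"}
    recs = []
    pos = 1
    for cls in classes:
        motif = motif_for[cls]
        recs.append(
            SSRRecord(
                motif=motif,
                unit_len=len(motif),
                copies=length // len(motif),
                start=pos,
                end=pos + length - 1,
                motif_class=canonical_class(motif),
                segment_name=seg,
            )
        )
        pos += length + gap
    return recs


class TestPeakLevels:
    @pytest.mark.parametrize(
        "density,expected",
        [
            (89.99, None),
            (90.00, "LP"),
            (149.99, "LP"),
            (150.00, "MP"),
            (299.99, "MP"),
            (300.00, "HP"),
            (424.99, "HP"),
            (425.00, "sHP"),
            (1000.0, "sHP"),
            (0.0, None),
        ],
    )
    def test_printed_boundaries(self, density, expected):
        assert peak_level(density) == expected

    def test_levels_partition_above_floor(self):
        """Every density >= 90 maps to exactly one of the four levels."""
        rng = np.random.default_rng(7)
        for d in rng.uniform(90, 1000, size=500):
            assert peak_level(float(d)) in {"sHP", "HP", "MP", "LP"}

    def test_call_peaks_bracket_lookup(self):
        bins = make_bins([0, 95, 160, 310, 430])
        calls = call_peaks(bins)
        assert [c.level for c in calls] == ["LP", "MP", "HP", "sHP"]
        assert calls[0].bin.index_i == 2

    def test_one_call_per_qualifying_bin_no_merging(self):
        bins = make_bins([430, 430, 430])
        assert [c.level for c in call_peaks(bins)] == ["sHP"] * 3

    def test_refuses_non_1kb_bins(self):
        from conftest import make_bins as mb

        bins = mb([100], d_n=500)
        with pytest.raises(ValueError):
            call_peaks(bins)


class TestELRs:
    def test_long_sparse_run_is_belr(self):
        bins = make_bins([10] * 150)
        calls = call_elrs(bins)
        assert len(calls) == 1
        e = calls[0]
        assert (e.kind, e.size) == ("bELR", 150_000)
        assert e.rd == pytest.approx(10.0)

    def test_two_zero_bins_flanked_dense_is_zd(self):
        bins = make_bins([100, 0, 0, 100])
        calls = call_elrs(bins)
        assert [(c.kind, c.size) for c in calls] == [("ZD", 2000)]

    def test_four_zero_bins_is_selr_not_zd(self):
        bins = make_bins([100, 0, 0, 0, 0, 100])
        calls = call_elrs(bins)
        assert [(c.kind, c.size) for c in calls] == [("sELR", 4000)]

    def test_mixed_sparse_run_of_three_is_selr(self):
        bins = make_bins([100, 10, 0, 0, 100])
        calls = call_elrs(bins)
        assert [(c.kind, c.size) for c in calls] == [("sELR", 3000)]

    def test_dense_bin_terminates_run(self):
        bins = make_bins([0, 0, 100, 0, 0])
        calls = call_elrs(bins)
        assert [(c.kind, c.start) for c in calls] == [("ZD", 1), ("ZD", 3001)]

    def test_segment_edge_closes_run(self):
        bins = make_bins([0, 0], seg_name="S1") + make_bins(
            [0, 0], seg_name="S2", seg_start=10_001
        )
        calls = call_elrs(bins)
        assert len(calls) == 2 and all(c.kind == "ZD" for c in calls)

    def test_enumeration_of_small_bin_vectors(self):
        """Structural invariants hold for every small density vector."""
        for length in (1, 2, 3, 4, 5):
            for ms in itertools.product((0, 10, 100), repeat=length):
                bins = make_bins(list(ms))
                calls = call_elrs(bins)
                spans = []
                for c in calls:
                    members = [b for b in bins if c.start <= b.start <= c.end]
                    assert all(b.pdnrd_norm < 25.0 for b in members)
                    if c.kind == "ZD":
                        assert all(b.m_i == 0 for b in members) and c.size <= 2000
                    else:
                        assert c.size >= 3000 and c.rd < 25.0
                    spans.append((c.start, c.end))
                # no double-reporting: calls never overlap
                spans.sort()
                assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))
                # a ZD is never inside an ELR
                for c in calls:
                    if c.kind == "ZD":
                        assert not any(
                            o.start <= c.start and o.end >= c.end
                            for o in calls
                            if o is not c
                        )

    def test_no_bin_is_both_peak_and_in_elr(self):
        rng = np.random.default_rng(11)
        bins = make_bins(list(rng.integers(0, 500, size=200)))
        peak_starts = {c.bin.start for c in call_peaks(bins)}
        for e in call_elrs(bins):
            assert not any(e.start <= s <= e.end for s in peak_starts)


class TestClusters:
    def test_minimum_run_of_three(self):
        calls = call_clusters(make_class_records(["AT", "AT", "AT"]))
        assert len(calls) == 1
        assert (calls[0].level, calls[0].n_members) == ("mClu", 3)

    def test_interruption_breaks_run(self):
        assert call_clusters(make_class_records(["AT", "AT", "C", "AT"])) == []

    def test_level_boundaries(self):
        for n, lvl in [(3, "mClu"), (8, "mClu"), (9, "MClu"), (25, "MClu"), (26, "Clu")]:
            calls = call_clusters(make_class_records(["CT"] * n))
            assert [c.level for c in calls] == [lvl], n
            assert cluster_level(n) == lvl
        assert cluster_level(2) is None

    def test_rotation_classes_group_together(self):
        recs = make_class_records(["AT"] * 3)
        # same rotation class via a different literal motif
        rotated = recs[1].__class__(**{**recs[1].__dict__, "motif": "TA"})
        calls = call_clusters([recs[0], rotated, recs[2]])
        assert len(calls) == 1 and calls[0].n_members == 3

    def test_strict_motif_switch(self):
        recs = make_class_records(["AT"] * 3)
        rotated = recs[1].__class__(**{**recs[1].__dict__, "motif": "TA"})
        assert call_clusters([recs[0], rotated, recs[2]], strict_motif=True) == []

    def test_max_gap_breaks_run(self):
        recs = make_class_records(["AT"] * 4, gap=100)
        assert call_clusters(recs, max_gap=50) == []
        assert len(call_clusters(recs, max_gap=100)) == 1

    def test_segment_boundary_breaks_run(self):
        a = make_class_records(["AT"] * 2, seg="S1")
        b = make_class_records(["AT"] * 2, seg="S2")
        assert call_clusters(a + b) == []

    def test_matches_run_length_oracle(self):
        """Cluster calls equal an exhaustive run scanner on random classes."""
        rng = np.random.default_rng(99)
        pool = ["AT", "CT", "C", "AC", "AAAG"]
        for _ in range(300):
            classes = [pool[i] for i in rng.integers(0, len(pool), size=rng.integers(1, 40))]
            recs = make_class_records(classes)
            got = [(c.members[0].start, c.n_members, c.motif_class) for c in call_clusters(recs)]
            expect = [
                (recs[i].start, j - i, canonical_class(recs[i].motif))
                for i, j, _ in brute_force_cluster_runs(classes)
            ]
            assert got == expect

    def test_maximality(self):
        """No cluster can be extended by an adjacent same-class record."""
        rng = np.random.default_rng(5)
        pool = ["AT", "CT", "C"]
        classes = [pool[i] for i in rng.integers(0, 3, size=200)]
        recs = make_class_records(classes)
        by_start = {r.start: i for i, r in enumerate(recs)}
        for c in call_clusters(recs):
            i0 = by_start[c.members[0].start]
            i1 = by_start[c.members[-1].start]
            if i0 > 0:
                assert recs[i0 - 1].motif_class != c.motif_class
            if i1 < len(recs) - 1:
                assert recs[i1 + 1].motif_class != c.motif_class
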