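import numpy as np
import pytest

from conftest import make_segment
from oracles import per_position_bin_counts
from ssrscape.density import bin_segment, global_rd, profile
from ssrscape.sequence_io import find_segments
from ssrscape.ssr_detect import SSRRecord, detect_ssrs


def make_ssr(start, end, seg="S1", motif="A"):
    return SSRRecord(
        motif=motif,
        unit_len=len(motif),
        copies=(end - start + 1) // len(motif),
        start=start,
        end=end,
        motif_class=motif,
        segment_name=seg,
    )


class TestGlobalRD:
    def test_reference_arithmetic(self):
        """The chromosome-wide average density from the published totals."""
        assert global_rd(1_528_466, 26_415_000) == pytest.approx(57.86, abs=0.005)

    def test_zero_ssr(self):
        assert global_rd(0, 1000) == 0.0

    def test_scale_is_per_kilobase(self):
        assert global_rd(50, 1000) == pytest.approx(50.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            global_rd(10, 0)


class TestBinSegment:
    def test_ceil_bin_count_and_sizes(self):
        bins = bin_segment(make_segment(2500), [], 1000)
        assert [b.size for b in bins] == [1000, 1000, 500]
        assert [(b.start, b.end) for b in bins] == [(1, 1000), (1001, 2000), (2001, 2500)]

    def test_ssr_wholly_inside_one_bin(self):
        bins = bin_segment(make_segment(3000), [make_ssr(1101, 1200)], 1000)
        assert [b.m_i for b in bins] == [0, 100, 0]
        assert bins[1].pdnrd == pytest.approx(100.0)

    def test_ssr_split_across_boundary(self):
        bins = bin_segment(make_segment(2000), [make_ssr(951, 1050)], 1000)
        assert [b.m_i for b in bins] == [50, 50]

    def test_ssr_spanning_many_bins(self):
        bins = bin_segment(make_segment(5000), [make_ssr(500, 4499)], 1000)
        assert [b.m_i for b in bins] == [501, 1000, 1000, 1000, 499]

    def test_ssr_outside_segment_rejected(self):
        with pytest.raises(ValueError):
            bin_segment(make_segment(1000, start=101), [make_ssr(50, 120)], 100)

    def test_offset_segment_coordinates(self):
        seg = make_segment(2000, start=5001)
        bins = bin_segment(seg, [make_ssr(5951, 6050)], 1000)
        assert [b.m_i for b in bins] == [50, 50]
        assert bins[0].start == 5001

    def test_matches_position_wise_oracle(self, small_fixture):
        """Interval-arithmetic binning equals per-position counting."""
        _, result = small_fixture
        seq = result.sequence
        segs, _ = find_segments(seq)
        ssrs = detect_ssrs(seq, segs)
        for seg in segs:
            seg_ssrs = [r for r in ssrs if r.segment_name == seg.name]
            for d_n in (1000, 3000, 700):
                got = [b.m_i for b in bin_segment(seg, seg_ssrs, d_n)]
                expect = per_position_bin_counts(
                    [(r.start, r.end) for r in seg_ssrs], seg.start, seg.size, d_n
                )
                assert got == expect


class TestProfile:
    def test_single_full_bin(self):
        seg = make_segment(1000)
        prof = profile([seg], [make_ssr(101, 200)], 1000)
        assert len(prof.bins) == 1
        assert prof.bins[0].pdnrd == pytest.approx(100.0)
        assert prof.sd_pdnrd == 0.0

    def test_uniform_coverage_has_zero_sd(self):
        seg = make_segment(4000)
        ssrs = [make_ssr(1 + i * 1000, 100 + i * 1000) for i in range(4)]
        for d_n in (1000, 2000, 4000):
            prof = profile([seg], ssrs, d_n)
            assert prof.sd_pdnrd == pytest.approx(0.0)

    def test_conservation_at_all_resolutions(self, small_fixture):
        """Total binned SSR bp equals total SSR bp at every bin size."""
        _, result = small_fixture
        seq = result.sequence
        segs, _ = find_segments(seq)
        ssrs = detect_ssrs(seq, segs)
        total = sum(r.length for r in ssrs)
        for d_n in (100_000, 50_000, 10_000, 5_000, 2_000, 1_000, 333):
            prof = profile(segs, ssrs, d_n)
            assert sum(b.m_i for b in prof.bins) == total

    def test_degenerate_bin_recovers_global_rd(self):
        """One bin covering the whole segment reproduces the plain RD."""
        seg = make_segment(7500)
        ssrs = [make_ssr(101, 700)]
        prof = profile([seg], ssrs, 10_000)
        assert len(prof.bins) == 1
        assert prof.bins[0].pdnrd_norm == pytest.approx(global_rd(600, 7500))

    def test_refinement_consistency(self, small_fixture):
        """Merging 1 kb bins in groups of ten reproduces the 10 kb bins."""
        _, result = small_fixture
        seq = result.sequence
        segs, _ = find_segments(seq)
        ssrs = detect_ssrs(seq, segs)
        for seg in segs:
            seg_ssrs = [r for r in ssrs if r.segment_name == seg.name]
            fine = [b.m_i for b in bin_segment(seg, seg_ssrs, 1000)]
            coarse = [b.m_i for b in bin_segment(seg, seg_ssrs, 10_000)]
            merged = [sum(fine[i : i + 10]) for i in range(0, len(fine), 10)]
            assert merged == coarse

    def test_sd_grows_as_resolution_shrinks(self, small_fixture):
        """On a heterogeneous landscape, finer bins resolve more variation."""
        _, result = small_fixture
        seq = result.sequence
        segs, _ = find_segments(seq)
        ssrs = detect_ssrs(seq, segs)
        sds = [
            profile(segs, ssrs, d_n).sd_pdnrd
            for d_n in (30_000, 10_000, 5_000, 2_000, 1_000)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(sds, sds[1:]))
        assert sds[-1] > sds[0]

    def test_full_bin_density_range(self, small_fixture):
        _, result = small_fixture
        seq = result.sequence
        segs, _ = find_segments(seq)
        ssrs = detect_ssrs(seq, segs)
        prof = profile(segs, ssrs, 1000)
        assert all(0.0 <= b.pdnrd_norm <= 1000.0 for b in prof.bins)
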