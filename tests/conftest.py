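import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ssrscape.density import DensityBin
from ssrscape.sequence_io import SequencedSegment
from ssrscape.synthetic import (
    PlantedCluster,
    PlantedSSR,
    SyntheticSpec,
    generate,
)


def make_bins(m_values, seg_name="S1", d_n=1000, seg_start=1, last_size=None):
    """1 kb bins with given SSR bp per bin; for full bins pD_1RD == m_i."""
    bins = []
    for i, m in enumerate(m_values):
        size = d_n if (last_size is None or i < len(m_values) - 1) else last_size
        start = seg_start + i * d_n
        bins.append(
            DensityBin(
                segment_name=seg_name,
                index_i=i + 1,
                start=start,
                end=start + size - 1,
                unit_size=d_n,
                m_i=m,
            )
        )
    return bins


def make_segment(size, name="S1", start=1):
    return SequencedSegment(name=name, start=start, end=start + size - 1)


@pytest.fixture(scope="session")
def small_fixture():
    """Compact planted assembly exercising every feature class.

    Segment 0 (30 kb): planted peak bins at all four levels plus zero
    background elsewhere (yielding sparse regions). Segment 1 (20 kb):
    three clusters (Clu n=26, MClu n=12, mClu n=3). Segment 2 (5 kb):
    short segment for pooled-map handling.
    """
    spec = SyntheticSpec(
        seed=20260925,
        segment_sizes=(30_000, 20_000, 5_000),
        gap_sizes=(500, 250),
        planted_ssrs=(
            # sHP: 450 bp of (AAAAG) wholly inside bin 3 of segment 0
            PlantedSSR(segment=0, offset=2_100, motif="AAAAG", copies=90),
            # HP: 310 bp of (AC) inside bin 6
            PlantedSSR(segment=0, offset=5_100, motif="AC", copies=155),
            # MP: 200 bp of (AT) inside bin 9
            PlantedSSR(segment=0, offset=8_100, motif="AT", copies=100),
            # LP: 96 bp of (AAG) inside bin 12
            PlantedSSR(segment=0, offset=11_100, motif="AAG", copies=32),
            # boundary-straddling SSR: 100 bp across bins 15/16 (50/50)
            PlantedSSR(segment=0, offset=14_950, motif="AAAT", copies=25),
        ),
        planted_clusters=(
            PlantedCluster(segment=1, offset=200, motif="CT", copies=6, n_members=26, spacing=30),
            PlantedCluster(segment=1, offset=6_000, motif="GAAA", copies=3, n_members=12, spacing=40),
            PlantedCluster(segment=1, offset=9_000, motif="TA", copies=5, n_members=3, spacing=25),
        ),
        planted_deserts=((0, 20_000, 8_000),),
    )
    return spec, generate(spec)
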