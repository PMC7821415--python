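"""Differential relative-density computation.

The classic relative density RD = M / N x 1000 (SSR bp per kilobase of
sequence; e.g. 1,528,466 SSR bp over 26,415 kb gives RD 57.86) is a single
global average and hides positional structure. The differential method
instead tiles each sequenced segment into ceil(N / D_n) bins of size D_n
and computes, per bin i, the position-related density

    pD_nRD_i = m_i / D_n x 1000

where m_i is the number of SSR base pairs falling in bin i, so a full bin
ranges from 0 (no SSR bases) to 1000 (wall-to-wall repeats). An SSR that
spans a bin boundary contributes its bases to each bin it overlaps, so
sum(m_i) equals the total SSR bp exactly at every resolution. The standard
deviation of pD_nRD across bins serves as the resolution-exactness
diagnostic: it grows as D_n shrinks and heterogeneity is resolved.

The final bin of a segment is usually shorter than D_n; its density
normalized by the actual bin size (``pdnrd_norm``) is stored alongside the
nominal value and is the one used for classification, avoiding spurious
low-density calls at segment tails.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ssrscape.sequence_io import SequencedSegment
from ssrscape.ssr_detect import SSRRecord


#: densities are reported as SSR bp per kilobase of sequence
DENSITY_SCALE = 1000.0


def global_rd(total_ssr_bp: int, total_seq_bp: int) -> float:
    """Relative density: SSR base pairs per kilobase of sequence."""
    if total_seq_bp <= 0:
        raise ValueError("total sequence size must be positive")
    return total_ssr_bp / total_seq_bp * DENSITY_SCALE


@dataclass(frozen=True)
class DensityBin:
    """One differential unit: 1-based inclusive coordinates within the assembly."""

    segment_name: str
    index_i: int  # 1-based index within the segment
    start: int
    end: int
    unit_size: int  # nominal bin size D_n
    m_i: int  # SSR base pairs in this bin

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def pdnrd(self) -> float:
        """Nominal density m_i / D_n x 1000 (SSR bp per kb)."""
        return self.m_i / self.unit_size * DENSITY_SCALE

    @property
    def pdnrd_norm(self) -> float:
        """Density normalized by actual bin size (differs only for tail bins)."""
        return self.m_i / self.size * DENSITY_SCALE


@dataclass(frozen=True)
class DensityProfile:
    resolution: int
    bins: list[DensityBin]
    global_rd: float
    sd_pdnrd: float


def bin_segment(
    segment: SequencedSegment, ssrs: list[SSRRecord], d_n: int
) -> list[DensityBin]:
    """Tile a segment into ceil(size / D_n) bins and count SSR bp per bin.

    ``ssrs`` must lie within the segment. SSR bases are split across bin
    boundaries by overlap, conserving total SSR bp.
    """
    if d_n < 1:
        raise ValueError("bin size must be >= 1")
    n_bins = -(-segment.size // d_n)  # ceil
    m = np.zeros(n_bins, dtype=np.int64)
    for r in ssrs:
        if r.start < segment.start or r.end > segment.end:
            raise ValueError(
                f"SSR {r.start}-{r.end} outside segment "
                f"{segment.name} {segment.start}-{segment.end}"
            )
        lo = r.start - segment.start  # 0-based offsets within segment
        hi = r.end - segment.start
        b0, b1 = lo // d_n, hi // d_n
        if b0 == b1:
            m[b0] += hi - lo + 1
        else:
            m[b0] += (b0 + 1) * d_n - lo
            m[b1] += hi - b1 * d_n + 1
            if b1 > b0 + 1:
                m[b0 + 1 : b1] += d_n
    bins = []
    for i in range(n_bins):
        start = segment.start + i * d_n
        end = min(segment.start + (i + 1) * d_n - 1, segment.end)
        bins.append(
            DensityBin(
                segment_name=segment.name,
                index_i=i + 1,
                start=start,
                end=end,
                unit_size=d_n,
                m_i=int(m[i]),
            )
        )
    return bins


def profile(
    segments: list[SequencedSegment],
    ssrs: list[SSRRecord],
    d_n: int,
) -> DensityProfile:
    """Per-bin densities over all segments plus global RD and SD(pD_nRD).

    Bins restart at each segment; gaps are never binned. The global RD is
    computed over the covered (sequenced) base pairs, and the SD is the
    population standard deviation of the per-bin normalized densities.
    """
    by_seg: dict[str, list[SSRRecord]] = {}
    for r in ssrs:
        by_seg.setdefault(r.segment_name, []).append(r)
    bins: list[DensityBin] = []
    for seg in segments:
        bins.extend(bin_segment(seg, by_seg.get(seg.name, []), d_n))
    total_bp = sum(s.size for s in segments)
    total_m = sum(b.m_i for b in bins)
    rd = global_rd(total_m, total_bp) if total_bp else 0.0
    densities = np.array([b.pdnrd_norm for b in bins]) if bins else np.array([0.0])
    return DensityProfile(
        resolution=d_n,
        bins=bins,
        global_rd=rd,
        sd_pdnrd=float(np.std(densities)),
    )


def bins_to_frame(bins: list[DensityBin]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "segment": b.segment_name,
                "i": b.index_i,
                "start": b.start,
                "end": b.end,
                "size": b.size,
                "m_i": b.m_i,
                "pdnrd": round(b.pdnrd, 2),
                "pdnrd_norm": round(b.pdnrd_norm, 2),
            }
            for b in bins
        ],
        columns=["segment", "i", "start", "end", "size", "m_i", "pdnrd", "pdnrd_norm"],
    )


def write_profile(prof: DensityProfile, out_dir: str | Path, chrom: str) -> None:
    """Write per-bin TSV and a bedGraph track for browser loading."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bins_to_frame(prof.bins).to_csv(
        out_dir / f"bins_D{prof.resolution}.tsv", sep="\t", index=False
    )
    with open(out_dir / f"density_D{prof.resolution}.bedgraph", "w") as fh:
        for b in prof.bins:
            fh.write(f"{chrom}\t{b.start - 1}\t{b.end}\t{b.pdnrd_norm:.2f}\n")
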