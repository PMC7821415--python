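"""Density peaks, extremely-low-density regions and motif clusters.

Peaks are individual 1 kb bins whose density stands well above the
chromosome average, graded into four levels:

    sHP  pD_1RD >= 425    super high
    HP   300 <= pD_1RD < 425
    MP   150 <= pD_1RD < 300
    LP    90 <= pD_1RD < 150

At the opposite extreme, runs of consecutive sparse bins form extremely
low density regions: bELR (aggregate RD < 25, size >= 100 kb), sELR
(RD < 25, 3 kb <= size < 100 kb) and ZD deserts (every bin exactly zero,
size <= 2 kb). The size bounds dovetail: a zero run of one or two 1 kb
bins is a desert, a longer sparse run is an ELR, and a desert is never
double-reported inside an ELR.

Clusters are maximal runs of >= 3 consecutive SSRs sharing a rotation
class with no other class interleaved: Clu (n >= 26), MClu (9 <= n < 26),
mClu (3 <= n < 9).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ssrscape.density import DENSITY_SCALE, DensityBin
from ssrscape.ssr_detect import SSRRecord

#: peak level lower bounds on pD_1RD, highest first
PEAK_LEVELS = (("sHP", 425.0), ("HP", 300.0), ("MP", 150.0), ("LP", 90.0))
#: density ceiling for extremely-low-density regions
ELR_RD_MAX = 25.0
BELR_MIN_SIZE = 100_000
SELR_MIN_SIZE = 3_000
ZD_MAX_SIZE = 2_000
#: cluster level lower bounds on member count, highest first
CLUSTER_LEVELS = (("Clu", 26), ("MClu", 9), ("mClu", 3))


@dataclass(frozen=True)
class PeakCall:
    bin: DensityBin
    level: str


@dataclass(frozen=True)
class ELRCall:
    segment_name: str
    start: int
    end: int
    rd: float
    kind: str  # bELR | sELR | ZD

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClusterCall:
    motif_class: str
    members: tuple[SSRRecord, ...]
    level: str

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def span(self) -> tuple[int, int]:
        return self.members[0].start, self.members[-1].end


def peak_level(density: float) -> str | None:
    """Level name for a 1 kb bin density, or None below the LP floor."""
    for name, floor in PEAK_LEVELS:
        if density >= floor:
            return name
    return None


def _require_1kb(bins: list[DensityBin]) -> None:
    if any(b.unit_size != 1000 for b in bins):
        raise ValueError("peak and ELR thresholds are defined at 1 kb resolution")


def call_peaks(bins: list[DensityBin]) -> list[PeakCall]:
    """One PeakCall per 1 kb bin with density >= 90 (no plateau merging)."""
    _require_1kb(bins)
    calls = []
    for b in bins:
        level = peak_level(b.pdnrd_norm)
        if level is not None:
            calls.append(PeakCall(bin=b, level=level))
    return calls


def call_elrs(bins: list[DensityBin]) -> list[ELRCall]:
    """Extremely-low-density regions from 1 kb bins.

    Within each segment, maximal runs of consecutive bins with density
    < 25 are collected. A run of total size >= 3 kb whose aggregate RD is
    < 25 becomes an ELR (bELR at >= 100 kb, else sELR); otherwise any
    maximal zero-density sub-run of size <= 2 kb becomes a ZD desert.
    Segment edges close open runs; a single above-threshold bin terminates
    a run.
    """
    _require_1kb(bins)
    calls: list[ELRCall] = []
    by_seg: dict[str, list[DensityBin]] = {}
    for b in bins:
        by_seg.setdefault(b.segment_name, []).append(b)
    for seg_name, seg_bins in by_seg.items():
        seg_bins = sorted(seg_bins, key=lambda b: b.start)
        run: list[DensityBin] = []
        for b in seg_bins + [None]:  # type: ignore[list-item]
            if b is not None and b.pdnrd_norm < ELR_RD_MAX:
                run.append(b)
                continue
            if run:
                calls.extend(_classify_low_run(seg_name, run))
                run = []
    calls.sort(key=lambda c: c.start)
    return calls


def _classify_low_run(seg_name: str, run: list[DensityBin]) -> list[ELRCall]:
    size = sum(b.size for b in run)
    m = sum(b.m_i for b in run)
    rd = m / size * DENSITY_SCALE
    if size >= SELR_MIN_SIZE and rd < ELR_RD_MAX:
        kind = "bELR" if size >= BELR_MIN_SIZE else "sELR"
        return [ELRCall(seg_name, run[0].start, run[-1].end, rd, kind)]
    # short sparse run: report maximal zero sub-runs as deserts
    out: list[ELRCall] = []
    zero: list[DensityBin] = []
    for b in run + [None]:  # type: ignore[list-item]
        if b is not None and b.m_i == 0:
            zero.append(b)
            continue
        if zero:
            zsize = sum(z.size for z in zero)
            if zsize <= ZD_MAX_SIZE:
                out.append(ELRCall(seg_name, zero[0].start, zero[-1].end, 0.0, "ZD"))
            zero = []
    return out


def call_clusters(
    ssrs: list[SSRRecord],
    max_gap: int | None = None,
    strict_motif: bool = False,
) -> list[ClusterCall]:
    """Maximal runs of >= 3 consecutive same-class SSRs.

    ``ssrs`` must be sorted by start. A run breaks when the next SSR has a
    different rotation class (or, with ``strict_motif``, a different
    literal motif), lies in a different segment, or starts more than
    ``max_gap`` bp after the previous SSR ends (default: unlimited).
    """
    key = (lambda r: r.motif) if strict_motif else (lambda r: r.motif_class)
    calls: list[ClusterCall] = []
    run: list[SSRRecord] = []
    for r in ssrs:
        if run and (
            key(r) != key(run[-1])
            or r.segment_name != run[-1].segment_name
            or (max_gap is not None and r.start - run[-1].end - 1 > max_gap)
        ):
            _close_cluster_run(run, key, calls)
            run = []
        run.append(r)
    _close_cluster_run(run, key, calls)
    return calls


def _close_cluster_run(run, key, calls: list[ClusterCall]) -> None:
    if len(run) < CLUSTER_LEVELS[-1][1]:
        return
    for level, floor in CLUSTER_LEVELS:
        if len(run) >= floor:
            calls.append(
                ClusterCall(motif_class=key(run[0]), members=tuple(run), level=level)
            )
            return


def cluster_level(n: int) -> str | None:
    for level, floor in CLUSTER_LEVELS:
        if n >= floor:
            return level
    return None


def peaks_to_frame(peaks: list[PeakCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "segment": p.bin.segment_name,
                "start": p.bin.start,
                "end": p.bin.end,
                "pdnrd": round(p.bin.pdnrd_norm, 2),
                "level": p.level,
            }
            for p in peaks
        ],
        columns=["segment", "start", "end", "pdnrd", "level"],
    )


def elrs_to_frame(elrs: list[ELRCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "segment": e.segment_name,
                "start": e.start,
                "end": e.end,
                "size": e.size,
                "rd": round(e.rd, 2),
                "kind": e.kind,
            }
            for e in elrs
        ],
        columns=["segment", "start", "end", "size", "rd", "kind"],
    )


def clusters_to_frame(clusters: list[ClusterCall]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        start, end = c.span
        gaps = [
            c.members[i + 1].start - c.members[i].end - 1
            for i in range(c.n_members - 1)
        ]
        rows.append(
            {
                "motif_class": c.motif_class,
                "n_members": c.n_members,
                "start": start,
                "end": end,
                "level": c.level,
                "mean_spacing": round(sum(gaps) / len(gaps), 1) if gaps else 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["motif_class", "n_members", "start", "end", "level", "mean_spacing"],
    )


def write_features(
    peaks: list[PeakCall],
    elrs: list[ELRCall],
    clusters: list[ClusterCall],
    out_dir: str | Path,
    chrom: str,
) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    peaks_to_frame(peaks).to_csv(out_dir / "peaks.tsv", sep="\t", index=False)
    elrs_to_frame(elrs).to_csv(out_dir / "elrs.tsv", sep="\t", index=False)
    clusters_to_frame(clusters).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    with open(out_dir / "peaks.bed", "w") as fh:
        for p in peaks:
            fh.write(
                f"{chrom}\t{p.bin.start - 1}\t{p.bin.end}\t{p.level}\t"
                f"{int(round(p.bin.pdnrd_norm))}\t+\n"
            )
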