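"""Zone partitioning, map typing and landscape rendering.

Each large segment's 1 kb bins are tiled into *zones* of 51 bins, with one
bin shared between neighbouring zones, so that consecutive landscape maps
overlap by exactly one bin. Zones are labelled Z001, Z002, ... within a
segment (e.g. S4-Z003). Segments whose bins fit in a single window form
one unnormal-size zone labelled by the segment name, and very short
segments (< 10 kb) are pooled into a single integrated zone.

Every zone receives exactly one map type under a fixed precedence:

    Penta  pentanucleotide SSR bp dominate (> half of the zone's SSR bp)
    HML    at least one super-high or high peak (mix of high/middle/low)
    ML     middle peaks but nothing higher
    L      only low peaks
    EL     every bin below the extremely-low ceiling
    AV     no peaks, densities near the chromosome average (default)

The quantitative thresholds live in :class:`MapTypeRule` and are
deliberately configurable: the type names describe qualitative looks of
the landscape and users may recalibrate the rule for other chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from ssrscape.density import DensityBin
from ssrscape.features import ELR_RD_MAX, PeakCall
from ssrscape.sequence_io import SequencedSegment
from ssrscape.ssr_detect import SSRRecord

#: bins per normal zone; neighbouring zones share one bin
ZONE_BINS = 51
#: segments below this size are pooled into one integrated map
INTEGRATE_BELOW = 10_000

MAP_TYPES = ("HML", "ML", "L", "Penta", "AV", "EL")

_LEVEL_COLORS = {
    "sHP": "#b2182b",
    "HP": "#ef8a62",
    "MP": "#fddbc7",
    "LP": "#d1e5f0",
    None: "#999999",
}


@dataclass
class Zone:
    label: str
    segment_name: str
    bins: list[DensityBin]
    map_type: str | None = None
    is_integrated: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return self.bins[0].start, self.bins[-1].end


@dataclass(frozen=True)
class MapTypeRule:
    """Thresholds for the Penta / AV / EL map types.

    ``penta_bp_fraction``: a zone is Penta when pentanucleotide SSR bp
    exceed this fraction of the zone's SSR bp. ``el_ceiling``: a zone is
    EL when every bin density is below it (same floor as ELR calling).
    ``av_band``: relative half-width of the near-average band around the
    global RD (kept for reporting; AV is the default fallback type).
    """

    penta_bp_fraction: float = 0.5
    el_ceiling: float = ELR_RD_MAX
    av_band: float = 0.5


def make_zones(
    segments: list[SequencedSegment], bins: list[DensityBin]
) -> list[Zone]:
    """Partition 1 kb bins into 51-bin zones with one-bin overlap.

    Segments < 10 kb are pooled into one integrated zone; segments whose
    bins fit within a single window form one zone labelled by segment
    name; larger segments tile into Z001, Z002, ... advancing 50 bins per
    zone, the final zone possibly short.
    """
    if any(b.unit_size != 1000 for b in bins):
        raise ValueError("zones are defined over 1 kb bins")
    by_seg: dict[str, list[DensityBin]] = {}
    for b in bins:
        by_seg.setdefault(b.segment_name, []).append(b)
    zones: list[Zone] = []
    pooled: list[DensityBin] = []
    pooled_names: list[str] = []
    for seg in segments:
        seg_bins = sorted(by_seg.get(seg.name, []), key=lambda b: b.start)
        if not seg_bins:
            continue
        if seg.size < INTEGRATE_BELOW:
            pooled.extend(seg_bins)
            pooled_names.append(seg.name)
            continue
        if len(seg_bins) <= ZONE_BINS:
            zones.append(Zone(label=seg.name, segment_name=seg.name, bins=seg_bins))
            continue
        start = 0
        k = 0
        while start < len(seg_bins) - 1:
            k += 1
            zones.append(
                Zone(
                    label=f"{seg.name}-Z{k:03d}",
                    segment_name=seg.name,
                    bins=seg_bins[start : start + ZONE_BINS],
                )
            )
            start += ZONE_BINS - 1
    if pooled:
        zones.append(
            Zone(
                label="+".join(pooled_names),
                segment_name="+".join(pooled_names),
                bins=pooled,
                is_integrated=True,
            )
        )
    return zones


def classify_map(
    zone: Zone,
    peaks: list[PeakCall],
    global_rd: float,
    rule: MapTypeRule | None = None,
    ssrs: list[SSRRecord] | None = None,
) -> str:
    """Assign one map type to a zone (precedence Penta > HML > ML > L > EL > AV)."""
    if rule is None:
        rule = MapTypeRule()
    bin_keys = {(b.segment_name, b.start) for b in zone.bins}
    levels = {
        p.level for p in peaks if (p.bin.segment_name, p.bin.start) in bin_keys
    }
    if ssrs is not None:
        lo, hi = zone.span
        zone_ssrs = [
            r
            for r in ssrs
            if r.segment_name in {b.segment_name for b in zone.bins}
            and r.start <= hi
            and r.end >= lo
        ]
        total_bp = sum(r.length for r in zone_ssrs)
        penta_bp = sum(r.length for r in zone_ssrs if r.unit_len == 5)
        if total_bp > 0 and penta_bp / total_bp > rule.penta_bp_fraction:
            return "Penta"
    if "sHP" in levels or "HP" in levels:
        return "HML"
    if "MP" in levels:
        return "ML"
    if "LP" in levels:
        return "L"
    if all(b.pdnrd_norm < rule.el_ceiling for b in zone.bins):
        return "EL"
    return "AV"


def _parse_bed_genes(path: Path) -> list[tuple[int, int, str]]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = []
    for _, row in df.iterrows():
        name = str(row[3]) if df.shape[1] > 3 else "gene"
        out.append((int(row[1]) + 1, int(row[2]), name))
    return out


def _parse_gff3_genes(path: Path) -> list[tuple[int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in ("gene", "ncRNA_gene", "pseudogene"):
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("Name", attrs.get("ID", "gene"))
            out.append((int(parts[3]), int(parts[4]), name))
    return out


def load_gene_annotations(path: str | Path) -> list[tuple[int, int, str]]:
    """Gene-level intervals (1-based) from a GFF3 or BED file."""
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _parse_gff3_genes(path)
    return _parse_bed_genes(path)


def render_map(
    zone: Zone,
    out_path: str | Path,
    global_rd: float,
    peaks: list[PeakCall] | None = None,
    annotations: list[tuple[int, int, str]] | None = None,
    fmt: str = "svg",
) -> Path:
    """Render one landscape map: per-bin density bars, average line, genes.

    Output is deterministic for fixed inputs (SVG hash metadata stripped).
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    level_by_bin: dict[tuple[str, int], str] = {}
    for p in peaks or []:
        level_by_bin[(p.bin.segment_name, p.bin.start)] = p.level

    # fixed hash salt keeps SVG element ids reproducible across runs
    plt.rcParams["svg.hashsalt"] = "ssrscape"
    fig, ax = plt.subplots(figsize=(10, 3.2))
    xs = [(b.start + b.end) / 2 for b in zone.bins]
    heights = [b.pdnrd_norm for b in zone.bins]
    widths = [b.size * 0.9 for b in zone.bins]
    colors = [
        _LEVEL_COLORS[level_by_bin.get((b.segment_name, b.start))] for b in zone.bins
    ]
    ax.bar(xs, heights, width=widths, color=colors, edgecolor="none")
    ax.axhline(global_rd, color="black", lw=0.8, ls="--", label=f"RD={global_rd:.2f}")
    seen = set()
    for lvl in ("sHP", "HP", "MP", "LP"):
        if lvl in level_by_bin.values() and lvl not in seen:
            ax.bar([], [], color=_LEVEL_COLORS[lvl], label=lvl)
            seen.add(lvl)
    lo, hi = zone.span
    if annotations:
        ymax = max(heights + [global_rd]) or 1.0
        for gstart, gend, gname in annotations:
            if gend < lo or gstart > hi:
                continue
            ax.hlines(-0.06 * ymax, max(gstart, lo), min(gend, hi), color="darkgreen", lw=3)
            ax.annotate(
                gname,
                ((max(gstart, lo) + min(gend, hi)) / 2, -0.12 * ymax),
                ha="center",
                va="top",
                fontsize=6,
                color="darkgreen",
                annotation_clip=False,
            )
    ax.set_xlim(lo - 1, hi + 1)
    ax.set_xlabel("chromosome position (bp)")
    ax.set_ylabel("pD$_1$RD")
    title = zone.label + (f"  [{zone.map_type}]" if zone.map_type else "")
    ax.set_title(title, fontsize=10)
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    target = out_path.with_suffix(f".{fmt}")
    fig.savefig(target, format=fmt, metadata={"Date": None} if fmt == "svg" else None)
    plt.close(fig)
    return target


def zones_to_frame(zones: list[Zone]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": z.label,
                "segment": z.segment_name,
                "start": z.span[0],
                "end": z.span[1],
                "n_bins": len(z.bins),
                "map_type": z.map_type,
                "integrated": z.is_integrated,
            }
            for z in zones
        ],
        columns=["label", "segment", "start", "end", "n_bins", "map_type", "integrated"],
    )


def map_type_summary(zones: list[Zone]) -> pd.DataFrame:
    counts = {t: 0 for t in MAP_TYPES}
    for z in zones:
        if z.map_type:
            counts[z.map_type] += 1
    return pd.DataFrame(
        [{"map_type": t, "n_maps": n} for t, n in counts.items()]
    )
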