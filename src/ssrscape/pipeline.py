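"""End-to-end orchestration: segments -> detect -> density -> features -> maps."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from ssrscape import density, features, maps, sequence_io, ssr_detect

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    resolutions: tuple[int, ...] = (1000,)
    min_gap_len: int = 1
    record_id: str | None = None
    detection: ssr_detect.DetectionConfig = field(
        default_factory=ssr_detect.DetectionConfig
    )
    cluster_max_gap: int | None = None
    cluster_strict_motif: bool = False
    map_rule: maps.MapTypeRule = field(default_factory=maps.MapTypeRule)
    render_figures: bool = False
    figure_format: str = "svg"
    annotation_path: str | None = None

    def __post_init__(self) -> None:
        if any(r < 1 for r in self.resolutions):
            raise ValueError("resolutions must be positive")
        object.__setattr__(self, "resolutions", tuple(sorted(set(self.resolutions))))


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def run_all(fasta: str | Path, out_dir: str | Path, config: RunConfig | None = None) -> dict:
    """Run the full landscape pipeline and write the output tree.

    Returns the summary dictionary also written to ``summary.json``.
    """
    if config is None:
        config = RunConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info("thresholds: min_copies=%s, peaks=%s, elr<%s, clusters=%s",
                config.detection.min_copies_by_unit, features.PEAK_LEVELS,
                features.ELR_RD_MAX, features.CLUSTER_LEVELS)

    try:
        seq = sequence_io.read_fasta(fasta, record_id=config.record_id)
        segments, gaps = sequence_io.find_segments(seq, min_gap_len=config.min_gap_len)
        sequence_io.write_segments(segments, gaps, out_dir / "segments", seq.identifier)
        summary_tbl = sequence_io.segment_summary(segments)
    except Exception as e:  # noqa: BLE001
        raise StageError("sequence_io", e) from e

    try:
        ssrs = ssr_detect.detect_ssrs(seq, segments, config.detection)
        n_ssrs, ssr_bp, per_unit = ssr_detect.ssr_totals(ssrs)
        ssr_detect.write_ssrs(ssrs, out_dir / "ssrs.tsv", seq.identifier, gff=True)
    except Exception as e:  # noqa: BLE001
        raise StageError("ssr_detect", e) from e

    profiles = {}
    try:
        for d_n in config.resolutions:
            prof = density.profile(segments, ssrs, d_n)
            density.write_profile(prof, out_dir / f"profile_D{d_n}", seq.identifier)
            profiles[d_n] = prof
        base = profiles.get(1000) or density.profile(segments, ssrs, 1000)
    except Exception as e:  # noqa: BLE001
        raise StageError("density", e) from e

    try:
        peaks = features.call_peaks(base.bins)
        elrs = features.call_elrs(base.bins)
        clusters = features.call_clusters(
            ssrs, max_gap=config.cluster_max_gap, strict_motif=config.cluster_strict_motif
        )
        features.write_features(peaks, elrs, clusters, out_dir / "features", seq.identifier)
    except Exception as e:  # noqa: BLE001
        raise StageError("features", e) from e

    try:
        annotations = (
            maps.load_gene_annotations(config.annotation_path)
            if config.annotation_path
            else None
        )
        zones = maps.make_zones(segments, base.bins)
        for z in zones:
            z.map_type = maps.classify_map(
                z, peaks, base.global_rd, config.map_rule, ssrs=ssrs
            )
        maps.zones_to_frame(zones).to_csv(out_dir / "zones.tsv", sep="\t", index=False)
        maps.map_type_summary(zones).to_csv(
            out_dir / "map_types.tsv", sep="\t", index=False
        )
        if config.render_figures:
            fig_dir = out_dir / "maps"
            for z in zones:
                maps.render_map(
                    z,
                    fig_dir / z.label.replace("+", "_"),
                    base.global_rd,
                    peaks=peaks,
                    annotations=annotations,
                    fmt=config.figure_format,
                )
    except Exception as e:  # noqa: BLE001
        raise StageError("maps", e) from e

    large = summary_tbl[summary_tbl.size_class == "large"].iloc[0]
    summary = {
        "sequence": seq.identifier,
        "sequence_length": seq.length,
        "n_segments": len(segments),
        "n_gaps": len(gaps),
        "large_segments": {"n": int(large.n_segments), "total_bp": int(large.total_bp)},
        "n_ssrs": n_ssrs,
        "ssr_bp": ssr_bp,
        "ssrs_per_unit_size": {
            int(r.unit_len): int(r.n_ssrs) for r in per_unit.itertuples()
        },
        "global_rd": round(base.global_rd, 2),
        "sd_pdnrd_by_resolution": {
            str(d): round(p.sd_pdnrd, 2) for d, p in profiles.items()
        },
        "n_peaks": len(peaks),
        "peaks_by_level": {
            lvl: sum(1 for p in peaks if p.level == lvl)
            for lvl, _ in features.PEAK_LEVELS
        },
        "elrs_by_kind": {
            k: sum(1 for e in elrs if e.kind == k) for k in ("bELR", "sELR", "ZD")
        },
        "n_clusters": len(clusters),
        "clusters_by_level": {
            lvl: sum(1 for c in clusters if c.level == lvl)
            for lvl, _ in features.CLUSTER_LEVELS
        },
        "n_zones": len(zones),
        "map_types": {
            t: sum(1 for z in zones if z.map_type == t) for t in maps.MAP_TYPES
        },
    }
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
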