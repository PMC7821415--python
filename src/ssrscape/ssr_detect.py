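"""Perfect microsatellite (SSR) detection.

An SSR is a maximal perfect tandem run of a 1-6 bp unit. Detection follows
the classic copy-number-threshold convention: a run qualifies when it holds
at least 6 complete copies of a mononucleotide unit or 3 complete copies of
a 2-6 bp unit (configurable). A maximal run may end mid-unit; those trailing
partial-unit bases count toward the SSR length but not toward its copy
number (``allow_partial_tail``).

Motifs are grouped into rotation classes: CT and TC describe the same
repeat read in different phase, so both map to the canonical class ``CT``
(the lexicographically smallest cyclic rotation). Detection is plus-strand
only; reverse complements (CT vs GA) are distinct classes.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ssrscape.sequence_io import AssemblySequence, SequencedSegment, find_segments

#: minimum complete copies for unit sizes 1..6
DEFAULT_MIN_COPIES = (6, 3, 3, 3, 3, 3)

_N_BYTE = ord("N")


def _smallest_period(motif: str) -> int:
    return (motif + motif).index(motif, 1)


def is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number repetition of a shorter unit."""
    return _smallest_period(motif) == len(motif)


def canonical_class(motif: str) -> str:
    """Lexicographically smallest cyclic rotation of a primitive motif.

    All rotations of a motif map to the same class (e.g. TC -> CT,
    GAAA -> AAAG). Motifs containing N or non-primitive motifs are rejected.
    """
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


@dataclass(frozen=True)
class SSRRecord:
    """One perfect microsatellite, absolute 1-based inclusive coordinates."""

    motif: str
    unit_len: int
    copies: int
    start: int
    end: int
    motif_class: str
    segment_name: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DetectionConfig:
    min_copies_by_unit: tuple[int, ...] = DEFAULT_MIN_COPIES
    #: include trailing partial-unit bases in SSR length (not in copies)
    allow_partial_tail: bool = True

    def __post_init__(self) -> None:
        if len(self.min_copies_by_unit) != 6 or any(
            c < 1 for c in self.min_copies_by_unit
        ):
            raise ValueError("min_copies_by_unit must be 6 integers >= 1")


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _detect_in_segment(
    sub: str, seg: SequencedSegment, config: DetectionConfig
) -> list[SSRRecord]:
    arr = np.frombuffer(sub.encode("ascii"), dtype=np.uint8)
    records: list[SSRRecord] = []
    # accepted intervals of smaller unit sizes, for the containment rule
    accepted_starts: list[int] = []
    accepted_prefix_max_end: list[int] = []

    for u, min_copies in enumerate(config.min_copies_by_unit, start=1):
        if len(arr) < u * min_copies:
            continue
        eq = (arr[u:] == arr[:-u]) & (arr[u:] != _N_BYTE)
        min_eq_run = u * (min_copies - 1)
        level: list[SSRRecord] = []
        for i, j in _runs_of_true(eq):
            total = (j - i) + u  # maximal run length incl. partial tail
            copies = total // u
            if copies < min_copies or (j - i) < max(min_eq_run, 1):
                continue
            motif = sub[i : i + u]
            if "N" in motif or not is_primitive(motif):
                continue
            length = total if config.allow_partial_tail else copies * u
            start_abs = seg.start + i
            end_abs = start_abs + length - 1
            # drop candidates wholly inside an accepted smaller-unit repeat
            k = bisect.bisect_right(accepted_starts, start_abs)
            if k > 0 and accepted_prefix_max_end[k - 1] >= end_abs:
                continue
            level.append(
                SSRRecord(
                    motif=motif,
                    unit_len=u,
                    copies=copies,
                    start=start_abs,
                    end=end_abs,
                    motif_class=canonical_class(motif),
                    segment_name=seg.name,
                )
            )
        if level:
            records.extend(level)
            # rebuild the containment index over all accepted intervals
            ivs = sorted((r.start, r.end) for r in records)
            accepted_starts = [s for s, _ in ivs]
            accepted_prefix_max_end = []
            mx = 0
            for _, e in ivs:
                mx = max(mx, e)
                accepted_prefix_max_end.append(mx)
    records.sort(key=lambda r: (r.start, r.unit_len))
    return records


def detect_ssrs(
    seq: AssemblySequence,
    segments: list[SequencedSegment] | None = None,
    config: DetectionConfig | None = None,
) -> list[SSRRecord]:
    """Find all maximal perfect SSRs meeting the copy-number thresholds.

    Repeats are detected within each sequenced segment independently and
    never span a gap. Unit sizes are scanned 1 to 6; a candidate whose
    interval lies entirely within an already-accepted repeat of smaller
    unit size is redundant and dropped (a poly-A run is not also reported
    as an AA repeat); partially overlapping repeats of different unit
    sizes are both kept. Output is sorted by start coordinate.
    """
    if config is None:
        config = DetectionConfig()
    if segments is None:
        segments, _ = find_segments(seq)
    records: list[SSRRecord] = []
    for seg in segments:
        sub = seq.residues[seg.start - 1 : seg.end]
        records.extend(_detect_in_segment(sub, seg, config))
    records.sort(key=lambda r: (r.start, r.unit_len))
    return records


def ssr_totals(ssrs: list[SSRRecord]) -> tuple[int, int, pd.DataFrame]:
    """Total count, total bp, and a per-unit-size breakdown table."""
    count = len(ssrs)
    total_bp = sum(r.length for r in ssrs)
    rows = []
    for u in range(1, 7):
        members = [r for r in ssrs if r.unit_len == u]
        rows.append(
            {
                "unit_len": u,
                "n_ssrs": len(members),
                "total_bp": sum(r.length for r in members),
            }
        )
    return count, total_bp, pd.DataFrame(rows)


def ssrs_to_frame(ssrs: list[SSRRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "segment": r.segment_name,
                "start": r.start,
                "end": r.end,
                "motif": r.motif,
                "motif_class": r.motif_class,
                "unit_len": r.unit_len,
                "copies": r.copies,
                "length": r.length,
            }
            for r in ssrs
        ],
        columns=[
            "segment",
            "start",
            "end",
            "motif",
            "motif_class",
            "unit_len",
            "copies",
            "length",
        ],
    )


def write_ssrs(
    ssrs: list[SSRRecord], out_path: str | Path, chrom: str, gff: bool = False
) -> None:
    """Write the SSR table as TSV, plus BED and optional GFF3 beside it."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    ssrs_to_frame(ssrs).to_csv(out_path, sep="\t", index=False)
    with open(out_path.with_suffix(".bed"), "w") as fh:
        for r in ssrs:
            fh.write(
                f"{chrom}\t{r.start - 1}\t{r.end}\t({r.motif}){r.copies}\t0\t+\n"
            )
    if gff:
        with open(out_path.with_suffix(".gff3"), "w") as fh:
            fh.write("##gff-version 3\n")
            for i, r in enumerate(ssrs, 1):
                fh.write(
                    f"{chrom}\tssrscape\tmicrosatellite\t{r.start}\t{r.end}\t.\t+\t.\t"
                    f"ID=ssr{i};motif={r.motif};motif_class={r.motif_class};"
                    f"copies={r.copies}\n"
                )
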