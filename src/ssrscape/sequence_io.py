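"""Assembly ingest and gap/segment decomposition.

A chromosome assembly is modelled as a single residue string over
``{A, C, G, T, N}``. Runs of ``N`` are unsequenced gaps; the maximal
non-N runs between them are the *sequenced segments*, named ``S1..Sk``
in coordinate order and classed as *large* (>= 100 kb) or *small*.
All coordinates are 1-based inclusive; BED export converts to 0-based
half-open.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: size boundary between large and small sequenced segments (bp)
LARGE_SEGMENT_MIN = 100_000

_VALID = set("ACGTN")
_AMBIG_RE = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class AssemblySequence:
    """One assembly sequence after normalization (uppercase, ACGTN only)."""

    identifier: str
    residues: str

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequencedSegment:
    """A maximal gap-free stretch of the assembly, 1-based inclusive."""

    name: str
    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    @property
    def size_class(self) -> str:
        return "large" if self.size >= LARGE_SEGMENT_MIN else "small"


@dataclass(frozen=True)
class GapRegion:
    """A maximal run of N characters, 1-based inclusive."""

    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start + 1


def normalize_residues(raw: str) -> tuple[str, int]:
    """Uppercase and map non-N IUPAC ambiguity codes to N.

    Returns the normalized string and the number of ambiguity characters
    that were mapped. Characters outside the IUPAC alphabet are rejected.
    """
    up = raw.upper()
    n_ambig = 0
    if set(up) - _VALID:
        bad = set(up) - set("ACGTNRYSWKMBDHV")
        if bad:
            raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)!r}")
        up, n_ambig = _AMBIG_RE.subn("N", up)
    return up, n_ambig


def read_fasta(path: str | Path, record_id: str | None = None) -> AssemblySequence:
    """Read one record from a FASTA file (plain or gzip).

    By default the first record is used; pass ``record_id`` to select a
    specific one from a multi-record file. Residues are uppercased and any
    IUPAC ambiguity code other than N is mapped to N (count logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if record_id is None or rec.id == record_id:
                residues, n_ambig = normalize_residues(str(rec.seq))
                if not residues:
                    raise ValueError(f"record {rec.id!r} in {path} is empty")
                if n_ambig:
                    logger.info(
                        "mapped %d ambiguity bases to N in record %s", n_ambig, rec.id
                    )
                return AssemblySequence(identifier=rec.id, residues=residues)
    if record_id is not None:
        raise ValueError(f"no record {record_id!r} in {path}")
    raise ValueError(f"no FASTA records in {path}")


def find_segments(
    seq: AssemblySequence, min_gap_len: int = 1
) -> tuple[list[SequencedSegment], list[GapRegion]]:
    """Split an assembly into sequenced segments and gaps.

    Gaps are maximal runs of N of size >= ``min_gap_len``; shorter N runs
    are absorbed into the enclosing segment (and logged). Segments are the
    maximal non-gap runs, named S1..Sk in coordinate order. Leading and
    trailing N runs count as gaps. An all-N sequence yields zero segments
    and one gap.
    """
    if seq.length == 0:
        raise ValueError("empty sequence")
    gaps: list[GapRegion] = []
    n_absorbed = 0
    for m in re.finditer(r"N+", seq.residues):
        if m.end() - m.start() >= min_gap_len:
            gaps.append(GapRegion(start=m.start() + 1, end=m.end()))
        else:
            n_absorbed += 1
    if n_absorbed:
        logger.info("absorbed %d N-runs shorter than %d bp", n_absorbed, min_gap_len)

    segments: list[SequencedSegment] = []
    cursor = 1
    for gap in gaps:
        if gap.start > cursor:
            segments.append(
                SequencedSegment(name=f"S{len(segments) + 1}", start=cursor, end=gap.start - 1)
            )
        cursor = gap.end + 1
    if cursor <= seq.length:
        segments.append(
            SequencedSegment(name=f"S{len(segments) + 1}", start=cursor, end=seq.length)
        )
    return segments, gaps


def segment_summary(segments: list[SequencedSegment]) -> pd.DataFrame:
    """Per-size-class segment counts, total bp and fraction of sequenced bp."""
    if not segments:
        raise ValueError("no segments")
    total = sum(s.size for s in segments)
    rows = []
    for cls in ("large", "small"):
        members = [s for s in segments if s.size_class == cls]
        bp = sum(s.size for s in members)
        rows.append(
            {
                "size_class": cls,
                "n_segments": len(members),
                "total_bp": bp,
                "fraction": bp / total,
            }
        )
    return pd.DataFrame(rows)


def segments_to_frame(segments: list[SequencedSegment]) -> pd.DataFrame:
    """Segments as a table with 1-based coordinates."""
    return pd.DataFrame(
        [
            {
                "name": s.name,
                "start": s.start,
                "end": s.end,
                "size": s.size,
                "size_class": s.size_class,
            }
            for s in segments
        ]
    )


def write_segments(
    segments: list[SequencedSegment],
    gaps: list[GapRegion],
    out_dir: str | Path,
    chrom: str,
) -> None:
    """Write segments and gaps as TSV (1-based) and BED (0-based half-open)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    segments_to_frame(segments).to_csv(out_dir / "segments.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"start": g.start, "end": g.end, "size": g.size} for g in gaps]
    ).to_csv(out_dir / "gaps.tsv", sep="\t", index=False)
    with open(out_dir / "segments.bed", "w") as fh:
        for s in segments:
            fh.write(
                f"{chrom}\t{s.start - 1}\t{s.end}\t{s.name}\t0\t+\n"
            )
    with open(out_dir / "gaps.bed", "w") as fh:
        for i, g in enumerate(gaps, 1):
            fh.write(f"{chrom}\t{g.start - 1}\t{g.end}\tgap{i}\t0\t+\n")
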