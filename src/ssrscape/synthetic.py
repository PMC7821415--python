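"""Synthetic assemblies with known ground truth.

Generates a chromosome-like FASTA — N-gap-separated segments of mixed
sizes — whose repeat content is fully controlled: perfect SSR arrays of
unit size 1-6 planted at chosen offsets, regularly spaced same-rotation-
class cluster runs, high-density bins built from long planted arrays, and
SSR-free desert stretches. The background is order-0 random sequence that
is *SSR-suppressed*: any incidental run meeting the detection thresholds
is broken by rewriting its centre base, so every SSR the detector should
report is a planted one.

Generation is deterministic for a given seed (byte-identical FASTA), and
the ground truth (planted SSRs, expected per-bin SSR bp at 1 kb, expected
cluster calls) is emitted alongside for pipeline-recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ssrscape.sequence_io import AssemblySequence
from ssrscape.ssr_detect import (
    DetectionConfig,
    canonical_class,
    detect_ssrs,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedSSR:
    """One planted perfect array: segment index (0-based), 0-based offset."""

    segment: int
    offset: int
    motif: str
    copies: int

    @property
    def length(self) -> int:
        return len(self.motif) * self.copies


@dataclass(frozen=True)
class PlantedCluster:
    """A run of identical arrays of one rotation class at regular spacing."""

    segment: int
    offset: int
    motif: str
    copies: int
    n_members: int
    spacing: int  # background bp between consecutive members

    def member_offsets(self) -> list[int]:
        unit = len(self.motif) * self.copies
        return [self.offset + i * (unit + self.spacing) for i in range(self.n_members)]

    @property
    def span_length(self) -> int:
        unit = len(self.motif) * self.copies
        return self.n_members * unit + (self.n_members - 1) * self.spacing


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    segment_sizes: tuple[int, ...]
    gap_sizes: tuple[int, ...]  # one gap between consecutive segments
    planted_ssrs: tuple[PlantedSSR, ...] = ()
    planted_clusters: tuple[PlantedCluster, ...] = ()
    #: (segment, offset, size) intervals guaranteed SSR-free
    planted_deserts: tuple[tuple[int, int, int], ...] = ()
    background_freqs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    identifier: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.gap_sizes) != max(len(self.segment_sizes) - 1, 0):
            raise ValueError("need exactly one gap between consecutive segments")
        if abs(sum(self.background_freqs) - 1.0) > 1e-9:
            raise ValueError("background frequencies must sum to 1")


@dataclass(frozen=True)
class SyntheticResult:
    sequence: AssemblySequence
    ssr_truth: pd.DataFrame  # absolute 1-based coords of every planted SSR
    cluster_truth: pd.DataFrame
    desert_truth: pd.DataFrame


def _all_planted(spec: SyntheticSpec) -> list[PlantedSSR]:
    planted = list(spec.planted_ssrs)
    for clu in spec.planted_clusters:
        for off in clu.member_offsets():
            planted.append(
                PlantedSSR(
                    segment=clu.segment, offset=off, motif=clu.motif, copies=clu.copies
                )
            )
    return planted


def _validate(spec: SyntheticSpec, planted: list[PlantedSSR]) -> None:
    by_seg: dict[int, list[tuple[int, int]]] = {}
    for p in planted:
        if not 0 <= p.segment < len(spec.segment_sizes):
            raise ValueError(f"planted feature references segment {p.segment}")
        seg_size = spec.segment_sizes[p.segment]
        # one flank base on each side is reserved for run-boundary control
        if p.offset < 1 or p.offset + p.length > seg_size - 1:
            raise ValueError(
                f"planted {p.motif}x{p.copies} at offset {p.offset} does not fit "
                f"inside segment {p.segment} (size {seg_size})"
            )
        by_seg.setdefault(p.segment, []).append((p.offset, p.offset + p.length))
    for seg, ivs in by_seg.items():
        ivs.sort()
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0 + 2:  # need >=2 bp between arrays for boundary bases
                raise ValueError(
                    f"planted features overlap or touch in segment {seg}: "
                    f"({s0},{e0}) vs ({s1},{e1})"
                )
    for seg, off, size in spec.planted_deserts:
        for p in planted:
            if p.segment == seg and p.offset < off + size and p.offset + p.length > off:
                raise ValueError("planted SSR overlaps a desert interval")


def _suppressed_background(
    rng: np.random.Generator, size: int, freqs, config: DetectionConfig
) -> np.ndarray:
    """Random sequence with every threshold-passing run broken."""
    arr = rng.choice(_BASES, size=size, p=list(freqs))
    seq = AssemblySequence("bg", arr.tobytes().decode("ascii"))
    for _ in range(60):
        hits = detect_ssrs(seq, config=config)
        if not hits:
            return np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8).copy()
        buf = bytearray(seq.residues, "ascii")
        for h in hits:
            mid = (h.start + h.end) // 2 - 1  # 0-based
            cur = buf[mid]
            choices = [b for b in _BASES.tolist() if b != cur]
            buf[mid] = int(rng.choice(choices))
        seq = AssemblySequence("bg", buf.decode("ascii"))
    raise RuntimeError("background SSR suppression did not converge")


def _fix_flanks(buf: bytearray, p: PlantedSSR, rng: np.random.Generator) -> None:
    """Choose flanking bases so the planted run is maximal exactly as planted."""
    u = len(p.motif)
    a, b = p.offset, p.offset + p.length  # half-open, 0-based in segment
    # left flank must break period-u extension: buf[a-1] != buf[a-1+u]
    forbid = {buf[a - 1 + u]}
    if a >= 2:
        forbid.add(buf[a - 2])  # avoid seeding a new homopolymer
    buf[a - 1] = int(rng.choice([x for x in _BASES.tolist() if x not in forbid]))
    # right flank: buf[b] != buf[b-u]
    if b < len(buf):
        forbid = {buf[b - u]}
        if b + 1 < len(buf):
            forbid.add(buf[b + 1])
        buf[b] = int(rng.choice([x for x in _BASES.tolist() if x not in forbid]))


def generate(
    spec: SyntheticSpec, config: DetectionConfig | None = None
) -> SyntheticResult:
    """Build the synthetic assembly and its ground-truth tables.

    The returned sequence is verified: running the detector on it yields
    exactly the planted SSRs (interfering background is rewritten until
    this holds, or generation fails).
    """
    if config is None:
        config = DetectionConfig()
    rng = np.random.default_rng(spec.seed)
    planted = _all_planted(spec)
    _validate(spec, planted)

    seg_arrays: list[bytearray] = []
    seg_starts: list[int] = []  # absolute 1-based start of each segment
    pos = 1
    for i, size in enumerate(spec.segment_sizes):
        bg = _suppressed_background(rng, size, spec.background_freqs, config)
        buf = bytearray(bg.tobytes())
        for p in sorted((q for q in planted if q.segment == i), key=lambda q: q.offset):
            unit = p.motif.encode("ascii")
            buf[p.offset : p.offset + p.length] = unit * p.copies
        for p in sorted((q for q in planted if q.segment == i), key=lambda q: q.offset):
            _fix_flanks(buf, p, rng)
        seg_arrays.append(buf)
        seg_starts.append(pos)
        pos += size
        if i < len(spec.gap_sizes):
            pos += spec.gap_sizes[i]

    residues = _assemble(spec, seg_arrays)
    sequence = AssemblySequence(spec.identifier, residues)
    sequence = _verify_and_repair(sequence, spec, seg_arrays, seg_starts, planted, config, rng)

    truth_rows = []
    for p in sorted(planted, key=lambda q: (q.segment, q.offset)):
        start = seg_starts[p.segment] + p.offset
        truth_rows.append(
            {
                "segment_index": p.segment,
                "start": start,
                "end": start + p.length - 1,
                "motif": p.motif,
                "motif_class": canonical_class(p.motif),
                "unit_len": len(p.motif),
                "copies": p.copies,
                "length": p.length,
            }
        )
    ssr_truth = pd.DataFrame(
        truth_rows,
        columns=[
            "segment_index",
            "start",
            "end",
            "motif",
            "motif_class",
            "unit_len",
            "copies",
            "length",
        ],
    )
    cluster_truth = pd.DataFrame(
        [
            {
                "segment_index": c.segment,
                "motif_class": canonical_class(c.motif),
                "n_members": c.n_members,
                "start": seg_starts[c.segment] + c.offset,
                "end": seg_starts[c.segment] + c.offset + c.span_length - 1,
            }
            for c in spec.planted_clusters
        ],
        columns=["segment_index", "motif_class", "n_members", "start", "end"],
    )
    desert_truth = pd.DataFrame(
        [
            {
                "segment_index": seg,
                "start": seg_starts[seg] + off,
                "end": seg_starts[seg] + off + size - 1,
                "size": size,
            }
            for seg, off, size in spec.planted_deserts
        ],
        columns=["segment_index", "start", "end", "size"],
    )
    return SyntheticResult(sequence, ssr_truth, cluster_truth, desert_truth)


def _assemble(spec: SyntheticSpec, seg_arrays: list[bytearray]) -> str:
    parts = []
    for i, buf in enumerate(seg_arrays):
        parts.append(buf.decode("ascii"))
        if i < len(spec.gap_sizes):
            parts.append("N" * spec.gap_sizes[i])
    return "".join(parts)


def _verify_and_repair(
    sequence: AssemblySequence,
    spec: SyntheticSpec,
    seg_arrays: list[bytearray],
    seg_starts: list[int],
    planted: list[PlantedSSR],
    config: DetectionConfig,
    rng: np.random.Generator,
) -> AssemblySequence:
    """Rewrite interfering background until detection == planted exactly."""
    expected = {
        (seg_starts[p.segment] + p.offset, seg_starts[p.segment] + p.offset + p.length - 1)
        for p in planted
    }
    planted_ivs = sorted(expected)
    for _ in range(60):
        found = {(r.start, r.end) for r in detect_ssrs(sequence, config=config)}
        extra = found - expected
        missing = expected - found
        if not extra and not missing:
            return sequence
        buf = bytearray(sequence.residues, "ascii")
        for s, e in extra:
            # rewrite a base of the offending run that lies outside planted arrays
            positions = [
                q
                for q in range(s, e + 1)
                if not any(ps <= q <= pe for ps, pe in planted_ivs)
            ]
            if not positions:
                raise RuntimeError(
                    f"unexpected repeat {s}-{e} entirely inside planted arrays"
                )
            q = positions[len(positions) // 2] - 1  # 0-based
            cur = buf[q]
            buf[q] = int(rng.choice([x for x in _BASES.tolist() if x != cur]))
        if missing and not extra:
            raise RuntimeError(f"planted SSRs not recovered: {sorted(missing)[:3]}")
        sequence = AssemblySequence(spec.identifier, buf.decode("ascii"))
    raise RuntimeError("could not reconcile detected SSRs with planted ground truth")


def write_fixture(result: SyntheticResult, spec: SyntheticSpec, out_dir: str | Path) -> Path:
    """Write FASTA plus ground-truth TSVs and the spec as a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "synthetic.fasta"
    with open(fasta, "w") as fh:
        fh.write(f">{result.sequence.identifier}\n")
        res = result.sequence.residues
        for i in range(0, len(res), 70):
            fh.write(res[i : i + 70] + "\n")
    result.ssr_truth.to_csv(out_dir / "truth_ssrs.tsv", sep="\t", index=False)
    result.cluster_truth.to_csv(out_dir / "truth_clusters.tsv", sep="\t", index=False)
    result.desert_truth.to_csv(out_dir / "truth_deserts.tsv", sep="\t", index=False)
    with open(out_dir / "spec.json", "w") as fh:
        json.dump(spec_to_dict(spec), fh, indent=2)
    return fasta


def spec_to_dict(spec: SyntheticSpec) -> dict:
    return asdict(spec)


def spec_from_dict(d: dict) -> SyntheticSpec:
    return SyntheticSpec(
        seed=d["seed"],
        segment_sizes=tuple(d["segment_sizes"]),
        gap_sizes=tuple(d["gap_sizes"]),
        planted_ssrs=tuple(PlantedSSR(**p) for p in d.get("planted_ssrs", [])),
        planted_clusters=tuple(
            PlantedCluster(**c) for c in d.get("planted_clusters", [])
        ),
        planted_deserts=tuple(tuple(x) for x in d.get("planted_deserts", [])),
        background_freqs=tuple(d.get("background_freqs", (0.3, 0.2, 0.2, 0.3))),
        identifier=d.get("identifier", "synthetic"),
    )


def expected_bin_ssr_bp(
    result: SyntheticResult, seg_start: int, seg_end: int, d_n: int
) -> np.ndarray:
    """Position-wise oracle for per-bin SSR bp within one segment.

    Marks every position covered by a planted SSR and sums marks per bin;
    independent of the interval-arithmetic binning used by the pipeline.
    """
    size = seg_end - seg_start + 1
    covered = np.zeros(size, dtype=bool)
    for _, row in result.ssr_truth.iterrows():
        if row.start >= seg_start and row.end <= seg_end:
            covered[row.start - seg_start : row.end - seg_start + 1] = True
    n_bins = -(-size // d_n)
    out = np.zeros(n_bins, dtype=np.int64)
    for pos in np.flatnonzero(covered):
        out[pos // d_n] += 1
    return out
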