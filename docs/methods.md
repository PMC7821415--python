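# Methods

## Model

`ssrscape` analyses one assembly sequence at a time over the alphabet
{A, C, G, T, N}. Runs of N are unsequenced gaps; the maximal non-N runs
are *sequenced segments* S1..Sk, classed large (≥ 100 kb) or small. All
coordinates are 1-based inclusive internally; BED/bedGraph exports are
0-based half-open.

### Perfect SSR detection

A perfect SSR of unit size *u* is a maximal window in which s[i] = s[i−u]
throughout (no mismatches, no interruptions). For each unit size 1–6 the
detector finds these windows vectorially (a shifted equality mask and its
True-runs), then applies:

- **copy thresholds** — minimum complete copies (6, 3, 3, 3, 3, 3) for
  unit sizes 1–6; a window of length L yields ⌊L/u⌋ complete copies.
- **partial tails** — a maximal window may end mid-unit. By default the
  trailing partial bases count toward SSR length but not copies
  (`allow_partial_tail=True`); the alternative convention (length =
  copies × u) is a config switch because published totals from older
  detectors can follow either.
- **primitivity** — the motif must not itself be a repetition of a
  shorter unit (ATAT is never a unit; the repeat is the dinucleotide AT).
- **redundancy** — unit sizes are scanned 1→6 and a candidate wholly
  contained in an accepted repeat of smaller unit size is dropped
  (a poly-A run is not re-reported as AA/AAA/...). Partially overlapping
  repeats of different unit sizes are both kept, because both maximal
  runs are real (e.g. ...AAAAAAACACACA... holds an A-run and an AC-run
  sharing one base).
- **gaps** — detection is per segment; no repeat spans an N.

Motifs are grouped by cyclic rotation: the class representative is the
lexicographically smallest rotation (TC→CT, GAAA→AAAG). Rotations of a
primitive word are pairwise distinct, so the minimum is unique. Detection
is plus-strand only and reverse complements are distinct classes (CT and
GA are different classes), since phase-shifted repeats are the same
physical run while complementary ones are not.

### Differential densities

Global relative density is RD = M/N × 1000 — SSR base pairs per kilobase
(the chromosome totals 1,528,466 bp over 26,415 kb give RD 57.86 on this
scale). Each segment is tiled into ⌈size/Dₙ⌉ bins of nominal size Dₙ;
m&#8342; counts SSR bp overlapping bin *i*, with an SSR that straddles a
boundary contributing its bases to each bin it overlaps. This makes
Σm&#8342; = M exact at every resolution, which is the invariant the whole
differential construction rests on. pDₙRD&#8342; = m&#8342;/Dₙ × 1000, so a
full bin ranges 0–1000.

Two densities are stored per bin: the nominal value (over Dₙ) and the
value normalised by the actual bin size. They differ only in each
segment's short final bin; classification uses the normalised value so a
tail bin that is half repeat is not mistaken for a half-density bin.

The population standard deviation of pDₙRD across bins is the
resolution-exactness diagnostic: coarse bins average the landscape away
(SD → 0 as Dₙ → segment size, where the single bin's normalised density
equals the segment RD), while finer bins resolve heterogeneity and SD
grows. The convention (ddof = 0) is immaterial to this monotone use.

### Feature calling

**Peaks** are individual 1 kb bins — no plateau merging — because the
chromosome-level statistics this method was built for count peak *bins*.
Levels partition [90, ∞): LP [90, 150), MP [150, 300), HP [300, 425),
sHP [425, ∞). Peak calling refuses non-1 kb bins; the thresholds are
defined at that resolution only.

**Low-density regions.** Within each segment, maximal runs of consecutive
bins with density < 25 are collected (a single bin ≥ 25 terminates a run;
segment edges close open runs). A run of total size ≥ 3 kb with aggregate
RD < 25 is an ELR, big (≥ 100 kb) or small; within shorter sparse runs,
maximal zero-density sub-runs of ≤ 2 kb are ZD deserts. The published
size bounds (ZD ≤ 2 kb, sELR ≥ 3 kb) dovetail exactly, which this
precedence treats as an intentional partition: one or two zero bins are a
desert, three or more sparse bins are an ELR, and a desert is never
double-reported inside an ELR.

**Clusters** are maximal runs of ≥ 3 consecutive SSRs (genomic order)
sharing a rotation class, with no differently-classed SSR interleaved.
By default no distance cap is applied — observed clusters span mean
spacings from tens of bp to several kb, and interruption by another class
is the natural terminator — but `max_gap` imposes one, and
`strict_motif` switches grouping from rotation class to literal motif
for the stricter reading of "same motif". Levels: Clu ≥ 26,
MClu 9–25, mClu 3–8 members.

### Zones and map types

1 kb bins tile into 51-bin zones advancing 50 bins per zone, so adjacent
zones share exactly one bin; labels are Z001, Z002, ... within a segment.
Segments whose bins fit one window form a single zone labelled by segment
name; segments under 10 kb are pooled into one integrated zone. Map types
are assigned with precedence Penta > HML > ML > L > EL > AV:

- Penta: pentanucleotide SSR bp exceed 50 % of the zone's SSR bp;
- HML: the zone holds at least one sHP/HP (with the accompanying mix of
  lower peaks that high-density zones in practice carry);
- ML / L: middle / only-low peaks;
- EL: every bin below the ELR floor (25);
- AV: the fallback — no peaks, densities near the chromosome average.

The type names are qualitative landscape descriptions; the published
per-type map counts come without quantitative definitions, so the Penta
fraction, EL ceiling and AV band are declared approximations living in
`MapTypeRule`, to be recalibrated rather than trusted. Figures default to
SVG with a fixed hash salt and stripped date metadata, so rendered maps
are byte-identical across runs.

## Synthetic assemblies

The generator emulates the structural features of an incompletely
sequenced chromosome: N-gap-separated segments of mixed sizes, planted
perfect arrays of unit sizes 1–6, regularly spaced rotation-class cluster
runs, high-density bins (long arrays confined to one bin), and SSR-free
stretches. The background is order-0 random sequence (default base
frequencies 0.3/0.2/0.2/0.3, a mild AT bias typical of mammalian
chromosomes) that is *SSR-suppressed*: the detector is run repeatedly and
the centre base of any incidental threshold-passing run is rewritten
until none remain. Scan-and-rewrite terminates quickly where rejection
sampling of whole sequences would not. After planting, flanking bases are
chosen to break period-u extension on both sides (so each planted array
is maximal exactly as specified), and a final verify-and-repair loop
asserts that detection output equals the planted truth set before the
sequence is released. Generation is deterministic per seed, byte-identical
FASTA included.

What the generator does **not** emulate: mutational degradation of
repeats (imperfect/compound SSRs), GC heterogeneity and isochores, gene
content, and realistic length distributions of repeat tracts. Passing
recovery tests therefore demonstrates correctness of the detection and
classification machinery, not detector behaviour on biologically
degraded repeats — on real chromosomes, counts additionally depend on the
partial-tail and redundancy conventions, which is why both are exposed.

## Numerical and design choices

- Bin arithmetic is integer throughout (m&#8342; in bp); densities are
  derived floats, reported to 2 dp in tables with full precision kept
  internally.
- The last-bin normalisation choice (actual size for classification,
  nominal Dₙ retained for the formula value) affects only a handful of
  tail bins per segment.
- `min_gap_len` defaults to 1 (any N separates segments), reproducing the
  reference decomposition; other assemblies with sporadic single-N calls
  can raise it, absorbing short N runs into segments.
- Non-N IUPAC ambiguity codes are mapped to N on ingest (detection needs
  a strict 4-letter alphabet) and counted in the log.
- Sub-threshold candidate runs are pruned before thresholding; ties in
  rotation canonicalisation cannot occur for primitive motifs, and
  non-primitive input to `canonical_class` is an error.
- Problem sizes: the test fixtures use a 55 kb three-segment assembly;
  the acceptance run uses a ~665 kb six-segment assembly with 44 planted
  peak bins and three planted clusters (430/15/5 members). These sizes
  exercise every code path — bin boundaries, tail bins, pooled zones,
  all peak/ELR/cluster levels — while keeping a full run in seconds.

## Known limitations

- Perfect repeats only: no imperfect/compound SSR model, no alignment
  scoring, no polymorphism genotyping.
- Single sequence per run; multi-record FASTA requires explicit record
  selection.
- Published chromosome totals for the human Y depend on the original
  detector's unstated redundancy and tail conventions; residual
  divergence under either convention is reported per-convention by the
  reference-reproduction script rather than hidden.
- Map-type assignment beyond the peak-composition types (Penta/AV/EL
  thresholds) is a configurable approximation.
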