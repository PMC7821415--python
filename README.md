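# ssrscape

Fine-scale microsatellite landscape mapping for chromosome-sized sequences.

Microsatellites (simple sequence repeats, SSRs — perfect tandem runs of a
1–6 bp unit) are usually summarised by one chromosome-wide *relative
density*, RD = M/N × 1000 (SSR base pairs per kilobase, with M the total
SSR size and N the sequence size). That single average hides where repeats
actually sit. `ssrscape` implements a differential approach: every
sequenced segment of an assembly is tiled into ceil(N/Dₙ) bins of size Dₙ
and each bin *i* gets a position-related density

&nbsp;&nbsp;&nbsp;&nbsp;pDₙRD&#8342; = m&#8342; / Dₙ × 1000

where m&#8342; is the SSR base pairs overlapping bin *i* (split exactly
across bin boundaries, so Σm&#8342; = M at every resolution). At 1 kb
resolution this exposes a rich landscape that the toolkit then annotates:

- **density peaks** — single 1 kb bins graded sHP (pD₁RD ≥ 425),
  HP ([300, 425)), MP ([150, 300)), LP ([90, 150));
- **extremely-low-density regions** — runs of sparse bins: bELR
  (RD < 25, ≥ 100 kb), sELR (RD < 25, 3–100 kb), and ZD deserts
  (zero-density runs ≤ 2 kb);
- **motif clusters** — ≥ 3 consecutive SSRs of one rotation class
  (CT/TC count as the same class) with no other class interleaved,
  graded Clu (≥ 26), MClu (9–25), mClu (3–8);
- **landscape maps** — 51-bin zones (one bin shared with each neighbour),
  each typed HML/ML/L/Penta/AV/EL and rendered as an SVG/PNG figure with
  optional gene-annotation tracks.

Detection follows the classic perfect-repeat convention: minimum complete
copies 6, 3, 3, 3, 3, 3 for unit sizes 1–6, maximal runs only, trailing
partial units counted in length but not copies, plus-strand only. It is
intended for researchers studying repeat distribution, selection and
marker design on assembled chromosomes (the motivating use case is the
human Y), and ships a synthetic-assembly generator so every detector and
classifier can be validated against planted ground truth without
downloading real genomes.

## Worked example

Generate a small synthetic assembly — two gap-separated segments, a
planted pentanucleotide array of 450 bp, an AC array of 320 bp, and a
30-member CT-class cluster at 89 bp spacing — then run the full pipeline:

```bash
cat > spec.json << 'EOF'
{
  "seed": 11,
  "segment_sizes": [60000, 20000],
  "gap_sizes": [2000],
  "planted_ssrs": [
    {"segment": 0, "offset": 5200, "motif": "AAAAG", "copies": 90},
    {"segment": 0, "offset": 12200, "motif": "AC", "copies": 160}
  ],
  "planted_clusters": [
    {"segment": 1, "offset": 500, "motif": "CT", "copies": 6, "n_members": 30, "spacing": 89}
  ]
}
EOF
ssrscape synth --spec spec.json -o fixture/
ssrscape run-all fixture/synthetic.fasta -o out/
```

The run prints (abridged):

```
"n_segments": 2,            # two sequenced segments split by the 2 kb N gap
"n_ssrs": 32,               # 2 planted arrays + 30 cluster members, nothing else
"ssr_bp": 1130,             # 450 + 320 + 30 x 12
"global_rd": 14.12,         # 1130 bp over 80 kb of sequence, per kb
"peaks_by_level": {"sHP": 1, "HP": 1, "MP": 0, "LP": 2},
"n_clusters": 1,            # the CT cluster, level Clu (n = 30)
"n_zones": 3,
"map_types": {"L": 1, "Penta": 1, "EL": 1, ...}
```

The 450 bp penta array makes its bin a super-high peak (pD₁RD 450) and its
zone Penta-typed; the AC array is a high peak; the cluster's 360 bp fall
densely enough to produce two low peaks; everything else is SSR-free
background, so the remaining zone is EL. `out/` contains the segment/gap
tables, the SSR table (TSV/BED/GFF3), per-bin density tables and bedGraph
tracks, peak/ELR/cluster tables, the zone table and `summary.json`.

The same stages are available separately (`ssrscape segments`, `detect`,
`density`, `features`, `maps`) and as library functions.

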