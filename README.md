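# protistdiv

Genetic-distance clustering and phylogenetic-structure analysis for 18S
rDNA diversity surveys of microbial eukaryotes.

Environmental 18S rDNA surveys ask two complementary questions about each
taxonomic group (a class-level clade or an environmental "ribogroup" such as
the MAST or MALV clades): *how much* sequence diversity does the group hold
today, and *when* during its history did that diversity arise? `protistdiv`
implements both halves as a tested, reusable library with a thin
command-line pipeline on top.

## What it computes

**Sequence space.** From an aligned multi-FASTA per group:

- pairwise **Jukes-Cantor distances**, `d = -(3/4) ln(1 - 4p/3)`, with
  pairwise deletion of gaps/ambiguities and explicit errors at the
  saturation bound `p >= 3/4`;
- **furthest-neighbor (complete-linkage) OTU clustering** on a 1/10,000
  rounding grid, so every OTU at cutoff *c* is guaranteed to contain no
  pair more distant than *c*;
- per-group diversity statistics: the average (**Avg**) and maximum
  (**Max**) pairwise distance, the **maximum corrected distance**
  (**Max_c**: the smallest cutoff at which 90% of the group's sequences
  fall into a single OTU — robust to one divergent or error-laden
  sequence), OTU counts at graded cutoffs, and the **clustering pattern**
  (OTU counts as a percentage of the count at distance 0);
- calibration of a partial barcode region (e.g. V4–V5 or V9) against the
  full gene: OLS slope *m* and Pearson *R* over matched pairwise distances.

**Tree space.** From a rooted newick tree with a tip-to-group map:

- a deterministic **ultrametric transform** (mean-path-length smoothing);
- standardized **lineage-through-time (LTT) curves** on relative time from
  −1 (crown) to 0 (present), lineages as % of the present-day count;
- the **Pybus–Harvey γ statistic** with a one-tailed constant-rate test
  (γ ≈ N(0,1) under pure birth; significantly negative = early
  cladogenesis, positive = late);
- **MPD** (mean patristic distance within a group), **trunk length** (the
  stem branch subtending a monophyletic group), and mean **intergroup
  distances** with each group's closest neighbor.

**Synthetic data.** A generator produces Yule (pure-birth) trees, a
one-parameter time warp (node ages `a -> a^beta`) that controls the tempo of
cladogenesis and hence the sign of γ, Jukes-Cantor sequence evolution with
region-specific rate multipliers, and multi-group "supergroup" fixtures with
known trunk lengths — so every stage is testable end to end without any
external data.

## Worked example

```bash
python examples/phylogenetic_structure.py
```

builds three monophyletic 30-tip groups whose branching times are warped
toward the root, left constant, or warped toward the present, and prints:

```
     group    gamma  p(1-tail)     class     MPD  trunk
  constant     0.29      0.387      zero   1.248   0.60
     early    -5.88   2.01e-09  negative   1.885   0.40
      late     6.20    2.9e-10  positive   1.248   0.80
```

γ correctly flags the early group (branchings near the root, concave LTT)
as significantly negative and the late group as significantly positive,
while the constant-rate group is indistinguishable from the pure-birth
null. The trunk column recovers the configured stem lengths exactly. The
other examples (`diversity_statistics.py`, `region_calibration.py`,
`simulate_fixture.py`) demonstrate OTU clustering, region calibration —
a 550-column region evolving 1.4× faster than the gene background yields
slope m ≈ 1.39, R ≈ 0.98 — and fixture generation.

## Command-line pipeline

```bash
protistdiv simulate   --out fixture --seed 7 --groups "A:20:0.3,B:20:0.5,C:20:0.7"
protistdiv diversity  --out run fixture/*.fasta
protistdiv structure  --out run fixture/supergroup.nwk fixture/groups.tsv
protistdiv region-eval --out run gene.fasta regions.tsv
```

Reports are plain TSV/JSON (plot-ready; no figures are rendered). Exit
codes: 0 success, 2 partial (some groups skipped with logged reasons),
1 hard failure.

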