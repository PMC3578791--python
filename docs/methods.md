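# Methods

This note documents the models, algorithms and numerical choices behind
`protistdiv`, and what the synthetic-data generator does and does not
emulate.

## Distances

Observed divergence between two aligned rows is the proportion *p* of
differing sites among *comparable* columns: those where both rows carry an
unambiguous base (A/C/G/T). Gaps and IUPAC ambiguity codes are excluded per
pair (**pairwise deletion**), which keeps the per-pair information maximal
on ragged survey alignments; the number of comparable sites is recorded
alongside every distance. Ambiguity codes are excluded rather than
fractionally matched — simpler and directly testable.

The Jukes-Cantor correction `d = -(3/4) ln(1 - 4p/3)` assumes equal base
frequencies and a single substitution rate; it is the weakest (and most
comparable across groups) of the standard corrections and matches the
generative model of the simulator, so distance estimation is exactly
model-matched in tests. Pairs at or beyond the domain bound (`p >= 3/4`)
raise a `SaturationError` rather than being clamped: a clamped value would
silently corrupt the Max statistic of a group. Callers that can tolerate
undefined pairs (the region-calibration fit) request `nan` entries
explicitly and drop them with a logged count.

## OTU clustering

Furthest-neighbor (complete-linkage) agglomeration: the distance between
two clusters is the maximum over cross pairs, and the closest pair of
clusters merges at each step. Before agglomeration distances are rounded
**half-up to a 1/10,000 grid** (`precision = 10,000`), and cutoffs are
rounded to the same grid and compared with closed (`<=`) semantics — the
convention of mothur-style list output, which the package can emit.
Consequences worth knowing:

- every OTU at cutoff *c* satisfies the complete-linkage guarantee (no
  internal pair exceeds *c* on the grid);
- Avg/Max are computed on *unrounded* distances (they are summary
  statistics, not clustering quantities); the two differ only below 1e-4;
- ties between equal-height candidate merges are broken by the
  lexicographically smallest member names of the two clusters, making
  dendrograms byte-reproducible. Partitions at a cutoff can in general
  depend on tie order under complete linkage, so the brute-force oracle in
  the tests applies the same rule while recomputing every cluster distance
  from scratch.

The **maximum corrected distance** is the smallest merge height at which
some OTU holds at least a fraction *f* (default 0.9) of the group's
sequences; `f*n` is compared with `>=` on the real value, no integer
ceiling. It equals 0 when 90% of the sequences are already identical and is
bounded above by the (rounded) maximum pairwise distance.

The agglomerator maintains an O(n²) matrix with Lance-Williams `max`
updates; it is intended for the per-group scale of survey data (tens to a
few thousand sequences), not for amplicon-scale millions.

## Region calibration

For a partial region and the full gene over the same sequences, the
matched pairwise distances are regressed by OLS with the **partial**
distance as the response and a free intercept; the slope *m* says by what
factor the region over- or underestimates full-gene divergence and Pearson
*R* how tightly. The intercept is left free (and reported) because the
constrained fit is a trivial refit for anyone who prefers it. Note the
identity that governs simulation checks: if a region of length `L_r` in a
gene of length `L` runs at `k` times the background rate, the expected
slope is `k / ((L_r*k + (L-L_r)) / L)` — the full gene contains the fast
region, so the slope is below `k` unless the region is short relative to
the gene.

## Tree statistics

**Ultrametric transform.** Each internal node's height is set to the mean
of its subtree's node-to-tip path lengths, then heights are re-monotonized
root-ward (children capped at their parent's height; would-be negative
branches clamped to 0). The method is deterministic and parameter-free;
only the relative order and spacing of node heights matter for LTT and γ,
so penalized-likelihood dating would add machinery without changing the
statistics it feeds. Smoothing a mildly perturbed ultrametric tree changes
total tree length by well under 20% (property-tested).

**Branching times** require ultrametricity within a relative tolerance of
1e-6. Polytomies with *c* children count as *c − 1* coincident branching
events (equivalent to an arbitrary zero-length resolution, which leaves the
internode intervals — and hence γ — unchanged); degree-2 nodes are not
events.

**LTT curves** use relative time: −1 at the crown (the oldest branching
event of the extracted group tree — groups are analyzed as crown clades),
0 at the present, with lineage counts as percentages of the tip count. The
curve starts at 2 lineages at −1 and always ends at (0, 100%).

**γ statistic.** With `g_j` the duration during which exactly *j* lineages
exist (`j = 2..n`), `T_i = sum_{k=2..i} k*g_k` and `T = T_n`:

    gamma = [ (1/(n-2)) * sum_{i=2..n-1} T_i  -  T/2 ] / ( T * sqrt(1/(12(n-2))) )

Under constant-rate pure birth γ has mean 0 and unit variance
(approximately standard normal), verified here on 1000 simulated trees and
cross-checked against dendropy's independent implementation to 1e-8. The
constant-rate test is **one-tailed in the direction of the observed sign**
at α = 0.05, classifying groups as `negative` / `zero` / `positive`; the
direction-by-sign convention matches how early/constant/late cladogenesis
regimes are reported in survey work, and is noted here because a
fixed-direction test would halve the p-values.

**MPD, trunk, intergroup distances.** Patristic distances are computed by
an LCA/depth scheme and checked against explicit path enumeration and
against dendropy. MPD is the mean over unordered within-group tip pairs.
The trunk is the stem branch subtending a group's MRCA; non-monophyletic
groups are an error, a single-tip "group" degenerates to its terminal
branch (logged — needed for degenerate fixtures), and a group spanning the
whole tree has no stem. Intergroup distance (G, H) is the mean patristic
distance over cross pairs; each group's minimum off-diagonal entry
identifies its closest neighbor.

## Synthetic data

The generator emulates the *shape* of an 18S survey dataset:

- **Yule trees**: crown-conditioned pure birth; the interval with *k*
  lineages is Exp(k·λ) and a uniformly chosen lineage splits at each
  event. This is the exact null of γ. Extinction is not simulated
  explicitly — tempo effects are produced by warping instead.
- **Time warp**: node ages scaled to [0, 1] are remapped `a -> a^beta`
  (β > 0). β < 1 pushes branchings toward the root (γ < 0 in expectation),
  β > 1 toward the present (γ > 0), β = 1 is the identity; topology, tip
  set, total depth and ultrametricity are preserved. One parameter controls
  the sign of γ, which makes sign-recovery directly testable.
- **Sequence evolution**: Jukes-Cantor along the tree, root drawn uniform
  over {A,C,G,T}; on a branch of duration *t* a site with rate *r*
  substitutes with probability `(3/4)(1 - exp(-4rt/3))`, uniformly to one
  of the other three bases. Per-site rates are the base rate times the
  multiplier of the region containing the site. Defaults mirror a survey
  gene: 1800 columns with a 550-column V4V5-like region and a 160-column
  V9-like region at 1.4× the background, base rate 0.05 subs/site/time —
  chosen so that pairwise distances on unit-depth trees land in the
  0.05–0.3 range typical of within-group 18S comparisons.
- **Supergroup fixtures**: independent per-group Yule subtrees (optionally
  warped), scaled to a configured crown depth, attached to a common root by
  their trunk branches — monophyletic by construction, with exactly
  recoverable trunk lengths; sequences are evolved over the whole tree and
  emitted per group.

What the generator does **not** emulate: indels and alignment error (all
simulated alignments are gap-free; the gap handling code is exercised by
hand-built fixtures instead), across-site rate heterogeneity, base
composition bias, chimeras, and non-monophyletic groups. Passing tests
therefore demonstrate correctness of the statistics under their own model
assumptions, not robustness to alignment artifacts in real survey data.

Every stochastic operation is a pure function of (configuration, seed);
the RNG is numpy's default (PCG64) and reproducibility is guaranteed per
seed within this implementation, not across libraries.

## Problem sizes

The test suite and the acceptance script run at deliberately small scale —
clustering oracles up to n = 12 against an O(n³) reference, γ calibration
on 1000 trees of 50 tips, region recovery on 30 taxa × 5000 columns × 20
replicates — sizes at which the brute-force oracles are exact and the
Monte-Carlo bands (mean γ within ±0.1, sd within ±0.1 of 1, slope within
±0.1) are comfortably resolved.

## Known limitations

- Saturated pairs make the whole group matrix an error in strict mode;
  groups containing them must be analyzed with `on_undefined="nan"` and
  explicit pair dropping.
- The ultrametric smoother preserves node order only up to the
  re-monotonization clamp; trees with wildly rate-heterogeneous branches
  will see compressed old nodes.
- γ is sensitive to incomplete taxon sampling (apparent slowdowns); no
  sampling-fraction correction (MCCR-style) is implemented.
- The CLI's `diversity` subcommand derives the group id from the FASTA
  file stem; two files with the same stem collide.
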