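# Methods

## Coordinate conventions

All coordinates are 0-based half-open internally (BED convention). Chain
files are read faithfully — minus-strand query coordinates are kept on the
reverse complement as written — and converted to forward-strand coordinates
only when a chain is decomposed into anchor blocks
(`pos_fwd = qSize − pos_rev` applied to both ends, block flagged
*inverted*). Keeping the parser a pure reader of the format and converting
at extraction time avoids mixing conventions inside one data structure.

## Anchors and distance

An anchor point is one ungapped chain block of at least `min_block_size` bp
(default 10; smaller blocks are treated as alignment noise — the threshold
is configurable and no filter at all can be requested with
`min_block_size=1`). All chains contribute anchors; overlapping anchors
from multiple chains are retained and the index resolves queries over the
union, with containing-anchor ties broken by larger block then lower start
(larger blocks are higher-confidence alignments).

The distance `d` of a point to the anchor set is the bp distance to the
nearest edge of the nearest block on the same chromosome; anchors on other
chromosomes are never "near". With half-open ends, the position exactly at
a block's exclusive end has edge distance 0 without being inside the block;
this is the one place where `d = 0` does not imply containment, and it is
handled identically in the index, the projector and the oracle.

## Pairwise projection

For one species pair:

* **in-block** — exact offset mapping, reversed inside inverted blocks;
  `d = 0`. Round trips are exact by construction.
* **interpolated** — when the query lies between an upstream and a
  downstream anchor of equal orientation whose partner intervals share a
  chromosome, the target position is the linear interpolation between the
  two *facing* anchor edges (end of the upstream partner to start of the
  downstream partner; reversed for inverted pairs), rounded half-up to an
  integer. `d` is the distance to the nearer flanking edge.
* **one-sided** — a single flanking anchor, an orientation mismatch
  (an inversion breakpoint between the flanks makes interpolation
  meaningless), or partners on different chromosomes: constant-offset
  extrapolation from the nearest anchor, ties toward upstream.
  Extrapolated positions are not clamped to chromosome bounds; a negative
  target coordinate simply signals an extrapolation past the first anchor
  and such projections are invariably NC-grade.

## Bridged search and classification

The bridged projection is the species path minimizing the summed per-hop
`d`, found by uniform-cost search over (species, chromosome, position)
states. Distance is accrued on the **source side** of each hop — the
distance from the current point to the anchors actually used — because
that is what bounds the interpolation error introduced by the hop. Paths
never revisit a species, are cut off at `max_hops` (default 4) pairwise
projections, and are pruned once the cumulative distance reaches the IC
bound, so the search is exact within those limits (verified against
exhaustive path enumeration). Ties break by fewer hops, then lexicographic
species order, making outputs reproducible.

Classification: DC iff a direct projection exists with `d ≤ 300` bp
(boundary inclusive — "within"); else IC iff a bridged path exists with
summed distance strictly below 2500 bp ("less than"); else NC if any
projection exists. A bridged path at or above the IC bound is treated as
no bridged projection at all (it is pruned), so UNPROJECTABLE means: no
direct anchors on the chromosome and no bridged path below the bound.
The DC test uses the query-side distance; whether to measure on the query
or target side is a genuinely open choice, and the query side is the one
that limits how accurately the query can be placed. Regions are projected
as points (midpoint, or a user-supplied summit); interval projection is
out of scope.

## Activity labeling

A projection is active (+) when its projected point, widened by `window`
bp per side, intersects at least one target-genome peak; the peak with the
largest overlap is recorded. The default window is 0 (the bare point must
fall inside a peak); the labeling is monotone in the window by
construction. For DC rows the direct target coordinate is used; otherwise
the bridged coordinate when available. Background pairing draws a uniform
random nonortholog peak, preferring peaks inside the TAD containing the
ortholog peak and falling back genome-wide (`same_tad=False`) when the TAD
has no alternative.

## TFBS shuffling statistics

Per CRE window: overlapping hits of the same motif keep only the higher
score (greedy by descending score, ties by lower start). Shared content
between two CREs is the per-motif minimum of occurrence counts — a
multiset intersection, chosen over presence/absence so that repeated
motifs count as often as they co-occur. For ranking only, hits of
*different* motifs overlapping by ≥ 8 bp also keep only the higher score
(the ≥ convention is configurable), and contiguous runs of one motif
collapse to a single occurrence. A motif recurring noncontiguously
(A,B,C,A,D) expands into the matrix of unique ranking rows ({A,B,C,D},
{B,C,A,D}); row counts are capped at 4096 to keep the all-vs-all
comparison bounded.

`K_d` between two CREs is the number of discordant motif pairs divided by
`n(n−1)/2`, minimized over all row pairs of the two matrices and both
orientations of the second list (forward wins ties). Pairs enter the
pipeline only with at least `min_shared = 6` shared TFBS. Cohen's *d* uses
the pooled-SD form; magnitude labels are small (|d| < 0.2), medium
(0.2 ≤ |d| ≤ 0.5), and — as a conventional extension beyond the two
printed cutpoints — large (|d| > 0.5). When both samples are constant and
equal, d is defined as 0; constant unequal samples raise an error.

## The simulator

The generator is the package's study condition, not a claim about
molecular evolution: it is the minimal model producing the regime where
direct alignment fails but bridged alignment survives.

* An ancestral chromosome of `n_anchors` (default 200) anchor slots of
  `anchor_len` = 100 bp, separated by lognormal spacers with mean 900 bp
  and σ = 0.6 (σ = 0 degenerates to fixed spacers). Spacers are resampled
  independently per species — a crude indel model that moves orthologous
  points apart without destroying interpolability.
* Each anchor accrues divergence independently on every tree branch as an
  exponential increment with mean equal to the branch length; an anchor is
  alignable between two species iff its summed divergence along the tree
  path is below θ. The **standard fixture** is a 4-species path tree with
  branch lengths 0.45 and θ = 1: adjacent pairs retain ≈ 89 % of anchors,
  the end-to-end pair ≈ 39 %, yielding a stable DC/IC/NC mixture at
  500 queries.
* True ortholog positions come from piecewise-linear coordinate maps
  (exact inside anchors, fractional across spacers). An optional inverted
  anchor run in one species exercises minus-strand chains; spacer
  orthology across an inversion boundary is reported as undefined.
* Activity peaks are planted at the true ortholog positions of 60 % of
  queries (width 200 bp) plus 100 random decoys, so projection error
  translates into decreasing +-fractions from DC to NC.
* Motif pairs place `n` non-overlapping 10-bp hits in a 500-bp window and
  derive list B by `t` disjoint adjacent transpositions (each contributes
  exactly one discordant pair, so forward `K_d = t/(n(n−1)/2)` exactly),
  with optional orientation flips.

All randomness flows from one seeded generator; identical seeds give
byte-identical outputs, including file emission (output headers carry the
tool version, a config hash and the seed, never timestamps).

What the simulator does **not** emulate: nucleotide sequences, realistic
phylogenies, rearrangements beyond a single inversion, chromosome gain or
loss, and alignment artifacts such as paralogous chains. Passing tests
therefore demonstrate the correctness of the projection machinery and
statistics under conserved synteny — not the biological accuracy of any
particular genome pair.

## Verification

The production path (chain emission → parsing → anchor index → uniform-cost
search → classification) is checked against an independent brute-force
projector (linear scans plus exhaustive path enumeration) that shares only
the definitions; agreement is required for 100 % of the standard fixture's
queries. Kendall distances are checked against exhaustive discordant-pair
counting for all permutations up to length 6. Problem sizes throughout
(200 anchors, 500 queries, 4 species, 50-pair motif batches) were chosen
as the smallest at which all class regimes appear with stable margins.

## Known limitations

* Path cost is raw summed bp distance; no weighting by anchor quality or
  species divergence (configurable thresholds only).
* Anchors come from all chains; there is no net/reciprocal-best filtering.
* One-sided extrapolation trusts a single anchor arbitrarily far — such
  projections carry their large `d` honestly but their coordinates are
  unreliable, and callers should treat NC coordinates as rough.
* The per-hop distance ignores the interpolation *ratio* (a hop between
  distant anchors of very different spacer lengths scales error
  nonuniformly); the summed edge distance is a proxy.
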