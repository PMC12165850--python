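# ippoint — interspecies point projection

`ippoint` maps genomic positions between highly diverged genomes by synteny
rather than by sequence alignment. It is aimed at comparative regulatory
genomics: finding the positional ortholog of a cis-regulatory element (CRE —
an enhancer or promoter called from ATAC-seq or histone ChIP data) in a
species too distant for the element itself to align, e.g. mouse to chicken.

## The method

Most noncoding CREs lose direct alignability over large evolutionary
distances even when their function is conserved. But CREs sit between
*anchor points* — ungapped blocks of residual alignment (from UCSC pairwise
chain files) that persist in conserved synteny. A query point between two
anchors can be **interpolated** to the same relative position between the
orthologous anchors in the target genome. When the nearest direct anchor is
far, the projection is routed through **bridging species**: project
mouse → bridge, then bridge → chicken, choosing the species path that
minimizes the summed per-hop distance *d* to the anchors used (a
uniform-cost search over (species, chromosome, position) states).

Projections are classified by confidence:

| class | rule |
|---|---|
| **DC** (directly conserved) | within 300 bp of a direct query–target alignment (`d_direct ≤ 300`) |
| **IC** (indirectly conserved) | not DC, but bridged with summed anchor distance `Σ d < 2500` bp |
| **NC** (nonconserved) | a projection exists but meets neither bound |
| **UNPROJECTABLE** | no anchors on the chromosome and no bridged path below the IC bound |

Downstream, the package labels projections **+/−** by overlap with
target-genome activity peaks (ATAC/ChIP BED files) and summarizes the
fraction of active orthologs per class; and it quantifies **TFBS shuffling**
between ortholog CRE pairs as the normalized Kendall tau rank distance

```
K_d = (# discordant motif pairs) / (n(n−1)/2)
```

over the 5′→3′ order of their shared motifs, minimized over both
orientations of the second CRE and over all unique ranking rows when motifs
recur, with Cohen's *d* effect sizes between conservation classes.

A built-in simulator generates multispecies genomes with known ortholog
positions (anchors diverging along a species tree; alignable iff the summed
path divergence stays below a threshold), emits real chain files, and
provides a brute-force oracle — so the whole pipeline is testable offline.

## Worked example

Simulate a 4-species fixture (spA → spD with two bridges), project, label
activity and score motif shuffling:

```bash
ipp simulate --preset standard --seed 42 --out-dir demo --n-anchors 60 --n-queries 60
ipp project --query-bed demo/queries.bed --query-species spA --target-species spD \
    --config demo/config.yaml --out demo/projections.tsv
ipp classify-activity --projections demo/projections.tsv --peaks demo/peaks.bed \
    --window 100 --out demo/fractions.tsv
ipp tfbs-kendall --pairs demo/pairs.tsv --out demo/kendall.tsv
```

which prints:

```
projected 60 regions: DC=15, IC=41, NC=4, UNPROJECTABLE=0
DC: n=15 plus=12 fraction=0.800
IC: n=41 plus=31 fraction=0.756
NC: n=4 plus=1 fraction=0.250
DC: n=4 median_k_d=0.017857142857142856
IC: n=4 median_k_d=0.08928571428571427
NC: n=4 median_k_d=0.125
```

Reading this: of 60 query points, 15 fell within 300 bp of a direct
spA–spD anchor (DC) and 41 more were reachable through the bridging
species with summed anchor distance under 2.5 kb (IC) — the bridging gain
that direct alignment alone would miss. DC and IC projections overlap a
target activity peak at similar high rates (0.80 vs 0.76), while the
low-confidence NC class drops to 0.25 because its larger interpolation
error lands projections away from true ortholog positions. The median
Kendall distance rises from DC to NC pairs, reflecting the increasing
motif-order shuffling built into the simulated pairs.

`demo/projections.tsv` has one row per query with the direct and bridged
target coordinates, distances, species path and class.

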