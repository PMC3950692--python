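# Methods

This note records the models, conventions and design decisions behind
`mirchromnet`, in the order the pipeline runs them.

## Coordinates and windows

All in-memory coordinates are 0-based half-open (BED convention); GFF3 is
converted on read and write. A point window of half-width *w* is closed at
base resolution — a feature exactly *w* bases away counts — so as an
interval it is `[x − w, x + w + 1)`. Interval overlap means ≥ 1 shared base;
abutting intervals do not overlap. Peak location for all window tests is the
peak *center* (the summit when a summit column is present, else the floor
midpoint); the one exception is anchor/blacklist filtering, which uses full
interval overlap.

## Promoter annotation

TSS evidence combines in a fixed cascade: a curated TSS always wins; CAGE
evidence beats RNAPII evidence. For the CAGE and RNAPII tiers the candidate
set is every tag/peak center with strand-aware upstream distance 0–50 000 bp
from the pre-miRNA 5′ end (both boundaries inclusive; distance 0 allowed);
the nearest candidate wins, ties break to the higher intensity and then to
the smaller coordinate. The RNAPII-tier TSS is the peak center, matching the
center convention used everywhere else. Promoter sharing ignores relative
strand: any coding-gene TSS within ±2 kb (inclusive) makes the promoter
shared. Manual promoter verification is replaced by a reported
`h3k4me3_supported` flag (≥ 1 H3K4me3 peak center within the ±2 kb window);
the flag is never used as a filter. Mark profiles count peak centers within
±5 kb of the TSS, pooling replicates by summation.

## Chromatin network and communities

Each duplex interaction links the set of promoter-bearing entities whose
±2 kb TSS window overlaps one anchor with the set on the other anchor
(cross product minus self pairs; two entities sharing a single anchor are
not linked by it). Replicate support is counted per cell line; an entity
pair is retained when **some single cell line** recovers it in ≥ 2 distinct
replicates, and the edge's `cell_status` lists every cell line that
individually meets the threshold. Communities are the connected components
of the retained graph — the simplest reading of anchor-overlap connectivity,
and the one under which a unique giant component exists; isolated entities
belong to no community. Size ties for the giant community break to the
smallest lexicographic member id. Anchors are never pre-merged; overlap
connectivity emerges at the entity level.

## MIR interactome

Direct MIR–MIR edges follow the same ≥ 2-replicate rule, relaxed to
≥ 1 replicate for genomic neighbours. "Neighbours" is formalized as
same-chromosome pre-miRNA gap ≤ 10 kb (configurable): the conventional
miRNA-cluster distance, motivated by clustered MIRs being co-transcribed.
Indirect edges join MIR pairs that share a community but no direct edge,
taking the shortest connecting path inside the community; the pair is kept
when the path's edges carry ≥ 2 distinct (cell line, replicate) datasets in
total. An indirect edge's cell status is the set of cell lines that meet the
edge threshold on *every* path edge ("mixed" when empty). Summaries count
direct + indirect edges once per unordered pair; a `--direct-only` switch
restricts them. Model assignment partitions all annotated MIRs:
`interaction` for network/interactome members, else `basal` when ≥ 1 RNAPII
peak center lies within ±2 kb of the TSS, else `not_assigned` (including
MIRs without a promoter call).

## Target-pair enrichment

Only pairs supported by ≥ 2 prediction databases enter. A pair maps when
both endpoints are network nodes; `within` means same community. The
community-link test pools both directions of an unordered community pair
{A, B} and, for pairs with ≥ 10 mapped pairs (5 in the sensitivity mode),
computes an upper-tail hypergeometric p with population N = all mapped
between-community pairs, successes K = pairs incident to A, draws n = pairs
incident to B, observation k = the pooled count. The pair-based margin
convention is fixed and used identically for real and permuted data.
Benjamini–Hochberg runs over all tested pairs; significance is q ≤ 0.001.
The within-community depletion test crosses giant-community incidence with
within/between status in a 2×2 Fisher table; a zero margin returns p = 1
with a warning.

Permutation controls use the add-one estimator
`FDR = (1 + #{null ≥ observed}) / (1 + n_permutations)` so an estimate is
never zero, with 10³ replicates by default. The percent-targeted control
resamples, per replicate, all community gene sets jointly without
replacement from the pool of annotated protein-coding genes (network
membership not required — genes outside the network carry no mapped
targeting); drawing the sets jointly keeps each null replicate a disjoint
partition like the observed one, which makes the control exactly
exchangeable under a structureless target distribution. Per-community GO
style term enrichment is an upper-tail hypergeometric over flat labels,
BH-controlled at FDR < 0.05; linked communities are compared by the size of
the intersection of their enriched-term sets against same-size random gene
sets.

## Family and disease statistics

The contact null redraws the observed number of edges uniformly without
replacement from all unordered pairs of networked MIRs, preserving the edge
count exactly in every replicate; groups with < 2 networked members are
excluded. A MIR may carry several disease categories; an edge is concordant
when the two label sets intersect, and contributes to each shared category's
tally. The per-community χ² uses a 2-cell observed-vs-expected statistic
with 1 df, with the background class frequency taken over all networked
MIRs that carry ≥ 1 disease label, testing classes with ≥ 2 member MIRs at
α = 0.001.

## Marks, Mantel and expression

Mark correlation is Spearman (mid-ranks for ties) across promoter-bearing
MIRs; constant columns yield not-applicable (NaN) entries. The heatmap leaf
order comes from average-linkage clustering of 1 − ρ computed once on the
all-MIRs matrix (columns pre-sorted so ties are deterministic) and is reused
for the intergenic/intragenic submatrices. The Mantel statistic is the
Pearson correlation of the vectorized upper triangles, with a joint
row/column label permutation null and the add-one p; not-applicable entries
are masked pairwise, and 10³ permutations are the default. Promoter RNAPII
intensity is the sum of peak intensities with centers within ±2 kb of the
TSS — the same window as anchor mapping. Nearby-gene correlation strata use
the nearest gene TSS within 10 kb, split by same/opposite strand.
Expression contrasts across interaction models are one-sided Mann–Whitney
tests in the order mir_mir ≥ mir_gene_only ≥ basal ≥ not_assigned.

## Synthetic data

The generator emulates the study conditions at desk scale: two cell lines
with 3 (K562) and 4 (MCF7) replicates; 4 chromosomes × 12 Mb; 500 genes and
150 MIRs, half intragenic (placed inside a host gene on the same strand);
10 polycistronic clusters with 4–8 kb internal gaps; TSS evidence split
0.546/0.180/0.118/0.156 across curated/CAGE/RNAPII/none, mirroring the real
annotation's tier proportions. Promoterless ("none") MIRs are intergenic
singles placed in 60–80 kb peak deserts so no neighbouring evidence reaches
their search window. For every other MIR the generator places its intended
evidence and then computes the *effective* TSS by running the same promoter
cascade the pipeline uses — planted anchors, placement units and the
partition are built on effective TSSs, so annotation and ground truth agree
by construction (an RNAPII-tier MIR that adopts a neighbour's CAGE tag is
planted at that adopted position).

Communities are planted over *placement units* — groups of entities whose
TSSs lie within 6 kb of each other — because an anchor (width 0.5–4 kb,
centred on a TSS) can reach at most 4 kb, so no anchor can capture an entity
outside its own unit's block: cross-community captures are impossible by
construction. Each block gets a random spanning tree plus extra edges
(rate 0.4 per member); each planted edge is emitted independently per
replicate with probability 0.8 (the `edge_reproducibility`), giving the
textbook ≥2-of-3 recovery probability 1 − (0.2³ + 3·0.8·0.2²) = 0.896 at
K562's three replicates. Noise contacts (Poisson, mean 30 per replicate)
are drawn from never-reused unit pairs, so every noise-derived entity pair
is single-replicate by construction and the ≥ 2-replicate filter removes
them all. 20 % of blocks are cell-specific (edges restricted to one cell
line). Clustered MIR pairs inside one block are additionally planted at
exactly one replicate to exercise the neighbour rule.

Targets are Bernoulli over all (MIR, gene) pairs at base rate 0.06,
multiplied by 5 between the two planted enriched community pairs and by 0.2
within a community; database support is drawn from
(0.35, 0.30, 0.15, 0.10, 0.06, 0.04) over 1–6 databases, so the ≥ 2-database
filter keeps ~65 %. The enriched pairs join a MIR-dense "hotspot" block to a
gene-rich partner block: because the hypergeometric margins include each
community's own incidence, enrichment between two *balanced* blocks is
bounded near 2.5× background regardless of the multiplier, whereas the
hotspot/partner asymmetry transmits the full multiplier. Hotspot blocks
also mirror the MIR-dense regions of the real interactome.

Activity is log-normal per entity (×3 for planted members, ×0.3 for
promoterless MIRs; intragenic MIRs inherit their host's activity with
log-noise 0.3); expression is activity raised to `expression_activity_effect`
times log-normal noise (σ = 0.5), with a ×3 / ×⅓ boost/penalty in the
planted cell line for cell-specific blocks. Sixteen chromatin marks (11
active, 5 repressive) receive Poisson counts within ±4.5 kb of each
promoter, with idiosyncratic per-mark baselines and slopes in the
rank-normalized activity — the distinct slopes keep marks distinguishable,
so a label permutation cannot reproduce the observed correlation pattern
and the Mantel test has resolution. Families and disease labels are themed
per block (cluster members share a family; block members adopt a theme
disease with probability 0.6) over the 10 disease classes used in the
per-community χ² analysis.

What the generator does *not* emulate: genome-scale gene counts, real
miRBase content, realistic PET-count or anchor-size distributions,
overlapping genes, and any sequence-level signal. Passing tests therefore
demonstrate correctness of the algorithms and calibration of the statistics
under planted structure, not biological conclusions about real cell lines.

## Problem sizes and defaults

Tests and the acceptance script run the generator at its default scale
(500 genes / 150 MIRs / 40 communities, 10³ permutations for single
analyses; 99–200 permutations inside multi-seed calibration loops, whose
discreteness the corresponding thresholds account for). The calibration
suites use 20–200 seeds per property. These sizes were chosen once as the
smallest at which every planted effect is unambiguous and every null is
well-sampled.

## Known limitations

- Communities are connected components; modularity-based partitions are not
  implemented (the component reading is the one under which a unique giant
  community exists).
- Indirect MIR linkage uses one shortest path per pair; alternative paths
  with different replicate support are not enumerated.
- The hypergeometric margin convention for community links is pair-based;
  gene-based margins would give different (typically more conservative)
  p-values.
- Term enrichment treats terms as flat labels — no ontology DAG semantics.
- The within-community depletion 2×2 table convention (giant-incidence ×
  within/between) is one documented reading; other tables are constructible
  from the same mapping frame.
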