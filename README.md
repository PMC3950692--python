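# mirchromnet

Analysis pipeline linking RNAPII-associated 3D chromatin interactions
(ChIA-PET) to the transcription of microRNA genes (*MIRs*). Written for
regulatory-genomics researchers who want to reproduce, stress-test or extend
this kind of integrative analysis: the package implements every stage as a
plain Python API, ships a seeded synthetic-data generator with planted ground
truth, and exposes a thin `mirchromnet` command line over the same functions.

## What it computes

Starting from processed inputs — MIR/gene annotations (GFF3), RNAPII and
histone-mark peaks (BED/TSV), duplex ChIA-PET interactions per cell line and
replicate (BEDPE + pet_count, cell_line, replicate_id), curated TSS and CAGE
evidence, expression tables (FPKM/RPM) and miRNA–target predictions — the
pipeline performs:

1. **Tiered MIR promoter annotation.** TSS evidence precedence
   curated > CAGE > RNAPII; for CAGE/RNAPII the nearest candidate within the
   50 kb strand-aware upstream window of the pre-miRNA 5′ end wins. Promoters
   are *shared* when a coding-gene TSS lies within ±2 kb.
2. **Chromatin interaction network.** Entities map to interaction anchors
   through ±2 kb TSS windows; an entity pair becomes an edge only if one cell
   line recovers it in ≥ 2 replicates; *chromatin communities* are the
   connected components, the largest being the giant community.
3. **MIR interaction models.** Each MIR is `basal` (standalone promoter
   RNAPII peak), `interaction` (network node; submodel `mir_mir` when it
   contacts other MIRs) or `not_assigned`. MIR–MIR pairs need ≥ 2 replicates
   unless they are genomic neighbours (≤ 10 kb; then ≥ 1).
4. **Community-level target enrichment.** Filtered target pairs
   (≥ 2 databases) map onto communities; community pairs with ≥ 10 pooled
   pairs are tested with an upper-tail hypergeometric test

   *P*(X ≥ k), X ~ Hypergeom(N, K, n), with N = all mapped between-community
   pairs, K/n = pairs incident to the two communities, k = their pooled count,

   Benjamini–Hochberg controlled at FDR ≤ 0.001. Within-community depletion
   is tested with Fisher's exact test, and permutation controls (10³
   resamples, add-one empirical FDR) compare the percent of community genes
   targeted against same-size random gene sets.
5. **Family/disease co-localization.** Within-family and within-disease
   contact counts against a null that redraws the same number of contacts
   uniformly from all networked MIR pairs; disease-category concordance of
   edges; per-community χ² disease-class enrichment (p < 0.001, classes with
   ≥ 2 MIRs).
6. **Marks and expression.** Spearman mark-correlation matrices around MIR
   promoters (±5 kb counts) with average-linkage clustering, Mantel tests
   between MIR subsets, RNAPII-intensity–expression reports and one-sided
   Mann–Whitney expression contrasts across interaction models.

The `simulate` module generates a complete synthetic input bundle with
planted communities, replicate structure, noise contacts, enriched target
community pairs and activity-driven expression/marks — every downstream
result is checkable against `ground_truth.json`.

## Worked example

```python
from mirchromnet import SimulationConfig, simulate_bundle
from mirchromnet.pipeline import analyze_bundle

bundle = simulate_bundle(SimulationConfig(seed=1))
res = analyze_bundle(bundle)
print(len(res.communities), res.mapping.within_percent,
      sum(l.significant for l in res.links))
```

prints `40 0.6 2`: the replicate filter recovers the 40 planted chromatin
communities from 3 187 duplex interactions, only 0.6 % of the 1 425 mapped
miRNA–target pairs arise within a community (the planted self-depletion),
and exactly the two planted enriched community pairs are significant at
q ≤ 0.001 (q = 1.6 × 10⁻⁷ and 2.5 × 10⁻¹⁰). The scripts in `examples/`
walk through each capability one at a time and print what the numbers mean;
the same steps run file-to-file via

```bash
mirchromnet --seed 1 --outdir out simulate
mirchromnet --seed 1 --outdir out annotate-promoters --mirs out/mirs.gff3 \
    --genes out/genes.gff3 --curated out/curated_tss.tsv \
    --cage out/cage.bed --peaks out/peaks.tsv
# ... build-network, assign-models, enrich-targets, family-disease,
#     expression-report
```

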