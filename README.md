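# pleiobgs

**Degree of pleiotropy of GWAS loci versus effect size, allele frequency and
background selection.**

`pleiobgs` is a reusable pipeline for a recurring population-genetics
question: are variants associated with *many* traits (highly pleiotropic
loci) under stronger purifying selection than variants associated with one?
Direct selection coefficients are not observable from association catalogs,
but the background-selection statistic **B** — the expected fraction of
neutral diversity remaining at a position after linked purifying selection
(B = 1: no loss; B = 0: complete loss) — is mapped genome-wide, and so is
the local recombination rate **RR** (cM/Mb), which confounds it: linked
selection removes more diversity where recombination is low.

The pipeline takes a GWAS-Catalog-style association table, gene coordinates
(BED/GFF3), a B track (bedGraph dialect) and a genetic map (HapMap dialect),
and optionally a pleiotropic-region table, and computes:

1. **Filtering** — complete autosomal records with p ≤ 5×10⁻⁸, one SNP per
   (gene, trait) pair (lowest p), traits backed by ≥ 30 loci and ≥ 3
   studies, near-duplicate traits merged by gene-set overlap (Jaccard ≥ 0.5,
   single linkage).
2. **Liability-scale effects** — odds ratios for dichotomous traits are
   converted to per-allele liability effects β by the threshold model
   (prevalence K fixes the threshold t = Φ⁻¹(1−K); genotype penetrances
   satisfy a multiplicative-odds constraint and Σᵢ fᵢpᵢ = K), and each locus
   contributes h² = 2β²q(1−q) to heritability.
3. **Degrees** — each locus's pleiotropy degree (number of distinct traits,
   post-clustering) with per-degree summaries of |2β|, within-locus effect
   SD, MAF and h².
4. **Annotation** — B and RR at SNP positions (point lookups) or averaged
   over genes/regions (length-weighted means over covered bases), with the
   MHC window (chr6:25–34 Mb, GRCh37) masked.
5. **Inference** — the simple regression b of B on degree and the partial
   regression B ~ b₀ + b′₁·degree + b′₂·log₁₀(RR), which asks whether B
   declines with pleiotropy *net of* recombination.

It also ships a seeded synthetic-data generator that emulates all four
inputs with planted, machine-readable parameters (effect–degree slope,
MAF–degree slope, B–degree and B–RR partial slopes), so every stage has a
parameter-recovery test. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

Generate a synthetic bundle and run the analysis:

```sh
pleiobgs simulate --seed 1 --out demo
# wrote 11 files to demo (4938 catalog rows)

cat > run.yaml <<EOF
catalog: demo/catalog.tsv
genes: demo/genes.bed
b_track: demo/b_track.bedgraph
genetic_map: demo/genetic_map.txt
prevalence: demo/prevalence.yaml
domains: demo/domains.tsv
EOF

pleiobgs run --config run.yaml --out report
```

The run prints its provenance counts:

```
input_rows            4938
parsed_records        4938
significant_records   4545     # p <= 5e-8; 393 planted non-significant rows removed
trait_loci            3956     # one SNP per (gene, trait); duplicates collapsed
trait_loci_after_trait_filter 3933   # 2 noise traits (<3 studies / <30 genes) removed
traits_kept           41
loci                  2000
pleiotropic_loci      982      # degree >= 2 (49.1% of loci)
mhc_removed           59       # genes overlapping chr6:25-34 Mb
regression_rows       1941
```

and `report/regressions.tsv` holds every fit. From this seed-1 run:

| analysis | slope on degree | interpretation |
|---|---|---|
| effect ~ degree | 0.0350 | homozygous effect grows with degree (planted 0.035) |
| MAF ~ degree | 0.0050 | common alleles are more pleiotropic (planted 0.006) |
| B ~ degree (simple) | −0.0206 | diversity loss increases with degree |
| B ~ degree + log₁₀RR (partial) | −0.0199 | …and not because of recombination (planted −0.02) |
| B ~ log₁₀RR (partial) | 0.1506 | B rises with recombination, as expected (planted 0.15) |

A negative partial slope of B on degree means more pleiotropic loci sit in
regions that have lost more linked neutral diversity, holding recombination
fixed — the signature of stronger purifying selection on pleiotropic
variants.

## Command-line interface

`pleiobgs` exposes `simulate`, `run`, `regions` (region-table analysis), and
the individual stages `filter`, `convert`, `annotate`, `regress`. Exit codes
distinguish configuration (2), format (3) and numerical (4) errors. All
orchestration is a thin layer over the importable library
(`pleiobgs.run_analysis`, `pleiobgs.GeneratorConfig`, ...).
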