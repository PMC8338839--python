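# Methods

## The question the pipeline answers

A locus detected by genome-wide association studies may be associated with
one trait or with many; the number of distinct traits is its *degree of
pleiotropy* (degree 1 = non-pleiotropic). Pleiotropic variants are expected
to be under stronger purifying selection, because a mutation affecting many
traits has more ways to be deleterious. Direct selection coefficients are
not observable from association catalogs, but the *background-selection
statistic* B is: for every genomic position it gives the expected fraction
of neutral diversity remaining after linked purifying selection (B = 1, no
loss; B = 0, complete loss). Because B also depends on the local
recombination rate (RR, in cM/Mb) — linked selection bites harder where
recombination is low — any association between B and pleiotropy degree must
be assessed *net of* recombination. The pipeline therefore ends in a
two-predictor least-squares fit,

    B ~ b0 + b1·degree + b2·log10(RR),

whose partial coefficient `b1` is the quantity of interest, alongside the
simple regressions of effect size, minor allele frequency (MAF) and
heritability contribution on degree.

## Stages and their assumptions

**Catalog filtering** (`catalog`). Association rows need a SNP id, mapped
gene (or intergenic label), trait, study accession, p-value, effect (odds
ratio or beta) and risk-allele frequency; incomplete rows are dropped and
counted. Analysis is restricted to autosomes. Associations with p > 5e-8
are removed (the boundary itself is kept: only *worse* significance is
disregarded). One SNP per (gene, trait) pair is retained — the lowest
p-value, with ties broken by larger |effect| then lexicographic SNP id so
results never depend on file order. Traits keep their loci only if backed
by at least `min_genes` distinct loci (default 30) and `min_studies`
distinct studies (default 3), the study count taken over significant
records before deduplication. Finally, traits whose retained gene sets have
Jaccard similarity ≥ 0.5 are merged single-linkage into one cluster
(label = lexicographically smallest member), so near-duplicate phenotypes
do not inflate degrees; the threshold is configuration.

**Liability-scale effects** (`effects`). For a dichotomous trait of
prevalence K, liability is standard normal with threshold t = Φ⁻¹(1−K).
A per-allele odds ratio OR with risk-allele frequency q fixes genotype
penetrances p_i through odds(p_i) = odds(p_0)·ORⁱ and the population
constraint Σ f_i p_i = K (Hardy–Weinberg f_i). The constraint is monotone
in log-odds(p_0) and solved by bracketed root finding (Brent scalar path;
an 80-step vectorised bisection for whole columns), to a residual ≤ 1e-12.
Genotype liability means are recovered as μ_i = t − Φ⁻¹(1 − p_i), assuming
unit within-genotype variance, and β is the f_i-weighted least-squares
slope of μ_i on allele count — the allele-substitution effect. OR = 1 is
short-circuited to β = 0 exactly. Quantitative traits bypass conversion (β
in trait-SD units as reported). Prevalence is *required* configuration for
every odds-ratio trait; there is no default. Each locus contributes
h² = 2β²q(1−q) to heritability; downstream summaries use the absolute
homozygous effect |2β|, since risk-allele coding makes signs arbitrary
across traits.

**Degrees and summaries** (`pleiotropy`). Degree = number of distinct trait
labels per locus, counted after clustering. Effect and h² summaries pool
trait–locus observations; MAF is per locus. Two dispersion statistics are
kept deliberately distinct: the mean *within-locus* SD of a locus's several
effects (defined only for degree ≥ 2; undefined, not zero, for degree 1),
and the variance *across loci* of per-locus mean effects, which declines
with degree by the law of large numbers alone and is reported only as a
contrast. Regressions of effect and h² on degree run over per-observation
data and MAF over per-locus data — a choice forced by the arithmetic of
tiny R² with highly significant p in this kind of analysis, which requires
thousands of points; only the SD regression runs on the handful of
per-degree means.

**Genomic tracks** (`tracks`). B and RR are piecewise-constant tracks;
internally all coordinates are 0-based half-open, converted once at the
boundary (catalog positions and GFF3 are 1-based; genetic-map positions are
taken as 0-based segment starts). SNPs get point values; genes and regions
get length-weighted means over covered bases only, with the coverage
fraction reported so users can filter (uncovered bases are never imputed).
B maps distributed as integers 0–1000 are auto-detected (max > 1) and
rescaled. log10(RR) floors the rate at ε = 1e-3 cM/Mb first, since zero-rate
segments would otherwise be undefined; ε is configuration. The MHC window
(chromosome 6, 25–34 Mb, GRCh37) is masked for the B/RR analyses: points
inside it are removed, intervals on any overlap (the conservative reading
of "in or strongly linked to" the region). The mask is idempotent.

**Inference** (`regress`). Ordinary least squares via statsmodels, wrapped
to enforce the contracts: n ≥ 3 (simple) or ≥ 4 (two predictors), a
non-constant predictor, a full-rank design (an affine dependency raises a
collinearity error), F-tests with (1, n−2) or (2, n−3) df. A constant
response returns slope 0 and R² = 0 by convention rather than a 0/0. The
recombination covariate is log10(cM/Mb) by default with a raw-rate switch,
since either scale is defensible; degree always enters as a numeric
covariate (one slope per unit degree), never as a factor.

## The synthetic generator

`simulate.GeneratorConfig` defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_traits / n_genes | 41 / 2000 | robust traits and candidate loci |
| degree law | geometric r = 0.5, max 12 | P(d) ∝ r^(d−1), d ≤ 12 |
| effect model | 0.2 + 0.035·d ± N(0, 0.05) | homozygous effect \|2β\| |
| MAF model | 0.15 + 0.006·d ± N(0, 0.04) | per-gene MAF, clipped to (0, 0.5] |
| B model | 0.75 − 0.02·d + 0.15·log10RR ± N(0, 0.03) | per-gene B, clipped [0, 1] |
| RR model | log10RR ~ N(0, 0.4), truncated ±3.5σ | per-segment rate |
| background B | N(0.77, 0.05) | inter-gene segments |
| OR traits | 50%, K ~ U(0.01, 0.2) | dichotomous traits and prevalences |
| filter fodder | 15% duplicate SNPs, 10% non-significant rows, 3 noise traits | exercise every filter |

The planted slopes echo the magnitudes reported for real trait panels
(effect ≈ 0.035 per degree; B ≈ −0.02 per degree and ≈ +0.15–0.33 per
log10 cM/Mb) so desk-scale runs live in a realistic regime; they are
generator defaults, not empirical claims. Noise scales are sized so the
linear laws essentially never hit their clip bounds, keeping recovery
unbiased; B-model residuals are Gaussian so the OLS t-tests are exact,
which the null-calibration test (planted slope 0 → uniform p-values)
depends on. The degree ratio 0.5 populates degree classes up to ~10–12 at
n = 2000, which the degree regressions need for leverage; the trade-off is
a pleiotropic fraction (~50%) higher than curated real catalogs (~23–49%),
since a truncated geometric cannot match both a low pleiotropic fraction
and a populated degree-12 class at this size. No within-locus SD–degree
slope is planted (effect noise is homoscedastic), so the SD regression's
true slope is 0.

Each gene hosts exactly one SNP per associated trait at distinct in-gene
positions; there is no linkage disequilibrium, ascertainment/winner's-curse
effect, or population structure — so recovery tests validate the degree
logic and the regression machinery, not robustness to those real-data
features. B and RR are constant across each gene body with independent
baseline segments filling the genome, giving interval means a closed-form
truth. Odds ratios for dichotomous traits are obtained by numerically
inverting the liability conversion at the planted β (bisection on log OR),
so conversion back recovers the planted effect to solver precision; the
forward threshold construction would instead carry a small systematic
approximation error into every planted-slope recovery. The truth files
(per-locus and per-observation TSV plus a JSON parameter block) carry every
latent value, and identical (config, seed) bundles are byte-identical.

## Numerical choices

- Penetrance solve: bracketed in log-odds by ±2|log OR| around odds(K);
  residual tolerance 1e-12, scalar Brent xtol 1e-13.
- Normal quantiles through `scipy.special.ndtri` on the precise branch
  (μ_i = t + Φ⁻¹(p_i), t = −Φ⁻¹(K)) to avoid 1−p cancellation.
- File parsing re-runs valid numeric fields through numpy's correctly
  rounded strtod, because pandas' fast parser loses the last bit and the
  bundles must round-trip bit-identically.
- h² is computed as 2·β·β·(q·(1−q)) so allele relabelling q ↔ 1−q is exact
  in floating point.
- Ties, sorts and groupbys use stable (mergesort) ordering everywhere a
  result could otherwise depend on input order.

## Problem sizes used by the test suite

Unit tests run on 80–300-gene bundles; the parameter-recovery test runs 100
end-to-end replicates at the default n_genes = 2000 (about 3 minutes on one
CPU) and a 500-replicate null calibration at 200 regions each. These sizes
were chosen as the smallest at which the Monte-Carlo standard errors are
tight enough to make the ±2-SE recovery check informative.

## Known limitations

- The liability conversion assumes per-allele (multiplicative-odds) odds
  ratios and unit within-genotype liability variance; for |β| ≳ 0.5 the
  unit-variance approximation degrades.
- Trait clustering is single-linkage on Jaccard overlap of gene sets; with
  many intermediate-overlap traits it can chain. Real analyses may prefer a
  curated trait grouping supplied as configuration.
- Interval means weight every covered base equally; no within-gene
  weighting (e.g. exon density) is attempted.
- The region-table path assumes the degree column is already the median or
  maximal per-region degree; the pipeline does not recompute it from SNPs.
- No liftover: all coordinates are assumed to share one genome build.
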