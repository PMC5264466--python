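# Methods

## Scope and model

`eqtlkit` maps expression quantitative trait loci (eQTLs) in a
microarray-style setting: expression is summarized at two levels —
probesets, each targeting one exon, and transcript clusters, each the mean
of a gene's probesets — and genotypes are effect-allele dosages in [0, 2]
with per-SNP minor-allele-frequency and imputation-quality metadata.
Inclusion filters (MAF ≥ 0.01, imputation R² ≥ 0.3 by default) are applied
at load time with per-criterion exclusion accounting.

The association model is an additive linear model per SNP × transcript
pair. Adjustment is two-phase: (1) per-feature residuals on the biological
covariates (sex, age, platelet count, white-cell count, lymphocyte /
monocyte / eosinophil / basophil percentages), with an optional
generalized-least-squares path, covariance σ²(I + θ·kinship), θ per
feature by profile likelihood on a grid (grid {0} ∪ logspace(−3, 1, 9) —
wide enough to cover no-family to strong-family variance ratios); (2) a
per-pair ordinary-least-squares fit of the residual on mean, sex, age, K
latent factors, and dosage. Sex and age appear in both phases; that
redundancy is harmless (the second-phase coefficients are ~0) and keeps
the per-pair design explicit.

### Degrees of freedom of the two-phase fit

Because phase 1 consumes dimensions that the per-pair design does not
refit, the scan carries the phase-1 design matrix along with the
residuals, projects *both* the expression residuals and the dosages onto
the orthogonal complement of the combined design span, and uses
df = n − rank(combined) − 1. With this accounting the null t statistic is
exactly t-distributed and the genomic-control factor of fully null scans
is 1.00 within Monte-Carlo error; without it, λ is biased by about
rank/n (≈ 2% at n = 500). `fit_pair`, the reference single-pair fitter,
takes an explicit covariate matrix and uses the classical df = n − p.

### Retention, FDR, genomic control

Only pairs with P < 1e-4 are stored, but all evaluated tests are counted.
Benjamini–Hochberg q-values are computed separately for cis and trans
records, each ranked against its stratum's *total* test count — the stored
records are the smallest-P subset, so they occupy the smallest global
ranks and the cummin over stored ranks is exact. Stratum denominators
count a pair as cis when the SNP lies within 1 Mb of the transcript's
TSS; the final record label can still be upgraded to cis by long-range
block construction (below). λ = F⁻¹(median P)/F⁻¹(0.5), F the upper-tail
χ²(1) CDF, is computed from the full P-value set of a random SNP
subsample; `gc_adjust` divides the implied χ² statistics by λ and
recomputes P.

### Blocks, cis/trans, leads

Significant SNP positions per transcript and chromosome are merged
single-linkage with a 1 Mb gap cutoff (equivalent to sorting and cutting
at gaps > 1 Mb; verified against a brute-force all-pairs merge). A block
is cis iff it is on the transcript's chromosome and spans the TSS or has
a member within 1 Mb of the strand-aware TSS. The primary lead is the
smallest-P member (ties: smaller position, then lexicographic SNP id).
Secondary leads are admitted by forward stepwise regression: candidates
are block members with LD r² < 0.36 against *every* current lead — not
only the primary — because that is the only reading that guarantees the
invariant that all pairs of leads are mutually independent; each step
refits all leads jointly plus the candidate and admits the smallest
conditional P if below 1e-4.

### Trans hotspot clusters

SNPs with ≥ 6 extrachromosomal FDR-significant targets are eligible. Per
chromosome, the unclustered eligible SNP with the smallest min-P seeds a
cluster; neighbours are scanned outward by position and join while
d(A, B) = 1 − |A∩B|/min(|A|,|B|) < 0.7, where A is the union of current
member target sets; each side stops at its first failing candidate;
the restart seed is again the smallest remaining min-P. Single-member
clusters are kept in a secondary table rather than the headline table.

### Polymorphism-in-probe flags

Probe–SNP overlap uses half-open intervals (start inclusive, end
exclusive) and is verified against a quadratic oracle. A SNP under a
probe triggers a flag when its gene-level R² exceeds 90% of the
transcript's lead R² *and* its exon-level R² for the overlapped probeset
exceeds 95% of the maximum exon-level R² over all cis SNP × probeset
pairs of the cluster; exon records absent from the retained table count
as R² = 0 (conservative for the maxima), and a cluster with overlaps but
no exon-level records at all is reported undecidable rather than
silently unflagged. A trigger marks every record of the transcript
cluster.

### Enrichment and replication

LD pruning is a greedy sweep over SNPs ordered by min-P (insignificant
last), dropping later SNPs with r² > 0.3 to a kept SNP; "LD > 0.3" and
"80% LD" are read as r² thresholds throughout, consistent with the other
R²-denominated rules. LD is evaluated in-sample from dosages and only
within 1 Mb (farther pairs are treated as unlinked). Enrichment 2×2
tables use the pruned set as the sampling frame; gene-set enrichment is
one-sided Fisher (equivalently a hypergeometric tail), applied per
cluster only when the intersection has ≥ 6 genes. Positional enrichment
assigns each lead to one of eight disjoint region classes in a 2 Mb
TSS-centered window; UTR proxies (300 bp at the transcript ends, since
the simulated annotation carries no true UTR boundaries) take precedence
over the exon classes so the classes stay disjoint. Internal replication
requires FDR < 0.05 in both halves of a split and reports per-stratum
rates plus sign concordance; external validation matches leads to an
external table directly or through an r² > 0.8 proxy, restricted to
pairs the external study could have seen, with the expected count equal
to the external detection rate times the eligible pair count.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions used by the acceptance experiments.

* **Genotypes.** Two haplotypes per sample are drawn by thresholding
  equicorrelated standard normals (correlation `ld_rho` = 0.8 within
  blocks of 5 consecutive SNPs) at the allele-frequency quantile; dosage
  is their sum, so LD decays to zero across blocks and has a
  population-genetic interpretation. MAF ~ U(0.05, 0.5); imputation
  quality ~ U(0.3, 1). Optional bounded noise produces fractional
  "imputed" dosages.
* **Annotation.** Non-overlapping genes (20–100 kb) with alternating
  strand, 4–10 probesets per gene, one 25 bp probe per probeset inside
  its exon. Coordinates are 0-based half-open internally, 1-based
  inclusive in GFF-style files, 0-based in BED.
* **Expression.** Exon value = gene baseline + planted genetic effects +
  covariate effects + latent-factor contribution + probeset noise
  (sd 0.5); the gene level is the exact probeset mean. Cis SNPs are
  chosen with probability decaying exponentially from the TSS (scale
  30 kb, matching the tens-of-kilobases scale at which lead eQTLs
  concentrate around transcription starts); planted cis effects have
  fixed magnitude 0.5 with random sign. Trans hotspots (default 2, 8
  extrachromosomal targets each, |β| = 0.4) act directly or through a
  latent platelet-proportion mediator; target sets are disjoint across
  hotspots so each planted locus is an identifiable cluster. Artifacts
  plant |β| = 1 on exactly one probeset, driven by a freshly synthesized
  unlinked SNP placed inside that probeset's probe — synthesizing the
  variant (rather than relocating an existing one) avoids creating
  impossible long-range LD between the probe SNP and its former
  neighbours.
* **Covariates and confounders.** Sex is Bernoulli(½), age U(30, 70),
  cell counts roughly calibrated to adult whole-blood reference ranges;
  3 latent confounders with N(0, 0.3) gene loadings. All randomness
  flows from one integer seed through named substreams.

What the generator does **not** emulate: realistic allele-frequency
spectra or recombination maps, population structure and relatedness
(kinship is only consumed, never simulated), probe-level sequence
affinity, count noise or batch × intensity interactions of real arrays.
Passing recovery tests therefore demonstrates correctness of the
*algorithms* under the stated generative assumptions, not performance on
real cohort data.

## Two-pass factor estimation

Latent factors are estimated by truncated SVD on the residualized
expression — an iterated-PCA stand-in for a Bayesian factor model, chosen
to keep the dependency surface small; the interface accepts any
sample-space factor matrix. At desk scale a genuine trans hotspot spans a
fifth of all genes, so a single PCA pass absorbs the hotspot signature
into a "confounder" and the scan then both loses true targets and gains
collider-induced false ones. The pipeline therefore runs two passes:
scan once, regress each transcript's strongest retained SNP per
chromosome out of the residuals, re-estimate factors on that cleaned
matrix, and rescan with the cleaned factors. With thousands of genes
this distinction is negligible; at 40 genes it is the difference between
~50% and ~95% hotspot target-set recovery.

The default factor count is 20 (appropriate for transcriptome-wide
feature counts); the desk-scale experiments use K = 3, equal to the
simulated confounder dimension, because at 40 transcripts a 20-factor
model would consume half the feature space.

## Problem sizes and numerical choices

Null calibration uses 20 simulations of 500 SNPs × 50 transcripts × 500
samples; recovery studies use 20 seeds at n = 2000 with 4 × ~150 SNPs
and 40 transcripts — sizes chosen so the full suite runs in minutes on
one CPU while keeping ≥ 95% power for the planted effect sizes.
All P-value ties are broken by genomic position then identifier;
association tables are sorted deterministically; all outputs are
byte-identical across reruns with the same seed. Zero-variance dosages
are skipped with a logged count, not an error, since fixed-seed
subsampling can produce monomorphic SNPs. Missing covariate cells other
than cell counts are an error rather than silently imputed; cell counts
are imputed by partial-least-squares regression on expression over
samples with measured values (measured values are never overwritten, and
cross-validated R² per field is reported).

## Known limitations

* The stepwise search is restricted to members of the original block; a
  secondary signal just outside the block is not considered.
* The λ subsample at desk scale is all SNPs rather than a 100k random
  subset; the subsample size is recorded in the diagnostics.
* GLS θ is a grid estimate, not a full mixed model; with strong, dense
  relatedness a dedicated mixed-model package should be preferred.
* The region classifier's UTR boundaries are fixed-width proxies; with a
  real annotation carrying UTR intervals the classifier should be fed
  those directly.
* Catalog SNPs absent from the genotype panel cannot be proxy-matched and
  are counted and logged; the proxy search window (1 Mb) is configurable.
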