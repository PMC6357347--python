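# Methods

This note documents the statistical models, conventions and design
choices behind `exonskip`, and what the synthetic-data generator does and
does not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open; GTF and VCF are 1-based
at the file boundary and BED is 0-based half-open, so exactly one
conversion site exists per format. Overlapping exon records within a gene
are flattened into disjoint counting bins by breakpoint union before any
counting or scanning — annotation-derived exon bins must be disjoint for
"reads per exon" to be unambiguous. Bin identifiers are
`<gene_id>:E001`-style in genomic order. Only biallelic SNVs enter the
splicing decision model; multi-allelic records and indels are skipped
with a logged warning. The GTF reader/writer is implemented in-package:
the contract here is line-level validation with parse errors that name
the offending line, over flat exon/CDS features, which a database-backed
annotation library would not add value to.

## Differential exon usage

The usage of exon *e* in sample *s* is its share of the gene total,
`u(e,s) = y(e,s) / T(g,s)` after size-factor normalization (the factors
cancel in the ratio; they are estimated by median-of-ratios against the
geometric-mean pseudo-reference, restricted to exons positive in all
samples, with a total-count fallback).

Each exon is tested on the paired counts (this exon, rest-of-gene): a
binomial GLM (logit link) of `y(e,s)` successes out of `T(g,s)` trials on
a condition indicator. Conditioning on the observed gene total is the
exact analogue of a per-sample offset/sample-effect term in a count-level
GLM — it removes sequencing depth and per-sample gene expression from the
problem without estimating them — and is what makes the test calibrated
at small sample sizes. Biological overdispersion (count-level variance of
the form μ + αμ² propagates to extra-binomial variance of the usage
proportions) is absorbed by a per-exon Pearson dispersion factor

    φ = max(X²_Pearson / (n − 2), 1),

estimated by moments with no information sharing across exons (sharing
buys power but costs transparency; the package trades the other way and
validates against simulation truth). The Wald statistic on the condition
coefficient is divided by √φ and referred to a t distribution with n − 2
degrees of freedom. Measured on null simulations at the emulated study
scale (24 vs 50 samples, dispersion 0.05, ~2000 exons) the rejection rate
at p < 0.05 is ≈ 0.05–0.06, and power at an inclusion drop of 0.6 → 0.3
is ≈ 1.

Degenerate inputs: exons of single-bin genes are skipped (usage relative
to "rest of gene" is undefined), as are exons whose own or rest-of-gene
counts are all zero; samples with a zero gene total are dropped per exon;
fewer than two usable samples per condition yields a missing p-value.

**Fold change** is reported oriented ≥ 1 with the direction
(`lower_in_case` / `higher_in_case`) carried separately. It is computed
on size-factor-normalized exon counts by default (`fold_change_on=
"counts"`), matching how exon-level "expression" fold changes are
conventionally reported, and because the normalized-count ratio equals
the generative inclusion ratio ψ_control/ψ_case exactly; a relative-usage
variant (`"usage"`) is exposed, but its ratio is additionally shifted by
the gene-total renormalization (for a gene with few exons the usage ratio
of a 0.6→0.3 inclusion drop can fall below 1.8). Skipping events are
called at FDR < 0.05 and fold change > 1.5, both strict, sorted by FDR
then exon id.

**Benjamini–Hochberg** adjustment is the step-up procedure with the
cumulative-minimum monotonicity pass from the largest rank (the semantics
of R's `p.adjust(method="BH")`); missing p-values are excluded from the
number of tests and stay missing. The one-way chi-squared helper is the
Pearson goodness-of-fit statistic with k − 1 df against equal expected
proportions unless expected counts are given.

## SRE scanning and the splicing decision model

Hexamer matching is exact and case-insensitive with no ambiguity codes.
ESE/ESS sites are searched within exon bins; ISE sites within introns,
either whole (`intron_flank="full"`, the default — the intronic search
space is deliberately unbounded) or restricted to a window from each
exon boundary. Minus-strand genes are scanned on the reverse complement
with site coordinates reported on the forward strand; overlapping matches
are all reported. The scanner is property-tested against a brute-force
all-positions substring oracle.

A SNP inside a site yields one record per overlapping site with its
1-based offset within the hexamer *on the motif's strand* (so "5th base"
means the 5th base of the motif as written, also for minus-strand genes).
The decision rule retains an overlap iff the linked exon is a called
skipping event: the embedding exon for exonic sites, either flanking exon
of the host intron for intronic sites (the linkage is deliberately
side-agnostic; the nearest exon is recorded as the anchor). Effect calls
are `enhancer_loss_promotes_skipping` for ESE/ISE and
`silencer_loss_promotes_inclusion` for ESS. The reference allele must
equal the motif base at the SNP's offset (strand-aware); mismatches —
annotation/genotype inconsistencies — are dropped with a warning. If the
alternate allele turns the window into a different perfect motif of any
class this is recorded (`alt_creates_motif`) but the call is still
emitted: the model is loss-of-perfect-match, and interpretation of a
motif swap is left to the user. Candidate SNPs are then filtered at
MAF strictly > 0.01 (computed from the genotypes, folded).

## Impact annotation

Frame status is pure mod-3 arithmetic on the exon's CDS length
(0 → non-coding). Residues are mapped from the strand-aware cumulative
CDS offset; adjacent exons share at most the junction codon's residue.
Domain annotations are a TSV input (protein_id, domain_id, 1-based
inclusive residue interval) rather than a live database query, so tests
run offline; any interval overlap counts as "encodes part of" the
domain. Each exon's frame effect is evaluated in isolation;
combinatorial multi-exon skipping is out of scope.

## Association

Per-SNP inference is OLS of the phenotype on dosage + covariates +
intercept (dosage additive 0/1/2 — no dominance model is fitted), with a
two-sided t test on the dosage coefficient; samples with missing values
are dropped pairwise and constant-dosage SNPs are flagged untestable.
Sex is coded M=1/F=0.

Family-wise correction is max-T on covariate residuals: the phenotype and
all dosages are residualized on the covariates once; for each of B
permutations the residual vector is permuted and every SNP's t statistic
recomputed (by Frisch–Waugh–Lovell this equals the full-model OLS t, and
the implementation's observed statistics match `fit_additive_model`
exactly); corrected p = (1 + #{b : max|t|_b ≥ |t_j|})/(B+1), so corrected
p ∈ [1/(B+1), 1]. B defaults to 10,000 (1,000 in the pipeline's default
config) and must be ≥ 100. Measured family-wise error at a 57-SNP family
under the global null is ≈ 0.04–0.06 at the 0.05 level. The permutation
unit (covariate residuals, family-wise) is this package's choice among
several defensible schemes and is documented as such, not asserted as the
only one.

## Synthetic data

The generator emulates a two-group hippocampal RNA-seq study at desk
scale with a separate genotyped/phenotyped cohort:

- **Counts**: exon count ~ NB(mean = sf_s · μ_gene · ψ_{e,cond},
  dispersion α) with variance μ + αμ². Defaults: 24 cases / 50 controls,
  gene mean 500 reads (lognormal spread 0.4), α = 0.05, size factors
  Uniform(0.7, 1.4), baseline inclusion per exon Uniform(0.4, 0.9) shared
  between conditions; each affected gene has one *internal* exon (so an
  intron flanks it on both sides) with ψ 0.6 (control) → 0.3 (case).
  ψ acts multiplicatively on the gene mean — the simplest generative
  model consistent with usage testing.
- **Samples**: age ≈ N(89, 7), education ≈ N(14.5, 3.1) clipped to
  6–21 years, ~55% male; Braak stages are clipped rounded normals
  (cases 4.4 ± 1.7, controls 2.76 ± 1.49) so ordinal staging analyses
  have an input path.
- **Sequences**: i.i.d. uniform ACGT background with hexamers planted
  verbatim from the scanner's point of view (reverse-complemented on the
  forward strand for minus-strand genes); planting positions are returned
  as truth.
- **Genotypes**: dosage ~ Binomial(2, MAF) per sample (Hardy–Weinberg,
  no linkage disequilibrium between SNPs).
- **Phenotype**: y = 1.2 + β·dosage + 0.005·age − 0.02·sex −
  0.005·education + N(0, σ²), defaults β = −0.1 (minor allele decreases
  the phenotype) and σ = 0.2, with the truth coefficients returned.

Everything is deterministic under the configuration seed, with
decoupled per-operation random streams. What the generator does **not**
emulate — and hence what passing tests cannot speak to — includes
junction reads (the usage signal here is count-level only), correlated
exons within a transcript, LD between SNPs, genotype uncertainty from
imputation, population structure, and any spatial structure in the
phenotype (a single global quantitative value stands in for voxel-wise
imaging).

## Pipeline

Stages run in a fixed order (usage test → SRE scan → splicing decision →
impact → association), each output written before the next stage starts;
a rerun with identical inputs and seed is bit-identical, and the manifest
records input checksums, thresholds, seed and package version. Thresholds
default to FDR 0.05, fold change 1.5, MAF 0.01 and are printed at
startup by the CLI. Any stage failure aborts with the stage name and a
nonzero exit status.

## Problem sizes used in validation

The packaged calibration suites use ~2000 exons for the null rejection
rate, 200 replicates of a 5-gene study for fold-change/power recovery,
200 replicates at n = 500 for OLS effect recovery, 300 outer replicates
of a 57-SNP family at B = 1000 for the family-wise error rate, and a
12-gene end-to-end fixture with a 500-sample genotype cohort. These sizes
keep every Monte-Carlo standard error small relative to the acceptance
bands while remaining quick on a single CPU.

## Known limitations

- No dispersion shrinkage across exons: at very low counts the usage
  test loses power relative to shrinkage-based tools.
- The usage test models condition only; covariate columns in the sample
  table are accepted but not entered into the exon model by default
  (whether they should be is data-dependent and left to the caller).
- Exact hexamer matching cannot represent degenerate motif families, and
  ISS elements are absent from the inputs by construction.
- The splicing decision model is a linkage rule, not a mechanistic
  prediction: it flags loss of a perfect motif next to an observed
  skipping event and does not score binding affinity.
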