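# Methods

## Study design

The package implements a metabolome-wide two-sample Mendelian
randomization (MR) screen with downstream triangulation.  Stages run
in study order: per-metabolite instrument selection → allele
harmonization with LD-proxy substitution → Wald/IVW estimation →
Benjamini–Hochberg prioritization (FDR ≤ 0.05 across all metabolites
tested against one outcome) → sensitivity diagnostics for the
prioritized metabolites → multivariable BMI adjustment → approximate-
Bayes-factor colocalization → bidirectional MR for colocalized
metabolites → hypergeometric enrichment → cohort validation.  The run
manifest conserves the funnel bookkeeping (tested = prioritized +
non-prioritized; coloc-tested = colocalized + non-colocalized +
skipped), which the tests assert.

## Models and estimators

**Instrument strength.** Per-SNP exposure variance explained uses the
standardized-trait approximation r² = 2β²f(1−f); the global
F = (R²/k)/((1−R²)/(n−k−1)) with R² the sum of per-SNP r² over clumped
(near-independent) instruments.  Metabolites with F < 10 are excluded;
the boundary F = 10 is retained.

**Clumping.** Greedy: keep the smallest-p SNP, drop every SNP within
±window_kb (default 500, i.e. a 1 Mb span) with panel r² ≥ 0.001,
recurse.  SNPs absent from the LD panel are dropped rather than
assumed independent (conservative).  Ties in p break on SNP id so the
output is order-invariant.

**Harmonization.** Outcome records are aligned to the exposure's
effect allele; swapped alleles flip the beta sign and complement the
frequency, strand flips are complemented then matched.  Palindromic
(A/T, C/G) SNPs are oriented by allele frequency and kept only when
the minor-allele frequency is below 0.42 in both studies (configurable);
otherwise dropped as ambiguous.  Instruments missing from the outcome
take the best panel proxy with r² > 0.8 (ties by distance, then id),
the outcome effect entering with the sign of the panel correlation;
the reference-panel frequency stands in for the proxy record's
unreported frequency.

**Estimators.** Wald ratio by/bx with first-order delta SE; IVW as
weighted regression through the origin with weights 1/se(by)², using a
multiplicative random-effects scale floored at 1 (never narrower than
fixed-effect); MR-Egger adds a free intercept after orienting all bx
positive, with the same floored scale; weighted median interpolates
the inverse-variance-weighted percentile function at 0.5; weighted
mode maximizes a Gaussian-kernel weighted density of the ratios with a
modified-Silverman bandwidth (factor configurable).  Bootstrap SEs for
median/mode are parametric and seeded.  Multivariable IVW regresses by
on the matrix of exposure effects without intercept (pseudo-inverse,
so a degenerate exposure column collapses to a zero coefficient
without poisoning the rest) and is restricted to metabolites with at
least three instruments.  All IVW/Egger/MVMR p-values use the normal
reference: combined with the floor-at-1 residual scale, a t reference
would make the tests doubly conservative (the Egger intercept's null
rejection rate drops to ~1%, outside any useful calibration band).

**Cochran's Q** uses first-order ratio weights (bx²/se(by)²; df k−1
for IVW, Rücker's residual Q′ with df k−2 for Egger).  Second-order
weights are deliberately omitted.

**MR-PRESSO.** The observed weighted residual sum of squares around
leave-one-out IVW predictions is ranked within parametric simulations
(default 1000) that redraw both exposure and outcome effects from
their sampling distributions under the leave-one-out fits; the rank
tail probability with the +1 correction is the global p (attainable
minimum 1/(n_sim+1)).  Per-SNP terms are ranked the same way and
flagged at α/k (Bonferroni).  Outlier removal is iterative — one worst
flagged SNP per pass, then refit — because with a gross outlier the
contaminated leave-one-out fits otherwise implicate every honest
instrument; the reported global p and per-SNP p-values are always
first-pass.  SNPs are processed in canonical id order so results are
independent of row order at a fixed seed.

**Steiger directionality.** Per SNP, r²_exposure and r²_outcome via
2β²f(1−f) on standardized effects (t²/(t²+n−2) as fallback or by
config), compared by a Fisher-z two-sample test; the aggregate verdict
is all-SNPs-pass, matching the filtering use of the test.

**Colocalization.** Wakefield log-ABF per SNP,
0.5·(log(1−r) + r·z²) with r = prior_sd²/(prior_sd² + se²) and
prior_sd = 0.15 (quantitative-trait convention).  Five hypotheses
H0–H4 are enumerated over single-causal-variant configurations with
priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ and normalized by log-sum-exp —
50-SNP regions with |z| = 8 overflow the linear scale.  Regions are
±500 kb around each instrument (reading "within 1 MB" as the total
span), intersected between studies, MAF > 0.01 in both.  A metabolite
is colocalized when any of its regions has PP4 strictly above 0.8.
Single-SNP regions have PP3 = 0 exactly; p12 = 0 forces PP4 = 0.

**Enrichment and validation.** One-tailed hypergeometric P(X ≥ k)
per annotated set with BH-FDR across sets; the universe is the union
of set members and tested metabolites.  Cohort validation is
complete-case OLS of age-at-event on the metabolite with optional BMI
covariates; z-scoring uses the sample SD (n−1); missing age-8 BMI
z-scores are imputed from age 7 first, then age 9; the early-menopause
exclusion removes subjects with the outcome below 45 years.

## The synthetic-data generator

Summary statistics are simulated directly on the effect scale — the
pipeline consumes only summary data, so no individual-level genotypes
are generated.  For a SNP with effect-allele frequency f in a study of
n individuals, β̂ is drawn around the LD-smeared true effect (R·b)
with sampling SD 1/sqrt(2f(1−f)n); noise at SNPs in LD is correlated
through the panel's Cholesky factor.  LD is block AR(1)
(r(i,j) = ρ^|i−j| within a block, 0 across; blocks > 500 kb apart),
giving exact closed-form r² for clumping and proxy tests.  A seeded
fraction of records is emitted with swapped alleles (10%) or strand
flips (5%), and ~5% of panel SNPs are palindromic, exercising
harmonization.  The full-study generator gives each of 50 metabolites
1–5 instrument blocks (the instrument-count distribution is a
parameter, defaulting to uniform on 1–5), makes the first 5 causal at
θ = 0.25 years/SD, uses discovery-scale sample sizes (exposure 24,925,
outcome 201,323; block ρ = 0.9 so proxies at r² = 0.81 exist), and
withholds 3% of outcome records to exercise proxy substitution.  The
outcome also carries 20 loci of its own (direct effects, no metabolite
association): without them every outcome GWAS hit would sit on a
metabolite locus and reverse MR would be confined to shared loci,
which no reproductive-timing GWAS resembles.  The cohort generator
draws age = intercept + β_m·metab + β_BMI·BMI + ε, places an exact
fraction of subjects below the 45-year cutoff and rejection-samples
the rest above it, so the early-exclusion count is deterministic;
points stay on the structural line, preserving noiseless-recovery
exactness.

What the generator does not emulate: genome-scale polygenicity,
MAF-dependent effect sizes, population stratification, sample overlap
between studies, binary/censored outcomes, and assay batch effects.
Passing tests therefore demonstrate the correctness and calibration of
the statistical machinery under the stated structural model, not
robustness to those real-data pathologies.

## Problem sizes and numerical choices

Benchmark experiments use 500 replicates for bias/coverage/size
checks, 1000 for the estimator-oracle sweep, 1000 PRESSO simulations,
and 100 end-to-end studies of 50 metabolites — sizes at which every
Monte-Carlo band in the tests has comfortable margin on one CPU.
Calibration experiments run IVW and PRESSO on 10-instrument sets and
the Egger intercept and Cochran Q on 20-instrument sets, where the
floored residual scale distorts least.  Posteriors, ABFs and the
PRESSO ranks are computed in log or rank space; the IVW/ratio-mean
identity holds to 1e−12 and posterior normalization to 1e−9.
Degenerate inputs (bx = 0, zero SD, n ≤ k+1, rank-deficient designs)
raise typed errors; sensitivity results that need more instruments
than available are explicit not-computable markers, mirroring blank
cells in a results table, not exceptions.

## Known limitations

Single-causal-variant colocalization only (no SuSiE-style multiple
variants); no correlated-instrument IVW; proxy search is within-panel
only; the Steiger formula assumes near-standardized outcome effects
(the t-based fallback is exact but conservative); the enrichment
universe choice (union of sets and tested metabolites) affects p-values
when annotation coverage is partial; MR-PRESSO's iterative removal is
greedy and can over-remove under extreme heterogeneity.
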