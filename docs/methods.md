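# Methods

This note documents the statistical models behind each stage, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical and design choices made
where more than one reasonable option existed.

## Data model and harmonization

Summary statistics are pandas DataFrames with canonical columns; the
natural-log p-value (`log_p`) is the authoritative copy, so
significance comparisons survive associations far beyond float
underflow (p < 1e-308). Validation drops rows with non-positive
standard errors, out-of-range p-values, chromosomes outside 1–22, or a
duplicated (chromosome, position, allele-set) key, and reports the
count. Pairs of tables are matched on (chromosome, position) rather
than identifier, tolerating rsID-version drift; the second table's
effect is sign-flipped when its effect allele equals the first table's
other allele, strand flips are resolved by complementing before
matching, and unresolvable pairs are dropped. A/T and C/G palindromic
variants are dropped by default because, without allele frequencies,
their strand cannot be oriented; the flag exists for panels where
frequencies settle it. Harmonization is involution-safe: applying it
to an already-consistent pair changes nothing.

Liability-scale conversion uses the threshold-model factor
K²(1−K)²/(P(1−P)φ(Φ⁻¹(1−K))²) with sample case proportion P and
population prevalence K. K must be supplied for real data; when it is
absent it defaults to P with a warning, because silently guessing a
population prevalence is worse than an explicit degraded default.

## Synthetic studies

The generator implements a bivariate infinitesimal polygenic model:
every variant is causal, per-variant standardized effect pairs are
bivariate normal with variances h²_t/M and correlation r_g. LD is
block-diagonal with AR(1) profile r^|j−k| within blocks — positive
definite by construction and yielding a tunable LD-score distribution.
Defaults (chosen once, for realism): mixed block sizes of 10/25/50/100
variants with r = 0.8, because a single block size with modest
correlation produces a nearly constant LD-score regressor, a design no
real genome has and on which LD score regression is close to
degenerate; 1 variant per kb by default, 1 per 3 kb in gene-layout
studies (about genome-wide common-variant density); 20,000 variants
and 20,000 samples per GWAS in the documented study conditions.

Per block with correlation matrix R, trait-t z-scores are drawn as
N(√N_t·R·β_t, R); the two traits' noise vectors are correlated
ρₙ = (n_overlap/√(N₁N₂))·pheno_corr, the standard summary-statistic
consequence of shared individuals. Effects are reported as
β = z/√N, se = 1/√N on the standardized scale. Case-control traits are
simulated on the liability scale: the requested heritability is
treated as liability-scale, deflated to the observed scale for
generation, and the tables carry case/control counts so the downstream
liability conversion can be exercised end to end.

What the generator does **not** emulate: realistic human LD maps
(haplotype blocks with long-range structure), allele-frequency–
dependent architecture, sparse causal configurations (except through
the targeted constructions used in the regional tests), ascertainment,
population stratification, or sex-specific effects. Tests passing on
these simulations therefore demonstrate correctness of the estimators
under their own model assumptions, not robustness to every real-data
pathology.

## LD score regression

LD scores are ℓⱼ = Σₖ r²ⱼₖ,adj within block (optionally windowed by
position), with the unbiased adjustment r²_adj = r² − (1−r²)/(n_ref−2)
and the self term included. Heritability is a weighted regression of
χ² on Nℓ/M with heteroscedasticity weights 1/(1 + N·ĥ²·ℓ/M)² refined
over two iterations from an unweighted start; two iterations because
the weights move negligibly afterwards. Genetic covariance regresses
z₁z₂ on √(N₁N₂)ℓ/M with the analogous product-variance weights; its
intercept is free by default (absorbing sample overlap) and can be
constrained to 0 for cohorts known to be disjoint. Variants with
χ² > max(80, 0.001·N) are excluded as outliers and logged — the usual
guard against single-locus leverage. Standard errors come from a
delete-one jackknife over 200 contiguous equal-count variant blocks
(contiguity respects LD; the count is configurable), computed in
O(blocks) from per-block sufficient statistics; r_g is jackknifed as
the full ratio gencov/√(h₁²h₂²), with replicates whose heritability
slope goes non-positive dropped from the pseudovalue set. A
non-positive heritability point estimate flags the r_g result as
undefined rather than reporting a complex number.

## Regional pleiotropy posteriors

Per-variant evidence is the Wakefield approximate Bayes factor
√(1−r)·exp(z²r/2), r = W/(V+W), with prior effect variance W = 0.01
(sd 0.1 on the standardized scale) — a conventional weakly-informative
choice for complex-trait effect sizes. All Bayes-factor arithmetic is
in natural-log space and exact for |z| of 40 and beyond.

Regional Bayes factors average per-variant ABFs, encoding one causal
variant per trait per segment: RBF1/RBF2 are single-trait means; RBF3
averages the joint shared-variant evidence; RBF4 averages
abf1ᵢ·abf2ⱼ over ordered pairs i ≠ j. The shared-variant model uses a
bivariate normal Bayes factor in which the z-pair has null correlation
`null_cor` (wire it from the LDSC cross-trait intercept for
overlapping cohorts; 0 for disjoint ones); cross-variant terms need no
adjustment because each z is marginally standard normal under its own
null. The pairwise sum is computed either by the stable log-difference
identity ΣaΣb − Σab or, when the diagonal dominates, by a masked
log-sum-exp over the outer product.

Model priors: estimated by empirical-Bayes EM across segments
(maximizing the marginal likelihood of the five-model mixture), with a
fixed fallback (0.9 null, 0.025 per alternative) when fewer than 10
segments are available or the optimization degenerates. PPA3 > 0.5
calls a segment pleiotropic; the call table carries the lead variant
(highest joint ABF) and the direction of its effect allele on each
trait.

## Meta-analysis and novel loci

Fixed-effect IVW: β_meta = Σwβ/Σw with w = 1/se², so combined
precision is the sum of per-trait precisions; heterogeneity is
Cochran's Q on 1 df. The shared-candidate filter keeps variants
genome-wide significant in the meta-analysis (p < 5×10⁻⁸) but only
nominally significant in each trait (strictly between 5×10⁻⁸ and
0.05); it is applied before clumping. Clumping is greedy by ascending
p (ties broken by position): the best remaining variant leads, members
join at r² ≥ 0.1, and members at r² ≥ 0.6 define the locus span —
PLINK/FUMA-style, deterministic. Variants absent from the LD reference
are treated as unlinked and their count surfaced prominently, because
unlinked-by-ignorance is the anti-conservative direction for novelty
claims. The six-step novelty procedure masks the candidate leads'
p-values to the sentinel 1.0 (any non-significant value works — the
sentinel must only never outrank a true GWS variant, which also makes
the masking order-independent), pools them with both traits' GWS
variants, re-clumps, and keeps the masked leads that re-emerge as
index variants. Nearest-gene annotation minimizes the distance to the
[TSS, TES] interval, ties broken by smaller span then identifier.

## Mendelian randomisation

Instruments are LD-independent (r² < 0.1, reusing the clumping engine)
exposure-significant variants present in both GWAS; if fewer than 3
survive at 5×10⁻⁸ the threshold falls back to 1×10⁻⁵ (flagged in the
result). Fewer than 2 instruments refuses estimation. The minimum of 3
for triggering fallback is a configurable default — enough for the
median and Egger estimators to run.

IVW regresses outcome on exposure effects through the origin with
weights 1/se_zy², inflating the standard error by √(Q/(k−1)) when
over-dispersed (multiplicative random effects, floored at 1). The
weighted median uses inverse-variance ratio weights with a parametric
bootstrap (1,000 draws, seeded) for its standard error. MR-Egger
orients instruments to non-negative exposure effects, fits a free
intercept by weighted least squares, applies the same multiplicative
over-dispersion floor, and tests slope and intercept against a t
distribution with k−2 df; the intercept is the directional-pleiotropy
diagnostic. The PRESSO-style global test sums squared leave-one-out
outcome residuals and compares them to a null distribution built by
redrawing outcome effects from the fitted model with their stated
standard errors; the global p is rank-based with floor 1/(n_sim+1) and
is displayed as an inequality at the floor; per-instrument outlier
p-values are Bonferroni-screened (unfloored, so detection does not
depend on n_sim exceeding 20·k) and the corrected estimate is IVW on
the survivors. The HEIDI-filtered estimator takes the median Wald
ratio of the low-variance half of the instruments as reference,
tests each instrument's deviation with a delta-method standard error
that includes exposure-side error, removes those with p < 0.01, and
combines the survivors by exposure-error-aware IVW — an intentionally
transparent approximation in the spirit of GSMR, not a re-derivation
of it. Both trait orderings run with independently selected
instruments for the bidirectional analysis.

## Gene-based tests and overlap

SNPs map to genes within 15 kb of the TSS/TES span (closed bounds); a
variant may serve several genes, and empty genes are dropped with a
count. The effective number of independent tests is
Mₑ = M − Σ_{λᵢ>1}(λᵢ−1), clamped to [1, M]. GATES evaluates
min over j of Mₑ(all)·p₍ⱼ₎/Mₑ(top j) with Mₑ computed on the
*p-value* correlation matrix — genotype r mapped through the
sixth-degree polynomial (in |r|, since two-sided p-values are
sign-blind, with the |r| = 1 limit pinned to exactly 1 so perfect LD
collapses to the best SNP p-value). Using the genotype matrix directly
is measurably anticonservative (8–9% of null genes below p = 0.05 in
our AR(1) simulations); with the polynomial the 5% tail is calibrated.
Even then, GATES is a Simes-type statistic: under positive dependence
its null distribution is slightly conservative in the bulk (mean null
p ≈ 0.55 under strong AR(1) LD) and exactly uniform only for
independent SNPs. The calibration test therefore checks exact
uniformity where it is a theorem (independent SNPs) and tail
calibration under LD.

Effective gene counts apply the same eigenvalue rule per chromosome to
the genotype LD matrix of the genes' best SNPs — neighbouring genes
correlate through LD of their top variants — and sum across
chromosomes; genes whose best variant is missing from the reference
count as independent, logged. Overlap testing at thresholds 0.1, 0.05
and 0.01: expected proportion = effective target genes below the
threshold over total effective target genes; observed = effective
overlapping genes over effective discovery genes below the threshold;
one-sided upper-tail binomial with effective counts rounded to
integers (the test is defined on integer counts) and the tail computed
in log space so p-values far below float underflow keep their
magnitude. Shared genes combine the two trait p-values by Fisher's
method (χ² with 4 df, closed form e^(−X/2)(1+X/2)) among genes with
both p < 0.05, significant below 0.05 divided by the total effective
gene count.

## Pipeline

Stages run in a fixed order with explicit dependencies (the regional
stage's null correlation can be wired from the genetic-correlation
stage's intercept); each stage writes one TSV and the report echoes
stage outputs without recomputation, including an explicit
"0 novel loci" line rather than an omission. Everything is a pure
function of configuration plus seed; rerunning reproduces outputs byte
for byte. Logging is line-oriented with in/out/dropped counts so every
filter is auditable from the log alone.

## Problem sizes

The documented study conditions — and the sizes the acceptance script
and test suite run — are M = 20,000 variants, N = 20,000 samples,
200 jackknife blocks, 50 replicates for recovery studies (20–50 where
a study is nested inside a larger one), 2,000 genes for calibration,
and 200 PRESSO null simulations per run. These keep a full run on one
CPU in the minutes range while leaving Monte-Carlo error well inside
the ±2·se acceptance bands.

## Known limitations

Single-ancestry, autosomal, block-diagonal LD only; no partitioned
heritability; no Han–Eskin random-effects tail (heterogeneity is
Cochran's Q); at most one causal variant per trait per segment in the
regional model; the HEIDI/GSMR stage is a documented approximation;
binary-trait simulation does not model case over-sampling beyond the
liability-scale variance correction; and effective gene counts are a
principled stand-in for the external "effective number of tests"
calculators, so absolute effective counts from real panels are not
comparable across tools even though the downstream binomial arithmetic
is exact.
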