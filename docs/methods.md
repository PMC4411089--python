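# Methods

This note documents the models implemented in `celiacrisk`, the parameters
that matter, the numerical choices made where the design was genuinely
open, and what the synthetic cohorts do and do not establish about real
data.

## Cohort model

One row per child: case/control status (CD diagnosed or ruled out by
duodenal histology), sex, age (years), H. pylori infection (yes/no/unknown),
anti-tTG IgA (units), Marsh-Oberhuber grade (none, 1, 2, 3a, 3b, 3c), HLA-DQ
allele-group calls, and unordered genotypes at the seven panel SNPs.
Genotypes are unphased throughout: phase is inferred, never an input. DQB1
alleles other than *02/*0302 are collapsed to the symbol X, because the risk
classification depends only on the *02 dose and *0302 presence. Missing
values are the single token `NA`; every statistical routine uses complete
cases for the fields it needs and reports the n actually used. Minor-allele
designations are fixed by the panel definition, not re-derived per sample,
so a sample in which a designated minor allele drifts above 50% still
reports that allele's frequency.

## HLA-DQ classification and post-test risk

Classification applies eight first-match rules on (*05 presence, *03
presence, *02 dose, *0302 presence), from DQ2.5 homozygous (rule 1) down to
HLA-DQ negative (fallback). The rules are total: a truth-table test covers
every legal input. The three clinical tiers are fixed mappings — negative ↔
the negative category, high ↔ DQ2.5 homozygous, intermediate ↔ the six
others.

Post-test risk anchors a category's within-row case/control frequencies to a
population prevalence of 1:P (default P = 184, the reported prevalence among
children of the study region; configurable):

    N = (f_ctrl / f_case) · P

Two rounding modes exist because the published arithmetic is reproducible
only with intermediate rounding:

* `paper` (default): round f_ctrl half-up to two decimals, set
  f_case = 1 − f_ctrl (the published tables print complement-rounded
  frequency pairs), then round N to the nearest integer with exact halves
  rounded down. This reproduces seven of the eight published rows
  (18216, 450, 429, 313, 103, 75, 52). The eighth (DQ2.5 homozygous:
  7.67 → published as 7) is inconsistent with any single rounding rule;
  this implementation yields 8.
* `exact`: unrounded frequencies, N reported as a real number. Use this for
  honest estimates; `paper` mode exists for comparability. Both are logged
  by the pipeline.

In exact mode N/P equals the control:case frequency ratio, i.e. the
inverse of the category's case-control odds — with the prevalence treated
as a proportion rather than odds, so N approximates (not equals) the Bayes
posterior; at 1:184 the distinction is negligible.

## Haplotype EM and diplotype posteriors

Haplotype frequencies over the four promoter SNPs (-1031, -857, -376, -308)
are maximum-likelihood estimates under Hardy-Weinberg random mating,
computed by EM on unphased genotypes. A subject heterozygous at k panel loci
is compatible with 2^(k−1) unordered haplotype pairs (1 if k = 0); the
E-step weights pair (h1, h2) by 2^[h1≠h2]·p_h1·p_h2 normalized per subject,
and the M-step sets each frequency to its expected allele share over 2n. The
observed-data log-likelihood is asserted non-decreasing at every iteration.

Numerical choices: convergence at a log-likelihood increase below 1e-8, at
most 1000 iterations (both configurable); one uniform start over the
compatible haplotypes plus two random Dirichlet restarts, best
log-likelihood wins — double-heterozygote-rich data has genuine local
optima, and a fully double-heterozygous two-locus sample is a known
unidentifiable case (the LD routine detects the mirrored solution and flags
the result phase-ambiguous). Subjects missing any panel genotype are
excluded (complete-case); a tolerant mode that sums over missing loci
exists but is off by default. Haplotypes below a reporting floor of 1e-5
are pruned from reports but kept in the model.

Diplotype calls use the maximum-posterior pair (ties broken by the
lexicographically smallest pair string, with a logged warning); a threshold
policy (default 0.8) returns "unassigned" for ambiguous subjects instead.
Downstream grouping uses MAP calls, matching the one-combination-per-subject
convention of the source analysis; posterior-weighted propagation is
available through the fractional-weight logistic fit for sensitivity
analyses. Haplotype codes H1–H6 map CCGG, TTGG, TCGG, CCAG, TCGA, CCGA in
that order; the reference haplotype for odds ratios is chosen as the most
frequent in the pooled sample rather than hard-coded.

## Population genetics

The exact Hardy-Weinberg test conditions on the observed allele counts and
enumerates every compatible heterozygote count (Levene/Haldane conditional
distribution), summing the probabilities of configurations no more likely
than the observed one. Enumeration is exact and fast at cohort scale, which
is why it is preferred over a Markov-chain approximation; a 1-df chi-square
alternative is reported alongside. Pairwise LD between unphased loci goes
through the two-locus EM: D = p_AB − p_A·p_B for the minor/minor haplotype,
D′ = D/D_max with the usual sign-dependent bound, r² = D²/(p_A p_a p_B p_b).

## Association models

Crude 2×2 odds ratios are ad/bc with Woolf 95% intervals; the Haldane 0.5
correction applies to zero cells (for crude tables only — model-based fits
treat separation as an error instead). Logistic regression is fitted by
iteratively reweighted least squares with optional fractional row weights;
standard errors come from the inverse observed information. A constant
outcome or diverging coefficients (|β| > 30) raise a separation error
rather than returning estimates. A model with a single binary predictor
reproduces the crude OR and Woolf interval analytically, which is tested to
1e-6 against the 2×2 arithmetic and against statsmodels as an independent
oracle.

SNP models: dominant = carriage of ≥1 designated minor allele, recessive =
minor-allele homozygosity; the adjusted profile is {age, sex, H. pylori}.
Haplotype odds ratios approximate a retrospective profile-likelihood fit by
prospective logistic regression on posterior expected carriage: each
subject contributes their posterior probability of carrying ≥1 copy of each
non-reference haplotype, and one joint fit makes the baseline "carries the
reference haplotype only". Under case-control sampling the carriage log-OR
is consistently estimated with the intercept absorbing the sampling
fractions, so estimates are expected to track, not exactly equal, a true
retrospective likelihood fit.

Bonferroni adjustment is min(1, m·p); the joint-model default m = 10
mirrors the source table's visible ×10 adjustment, whose basis is not
stated — it is configurable. DeLong's paired test compares ROC areas of two
models fitted on the same subjects via placement-value variances; the
implementation was cross-checked against R's pROC and a frozen oracle value
is kept in the tests.

## Combination groups and the joint model

Observed diplotypes are banded by their CD fraction into groups A–E with
lower-closed intervals [0, .10), [.10, .40), [.40, .60), [.60, .80),
[.80, 1]; the source's "60–80%"-style wording does not fix the closure, so
lower-closed was chosen and the cut points are configurable. Learning
groups from the analysis cohort is circular for inference; a frozen
combination→group map can be supplied to apply reference definitions to new
subjects, which is the intended reuse mode.

The joint model regresses status on tier indicators (reference: negative)
and group indicators (reference: A) plus covariates. Predictive margins per
(tier, group) cell are average predicted probabilities over the cohort's
covariate distribution — chosen over prediction-at-covariate-means because
it answers the population question directly — with delta-method standard
errors; cells never observed in the data are still computable and flagged
extrapolated. The atrophy trend scores groups A..E as 0..4 and regresses
total atrophy on the score within an HLA stratum; "total atrophy" defaults
to Marsh-Oberhuber 3c, configurable to {3b,3c} or {3a,3b,3c}.

A reference cell populated by one status only makes the joint-model MLE
infinite. This is a property of the data (with the cohort's own ~1/244
HLA-negative case frequency, a simulated cohort of the same size has no
negative-tier case about 37% of the time). The pipeline therefore records
the degeneracy in the joint-model/margins/ROC report sections and
continues, rather than aborting the run; all other stage failures abort
with the stage name.

## Synthetic cohorts

The generator's defaults reproduce the studied cohort's structure: sizes
244/267; the eight-category HLA distribution per status; covariate
marginals (sex 68%/55% female, age 7±4 / 10±4 years clipped to 0.5–23,
H. pylori 4.9%/18.7%, tTG 153±79 / 5±9 units); the Marsh-grade distribution;
and per-status TNFA haplotype frequencies. The published record fixes only
the per-status single-SNP minor allele frequencies, which constrain f(H2),
f(H4), f(H5)+f(H6) and f(H1)+f(H4)+f(H6); the H5/H6 split was set once
(H6 = 0.03 in cases, 0.01 in controls) and not revisited. The implied
defaults make TCGG (H3) the most frequent haplotype, CCGG/TTGG
control-associated and CCAG/TCGA/CCGA CD-associated, consistent with the
qualitative published description.

Retrospective mode draws cases and controls independently from their
per-status distributions (the study design; HLA category and TNFA diplotype
are sampled independently given status). Prospective mode generates a
control-like latent population, assigns status by a logistic model over a
fixed term vocabulary (tier indicators, a group score from a frozen
combination→group map, covariates, dominant SNP carriage) and subsamples
the requested cohort — only this mode has true coefficients, so
parameter-recovery checks use it. One integer seed drives a single
`numpy.random.default_rng` stream with a documented per-subject draw order,
making cohorts byte-reproducible.

What the simulator does **not** emulate: linkage between the TNFA promoter
and the HLA region beyond status-mediated correlation (the real loci sit
together on 6p21.3), genotyping error, family structure, tTG/TNF-α biology
beyond independent noise, and any HLA×haplotype dependence within a status
group (an optional joint table could encode it, but no published values pin
it down). Passing recovery tests therefore show the estimators are correct
under Hardy-Weinberg random mating and the stated sampling designs — not
that the defaults capture every dependency of the real cohort.

## Problem sizes used in the checks

Oracle-equivalence checks run at enumeration-tractable sizes (EM vs an
exhaustive 0.005-step simplex grid at n ≤ 12 and ≤ 3 loci; exact HWE vs
big-integer enumeration at n ≤ 50). Calibration and recovery use one fixed
seed each: haplotype-frequency recovery at n = 5000 (tolerance 0.02),
logistic coefficient recovery on a latent population of n = 20000 (within
3 SE), HWE type-I error over 500 null draws at n = 10000 (≤ 8% at nominal
5%). These sizes give stable Monte-Carlo behaviour while keeping the whole
suite fast on a single CPU.

## Known limitations

* Covariate-adjusted odds ratios from the source cohort cannot be
  reproduced without its subject-level data; only statistics derivable from
  printed counts are checked exactly.
* The haplotype-OR routine is a prospective approximation of the
  retrospective profile likelihood (above); intercepts are not
  interpretable as baseline risks in retrospective samples.
* The exact HWE test is conditional on allele counts; its p-values are
  discrete and conservative at small n.
* No multi-allelic SNPs, imputation, haplotype-block detection, or full
  HLA typing nomenclature beyond the allele groups the classification
  needs; panels beyond four loci are untested for the EM.
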