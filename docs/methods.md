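# Methods

`pedscan` implements a three-phase strategy for mapping quantitative-trait
loci in extended pedigrees: (1) construct a censoring-corrected summary
phenotype from longitudinal blood-pressure exams, (2) scan randomly sampled
common markers with two-point variance-components linkage and keep regions
whose LOD exceeds a threshold, (3) test every variant inside the kept
regions with family-based association (measured genotype and QTDT). This
note records the models, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Phase 1 — censored phenotype adjustment

Antihypertensive treatment makes an observed systolic blood pressure (SBP)
a *lower bound* on the untreated value. Each exam is modelled separately as

    Y_ij = x_ij' beta + u_j + eps_ij,   eps ~ N(0, sigma^2),  u_j ~ N(0, tau^2)

with fixed effects (intercept, sex, exam-specific age, smoking; all linear,
no interactions) and a random intercept per pedigree *j*. An unmedicated
record contributes the normal density; a medicated record contributes the
survival probability P(Y > y_obs), i.e. noninformative right-censoring at
the observed value. The random intercept is integrated out with 20-point
Gauss–Hermite quadrature; with the integrand being a one-dimensional,
well-scaled Gaussian mixture this order is ample, and an adaptive recentring
step was not needed (checked against a converged `statsmodels` MixedLM fit
in the uncensored limit, agreement ~1e-5 relative). Optimization is
L-BFGS-B over (beta, sigma, tau) with tau bounded at 0; `tau` estimates
below 1e-4·sigma are flagged as boundary fits. Three perturbed restarts
guard against local optima.

After fitting, each pedigree's random intercept is set to its posterior
mode given the MLEs. Fitted values are Yhat = x'beta + u. For medicated
records the underlying value is replaced by the truncated-normal mean

    Y* = E[Y | Y > y_obs] = mu + sigma · phi(a)/(1 − Phi(a)),  a = (y_obs − mu)/sigma

computed in log space (stable arbitrarily far into the tail); `mu` includes
the pedigree random effect. The adjusted phenotype is R = mean over exams
1–3 of (Y − Yhat) or (Y* − Yhat); individuals with a subset of those exams
use the mean over the exams they have, and exam 4 is never used. R carries
no covariate signal, so later phases fit intercept-only mean models.

## Phase 2 — two-point variance-components linkage

For pedigree members with phenotype R the covariance of one pedigree is

    Sigma = Pi·sigma2_qtl + 2Phi·sigma2_a + I·sigma2_e

with Phi the kinship matrix (exact tabular recursion, loop-safe, founders
unrelated and non-inbred) and Pi the marker-specific IBD-sharing matrix.
Both the polygenic null (sigma2_qtl ≡ 0) and the marker model are fitted by
full maximum likelihood — not REML — because the LOD is a likelihood ratio:
LOD = (l_alt − l_null)/ln 10. The mean is profiled out by GLS inside every
variance evaluation, variances are optimized by bound-constrained
quasi-Newton (L-BFGS-B, ftol 1e-12) on data rescaled to unit variance, and
blocks of equal size are solved with batched linear algebra. The
alternative nests the null, so l_alt is floored at l_null; an estimate of
sigma2_qtl at the 0 boundary yields LOD = 0 exactly, and a marker whose Pi
equals 2Phi in every pedigree is flagged confounded with LOD = 0 (the QTL
variance is then unidentifiable against the polygenic one). Under the null
the LOD·2ln10 statistic follows the boundary mixture ½χ²₀ + ½χ²₁, giving
P(LOD > 1.2) ≈ 0.0094; the acceptance suite verifies this empirically.

### Single-marker IBD

Pi is the conditional expectation of realized allele sharing given the
observed genotypes at one marker (strictly two-point; no map). The exact
engine enumerates inheritance vectors (one bit per meiosis) jointly with
founder-allele states, weighting by Hardy–Weinberg founder priors and fair
Mendelian transmissions, and conditioning on observed genotypes; missing
genotypes are marginalized. A founder-phase symmetry (swapping a founder's
two exchangeable alleles while flipping the meioses that draw from that
founder) lets the enumeration pin one meiosis per transmitting founder,
shrinking the inheritance-vector space by 2^founders. The exact path is
capped at ~2^24 joint (vector × founder-state) configurations — a total-work
cap chosen so a 12-member, 4-founder family evaluates in tens of
milliseconds; larger problems route to Monte Carlo. The Monte-Carlo
estimator samples inheritance vectors uniformly and either weights each by
its exact genotype likelihood with founder alleles summed out analytically
(importance route, used when the founder state space is ≤ 4096) or draws
founder alleles from the prior and rejects inconsistent configurations
(rejection route for many-founder pedigrees). Both return elementwise
standard errors. Mendelian-inconsistent genotypes raise an error naming
the family and marker; the pipeline can instead substitute the prior 2Phi
with a logged warning (`mendelian_policy: prior`).

Marker sampling filters at MAF ≥ 0.05 (inclusive) and draws uniformly
without replacement under a seed; repeated rounds exclude earlier picks.
Region selection keeps markers with LOD ≥ threshold (default 1.2; the
comparison is inclusive so values printed at the threshold's precision are
kept) and merges qualifying markers within 10 Mb — a tunable matching the
several-to-tens-of-Mb widths typical of two-point linkage regions.

## Phase 3 — family-based association

Each variant's dosage is decomposed as g = b + w: b is the parental-mean
dosage when both parents are genotyped, else the mean of the genotyped full
sibship (self included), else the individual's own dosage (founders; then
w = 0 and the individual contributes no within-family information). The
mixed model is

    R = mu + beta_b·b + beta_w·w + polygenic(2Phi·sigma2_a) [+ Pi·sigma2_qtl] + e

The measured-genotype (MG) test constrains beta_b = beta_w (a single
allelic slope) and tests beta = 0; QTDT leaves both free and tests
beta_w = 0. Both are 1-df likelihood-ratio tests — fixed-effect contrasts,
so no boundary correction applies. Because b soaks up between-family
frequency differences, QTDT is robust to population stratification where
MG inflates; in a homogeneous population MG is the more powerful test. The
optional linkage variance component (the variant's own Pi) enters both the
null and alternative of each test, absorbing locus-specific familial
correlation; when a true QTL is linked to the tested variant this lowers
the MG type-I error. Variants are labelled rare (MAF < 1%), low-frequency
(1–5%, half-open) or common (≥ 5%), and results are reported ranked with
no multiple-testing correction by default (the candidate-region setting
leaves the appropriate criterion to the analyst). Q-Q diagnostics report
the genomic inflation factor lambda = median(χ²)/0.4549.

## Synthetic data

The generator emulates the study design the pipeline expects: multiple
multigenerational families (default template: a founding couple, a sibship
of four of whom two marry in spouses, final sibships of two — exactly 12
members, three generations; 20 families by default), up to 4 exams with
sex, exam-specific age (generation-based, 5-year spacing) and smoking
(rate 0.2), a polygenic background sampled from MVN(0, 2Phi·sigma2_a), an
optional biallelic QTL whose allelic effect is derived from its variance
fraction, a pedigree-level intercept (tau = 5 mmHg), exam noise, and total
non-covariate s.d. 15 mmHg with baseline 120 mmHg — values in the range
reported for adult SBP cohorts. Covariate effects default to −4 mmHg
(female), +0.4 mmHg/year, +3 mmHg (smoking). Markers are simulated
unlinked from Hardy–Weinberg founder alleles with recorded descent, so
realized IBD is available as ground truth; a linked-pair helper (shared
inheritance vectors, independent allele values, configurable recombination
fraction) exists solely to create linked-but-not-associated scenarios.
Stratification assigns whole families to strata differing in allele
frequency and trait mean.

Medication censoring defaults to a *random treatment-level* mechanism:
each individual carries a level C ~ N(q, censor_sd²) with q the
`censor_quantile` (default 0.7) quantile of the underlying SBP
distribution; a record is medicated iff its underlying value exceeds C and
the observation is C itself. This is textbook noninformative
right-censoring — exactly what phase 1 assumes — while still concentrating
medication among high-SBP individuals (~30% of records at the defaults)
and keeping every treated observation below its underlying value. An
alternative `subtractive` mechanism (observed = underlying − lognormal
drop) is available; it makes the observed value informative about the
underlying one, measurably biasing the censored fit, and is retained
precisely to let users study that misspecification.

What passing tests on these data do *not* show: robustness to linkage
disequilibrium (markers are unlinked), to imputation error (genotypes are
taken as given), to non-normal trait distributions, to household/shared
environment covariance, or to informative censoring; real pedigrees are
also far larger and messier than the 12-member template.

## Problem sizes and numerical notes

The test and acceptance suites run at desk scale: 20–50 families of 12
(240–600 phenotyped individuals), hundreds to 2,000 markers, and 100–500
simulation replicates — sizes at which every Monte-Carlo band in the suite
is computed from the replicates themselves (3 s.e.). Degenerate inputs are
handled explicitly: unrelated-only samples pin sigma2_a to 0 (the
polygenic component is unidentifiable against the residual), constant
genotypes and w ≡ 0 markers return non-informative flags rather than
estimates, all-missing markers raise, and empty region selections are
empty results, not errors. All randomness flows from user seeds; the
pipeline derives per-phase seeds from the single config seed by keyed
`SeedSequence` spawning, making full reruns byte-identical.

A caveat of the two-stage design itself: the phase-1 pedigree random
intercept cannot distinguish a shared-family environment from the
between-family part of the polygenic signal, so subtracting its posterior
mode removes some genetic variance from R and the downstream heritability
estimate leans on within-family contrasts. With many or large families
this costs little; with few small families the polygenic estimate is
noticeably variable and can hit the zero boundary on unlucky samples.

## Known limitations

Two-point only (no multipoint IBD); kinship and IBD are autosomal (no X
chromosome); the exact IBD engine is exponential in pedigree size and
hands large families to Monte Carlo; the censored model assumes
noninformative censoring and linear age; no kurtosis-robust LOD
adjustment is applied; region-level significance is left to the user.
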