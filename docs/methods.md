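# Methods

This note records the models implemented in `tissuemr`, the defaults and why
they were chosen, the numerical decisions that matter, and what the synthetic
data can and cannot establish about behavior on real cohorts.

## Synthetic cohorts

The generator (`tissuemr.simulate`) exists because the individual-level data
this kind of analysis runs on (birth-cohort phenotypes, tissue eQTL panels,
methylation arrays) is access-controlled.  It produces data with exactly the
statistical structure the downstream stages assume, under five mechanistic
scenarios: single-gene mediation, multi-gene mediation, co-regulation with a
single mediator, two distinct causal variants in LD, and horizontal
pleiotropy.

**Genotypes.**  Each haplotype's allele indicators come from thresholding a
latent first-order autoregressive Gaussian process at the allele-frequency
quantile `Φ⁻¹(MAF)`; dosages sum two independent haplotypes.  This model was
chosen because the LD between any variant pair has a closed form: the
indicator correlation is `(Φ₂(t₁,t₂;ρ) − q₁q₂)/√(q₁(1−q₁)q₂(1−q₂))` with
`Φ₂` the bivariate normal CDF, and the dosage correlation equals the
indicator correlation.  For the LD-confounding scenario the latent
correlation between the two designated causal variants is obtained by
numerically inverting this closed form (Brent's method on the tetrachoric
relation), which hits the target r² exactly in expectation rather than
approximately by rejection; the simulation tolerance asserted in tests is
±0.05 on the empirical r².

**Molecular traits.**  Expression of gene g is `β_g·G + ε` with unit
residual SD by default, so simulated expression is on an approximately
standardized scale and eQTL effect sizes read as SDs per allele.
Methylation effects act on the logit scale and are squashed through the
logistic function, keeping values strictly inside (0, 1) as array
beta-values are.  The trait sums mediated expression effects, any direct
(pleiotropic) variant effect, age and sex effects, and Gaussian noise; a
per-trait switch exponentiates the trait for log-normal phenotypes, since
which phenotypes need log transformation is a property of the data, not the
method.

**Defaults as study conditions.**  Cohorts of n = 20,000 with MAF 0.3,
AR(1) LD 0.4, allelic effect 0.4 on expression and mediation 0.3 (hence an
expected variant→trait slope of 0.12) are the conditions under which
calibration and recovery are asserted.  Age is uniform on 7–10.5 years and
sex Bernoulli(0.5), matching a childhood-cohort design; covariate effects
default to (0.01, 0.2).  These were fixed once, before any result was
inspected, and are not tuning knobs.

**Randomness.**  A single integer seed feeds `numpy`'s `SeedSequence`, which
is split into independent child streams for genotypes, covariates,
expression, methylation and trait noise.  Identical specs produce
bit-identical cohorts.

**What passing tests do not show.**  The generator has no realistic
haplotype structure (no recombination hotspots, no allele-frequency
spectrum), no population stratification or relatedness, no trans effects,
no missingness mechanism, and its LD decays geometrically.  Calibration and
recovery results therefore validate the estimators under their own
assumptions; they do not quantify robustness to confounding structures the
generator does not produce.

## Association scan

Per-variant OLS of phenotype on additive dosage with age and sex covariates.
When no values are missing, all variants share one covariate projection, so
the scan residualizes the phenotype and dosages on [1, age, sex] and runs
the per-variant simple regressions on residuals (Frisch–Waugh–Lovell);
this is algebraically identical to per-variant multiple regression and is
verified against it in tests.  Variants with missing dosages fall back to an
explicit per-variant fit with listwise deletion.  p-values use the t
distribution with residual degrees of freedom, not the normal approximation.
Extreme statistics whose survival function underflows are floored at the
smallest positive double so p stays in (0, 1].

Phenotype outliers are flagged in a single pass: mean and SD computed once
on the full non-missing sample (after log transform where flagged), values
beyond ±4 SD set missing.  Iterating removal was considered and rejected:
single-pass is idempotent and reproducible, and at the 4 SD cut re-passes
rarely change anything.  A constant vector (SD = 0) is returned untouched
rather than fully removed.  The variant filters are inclusive at info = 0.8
and strict at MAF = 0.01; MAF is rounded to 12 decimals before the strict
comparison so that frequencies like 0.99 land exactly on the boundary
instead of a float hair above it.  Records lacking an info score pass the
filter but are counted, since summary sources often omit it.

## Fine-mapping

Exhaustive enumeration of causal configurations up to `k_max = 5` variants
(the conventional maximum), replacing stochastic search deliberately: at
regional scale the full enumeration is feasible and is its own exactness
guarantee.  The per-configuration Bayes factor uses the matrix determinant
lemma and Woodbury identity to reduce the m-dimensional density ratio to
|S|-dimensional quantities; besides speed this avoids the catastrophic
cancellation that the naive full-dimension density ratio suffers when R is
ill-conditioned (the two forms agree to ~1e-13 on well-posed regions, which
is how the test oracle checks them).

Priors: independent Gaussian effects with `prior_sd = 0.05` on the
standardized allelic scale (the conventional fine-mapping default), and
independent per-variant inclusion with probability 1/m truncated at
`k_max` (a uniform-on-k alternative is available).  R gets a ridge of 1e-6
on the diagonal before factorization.  Regions whose configuration count
would exceed 2×10⁶ have `k_max` reduced with a warning.  LD computed from a
reference panel rather than individual-level dosages is accepted but
flagged, because panel LD inflates false-positive fine-mapping claims.

## Mendelian randomization

Single-instrument Wald ratio with the first-order delta SE
`|se_out/β_exp|`, the convention for single-variant MR; a flag adds the
second-order exposure-variance term.  The Wald p-value is normal, not t:
in the two-sample summary setting the outcome estimate's degrees of freedom
are large and unknown to the consumer.  The cis window is inclusive at
exactly 1 Mb and the instrument threshold strict at p < 10⁻⁴.

Harmonization tries direct match, allele swap (flipping β and EAF), strand
complement, and complement-plus-swap, in that order.  Palindromic pairs
(A/T, C/G) are resolved by allele frequency only when both minor frequencies
are below 0.42 — a conventional cutoff beyond which frequency no longer
identifies strand — and dropped otherwise.

The Steiger test is implemented in its two-independent-samples form: each
study's variant-trait correlation is reconstructed from the regression t
statistic (`r = t/√(t² + n − 2)`), magnitudes are Fisher-z transformed and
compared with SE `√(1/(n₁−3) + 1/(n₂−3))`.  `direction_ok` is simply
`|r_exposure| > |r_outcome|`; the p-value quantifies the evidence that the
difference is real.

Deliberately out of scope: multi-instrument estimators (IVW, Egger, weighted
median).  The pipeline is single-instrument throughout, which means
horizontal pleiotropy (scenario 5) cannot be tested against mediation — the
scenario-5 generator exists precisely to demonstrate this limitation: the
Wald ratio there converges to pleiotropy/β_eQTL even though mediation is
zero, and a test asserts that analytic bias.

## Multiple-trait colocalization

For traits {G, E, M} all 15 configurations (set partitions of all subsets,
null included) are enumerated with canonical dot-separated labels ("GE.M" =
G and E share a variant, M has its own; the empty configuration is labelled
"null").  Evidence for a configuration with groups D₁…D_g sums, over
assignments of *distinct* variants to groups, the product of per-group
terms `p_{|D_h|}·Π_{t∈D_h} ABF_t(j_h)` — the two-trait "different variants"
convention extended to three traits.  Per-variant priors default to
1e-4 / 1e-6 / 1e-7 for variants causal for one/two/three traits, the values
recommended by the method's authors; the ABF prior SD defaults to 0.15 per
trait (the continuous-trait convention), configurable per trait.

The distinct-variant sums are evaluated by Möbius inclusion–exclusion over
partitions of the group indices.  Doing that directly in log space is
numerically catastrophic: when one variant dominates two traits, the
alternating sum cancels to the floating-point floor and produces NaNs.  The
implementation therefore normalizes each group's weights to probabilities
(factoring out the log scale), runs the alternating sum in linear space
with compensated summation, and restores the scale afterwards.  A sum that
still cancels below the float floor corresponds to evidence hundreds of log
units under the dominant configurations and is reported as −inf (PPA 0);
configurations affected this way never carry non-negligible posterior mass,
which is why the brute-force oracle agreement at 1e-10 holds.

Regions enter colocalization only with ≥ 50 variants at MAF ≥ 0.05
(inclusive) common to all three datasets after per-dataset filtering; thinner
regions return a structured "insufficient SNPs" result rather than raising.
Both methylation-sharing summaries are exposed: the all-share PPA (the
default for the methylation decision) and arbitrary subset sums via
`summed_ppa`, since "methylation on the causal pathway" can reasonably be
read as either.

## Pipeline

Discovery mode chains QC → scan → Bonferroni gate → fine-mapping → MR with
Steiger → colocalization per gene-CpG pair; the scheduled test count is
instruments × traits and the gate threshold α over that count.  Genome-wide
mode looks up lead eQTLs (or proxies at r² ≥ 0.8) across GWAS catalogs,
gates at the total lookup count, and never fine-maps — without
individual-level LD, reference-panel fine-mapping would manufacture false
positives.  One locus failing never kills a run: branch errors are logged
into the report.  Every output embeds a config fingerprint (SHA-256 of the
config plus package version) and reruns with identical config and seed are
byte-identical.  Threshold displays round to two significant figures
(half-to-even); stored values are full precision.

## Problem sizes used in tests and the acceptance script

Null calibration of the scan uses 40 replicate cohorts of 1,500 individuals
× 500 independent variants (20,000 tests); Steiger calibration uses 2,000
replicate study pairs of n = 2,000 at a shared correlation of 0.1.  Wald
recovery averages 200 mediated cohorts of n = 20,000; fine-mapping recovery
uses 100 cohorts of 10 variants at LD 0.5; colocalization discrimination
uses regions of 60 variants at n = 20,000 (10 replicates per scenario in
the acceptance script).  These sizes give Monte-Carlo standard errors
comfortably inside the asserted tolerances (±0.01 and ±0.02 on the type-I
error rates, 3 MC SEs on the recovery targets) while the whole suite runs
in a few minutes on one core.

## Known limitations

Beyond the generator's simplifications listed above: the association stage
has no mixed-model relatedness correction; fine-mapping assumes the z/LD
pair comes from one homogeneous sample; colocalization assumes at most one
causal variant per trait per region and independent (non-overlapping)
samples per trait; and the Wald MR stage inherits all single-instrument
caveats, most importantly its blindness to horizontal pleiotropy.
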