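# tissuemr

Tissue-specific causal triage of GWAS loci: from an eQTL-wide association
scan to fine-mapped, Mendelian-randomization-tested and colocalization-backed
candidate genes.

## The problem

A variant associated with a complex trait usually sits in a region containing
several genes, CpG sites and dozens of correlated variants. `tissuemr`
implements the statistical pipeline used to triage such loci into putative
causal mechanisms, distinguishing five explanations for a variant-trait
association: (1) mediation through a single gene's expression, (2) mediation
through several genes, (3) co-regulation of several genes with only one
causal, (4) two distinct causal variants in linkage disequilibrium (LD), and
(5) horizontal pleiotropy (a direct variant effect not through expression).

The pipeline stages are:

1. **Association scan** (`tissuemr.assoc`) — phenotype QC (outliers beyond
   ±4 SD removed, optional log transform), variant filters (imputation info
   ≥ 0.8, MAF > 0.01), then per-variant ordinary least squares of each trait
   on additive dosage adjusted for age and sex, with a Bonferroni gate at
   α / (instruments × traits).
2. **Fine-mapping** (`tissuemr.finemap`) — exhaustive Bayesian enumeration of
   causal configurations up to 5 variants in the 1-Mb region flanking each
   lead variant.  For a configuration S with regional z-scores z and LD
   matrix R, the marginal model is `z | S ~ N(0, R + W·R[:,S]R[S,:])` with
   `W = n·σ²` (σ the effect-size prior SD), giving
   `log BF(S) = -½ log det(I + W·R_SS) + ½ W·z_S'(I + W·R_SS)⁻¹ z_S` and
   exact per-variant posterior inclusion probabilities (PIPs).
3. **Mendelian randomization** (`tissuemr.mr`) — for each gene × tissue the
   lead cis-eQTL (p < 10⁻⁴ within 1 Mb of the TSS) instruments expression;
   the Wald ratio `β_MR = β_outcome / β_exposure` with first-order SE
   `|se_outcome / β_exposure|` estimates the causal effect.  Exposure and
   outcome alleles are harmonized first (sign flips, strand complements,
   palindromic resolution by frequency), the Steiger test checks
   directionality by comparing Fisher-z transformed variant-trait
   correlations, and missing outcome variants can be replaced by a proxy in
   LD (r² ≥ 0.8).
4. **Multiple-trait colocalization** (`tissuemr.moloc`) — for (trait G,
   expression E, methylation M) over one region, per-variant Wakefield
   approximate Bayes factors `log ABF = ½ log(1−r) + r z²/2`,
   `r = W/(V+W)`, feed posterior probabilities over the 15 configurations of
   which traits share a causal variant, with per-variant priors
   1e-4 / 1e-6 / 1e-7 for variants causal for one / two / three traits.
   Evidence that G and E share a variant is declared when the summed PPA of
   all G-E-sharing configurations reaches 0.8.

Because the individual-level cohort and consortium datasets behind such
analyses are access-controlled, the package ships a first-class synthetic
cohort generator (`tissuemr.simulate`) producing genotypes with AR(1) LD,
cis-regulated expression, logit-scale methylation, covariates and complex
traits under any of the five mechanistic scenarios — so every stage can be
exercised and calibrated end to end against known generative truth.

## Worked example

Simulate a single-gene mediation cohort (allelic effect 0.4 on expression,
expression→trait effect 0.3, 60 variants, n = 20,000) and run the discovery
pipeline:

```python
import numpy as np
from tissuemr.simulate import ScenarioSpec, EqtlEffect, MqtlEffect, simulate_cohort
from tissuemr.pipeline import PipelineConfig, run_discovery

spec = ScenarioSpec(
    scenario_id=1, n_individuals=20000, n_snps=60, maf=np.full(60, 0.3),
    ld_rho=0.4,
    eqtl_effects={"geneA": EqtlEffect(snp_index=30, beta=0.4)},
    mqtl_effects={"cg1": MqtlEffect(snp_index=30, beta=0.5)},
    mediation_effects={"geneA": 0.3},
    covariate_effects=(0.01, 0.2), seed=11,
)
report, outputs = run_discovery(PipelineConfig(), simulate_cohort(spec))
```

prints (via the report and stage outputs):

```
scheduled tests : 60
gate threshold  : 8.33e-04
signals         : 1 (1 unique lead variants)
top PIP         : snp30 (1.000)
Wald ratio      : 0.317 (SE 0.029, p 1.7e-28)
Steiger         : direction_ok=True (p 1.9e-67)
moloc           : PPA(GEM) 1.000, summed G-E 1.000
```

The gate admits exactly the simulated locus; fine-mapping concentrates all
posterior inclusion mass on the true causal variant (snp30); the Wald ratio
(0.317 ± 0.029) covers the generative mediation effect 0.3; Steiger confirms
the expression→trait orientation; and colocalization assigns essentially all
posterior mass to the configuration in which trait, expression and
methylation share one causal variant.

The same stages are available from the shell — `tissuemr simulate`,
`tissuemr assoc run|filter|threshold`, `tissuemr finemap run`,
`tissuemr mr run|volcano-table`, `tissuemr moloc run` and `tissuemr run`
for the configured discovery pipeline.

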