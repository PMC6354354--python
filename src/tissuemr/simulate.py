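"""Synthetic cohorts with the causal structure the pipeline is built to detect.

The generator produces individual-level data — genotype dosages with
linkage disequilibrium (LD), cis-regulated gene expression, CpG methylation,
age/sex covariates and a complex trait — under one of five mechanistic
scenarios describing how a genetic variant may relate to a trait through
gene expression:

1. single-gene mediation: variant → expression of one gene → trait;
2. multi-gene mediation: the variant drives several genes, more than one of
   which affects the trait;
3. co-regulation: the variant drives several genes, but only one mediates
   the trait effect;
4. LD confounding: two *distinct* variants in LD, one driving expression and
   the other driving the trait — no mediation;
5. horizontal pleiotropy: one variant drives expression *and* the trait
   directly, with no mediation through expression.

Genotypes use a latent-Gaussian haplotype model: each haplotype's allele
indicators are obtained by thresholding a first-order autoregressive Gaussian
process at the allele-frequency quantile, so the correlation between adjacent
variants decays geometrically and the LD between any chosen pair can be set
exactly via the closed-form tetrachoric relation.  Dosages are the sum of two
independent haplotypes and take values in {0, 1, 2}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np
import yaml
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "EqtlEffect",
    "MqtlEffect",
    "ScenarioSpec",
    "Cohort",
    "simulate_genotypes",
    "simulate_cohort",
    "dosage_correlation",
    "latent_rho_for_r2",
    "compute_bmi",
    "compute_friedewald_ldl",
    "variant_metadata",
    "export_cohort_tsv",
    "export_vcf",
]

_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("T", "C"), ("G", "A")]


@dataclass
class EqtlEffect:
    """A cis-eQTL: one causal variant for one gene.

    ``beta`` is the expression change per effect-allele copy; ``tissue_scaling``
    optionally rescales it per tissue (1.0 where a tissue is not listed),
    emulating tissue-specific regulatory activity.
    """

    snp_index: int
    beta: float
    tissue_scaling: dict[str, float] = field(default_factory=dict)

    def beta_in(self, tissue: Optional[str]) -> float:
        if tissue is None:
            return self.beta
        return self.beta * self.tissue_scaling.get(tissue, 1.0)


@dataclass
class MqtlEffect:
    """A cis-mQTL: one causal variant for one CpG site (effect on logit scale)."""

    snp_index: int
    beta: float


@dataclass
class ScenarioSpec:
    """Full parameterization of one synthetic cohort.

    Parameters
    ----------
    scenario_id : int
        Mechanistic scenario, 1-5 (see module docstring).
    n_individuals, n_snps : int
        Cohort and regional panel size.
    maf : array-like
        Per-variant effect-allele frequencies in (0, 0.5].
    ld_rho : float
        Latent AR(1) correlation between adjacent variants, in [0, 1).
    eqtl_effects : dict
        gene name -> :class:`EqtlEffect`.
    mqtl_effects : dict
        CpG name -> :class:`MqtlEffect`.
    mediation_effects : dict
        gene name -> effect of that gene's expression on the trait.
    pleiotropy_effect : float
        Direct variant -> trait effect (scenario 5 on the eQTL variant;
        scenario 4 on the first variant of ``ld_pair``).
    ld_pair : tuple, optional
        ``(i, j, target_r2)`` — scenario 4's two distinct causal variants and
        the LD (r^2) to enforce between them.
    noise_sds : dict
        Residual standard deviations; keys are gene names, CpG names and
        ``"trait"``; unlisted names default to 1.0 (0.5 for CpG logits).
    covariate_effects : tuple
        ``(age_beta, sex_beta)`` coefficients on the trait.
    age_range : tuple
        Uniform sampling range for age in years.
    lognormal_traits : tuple
        Trait names to exponentiate after simulation (log-normal traits).
    seed : int
        Global seed; all randomness derives from it via a splittable stream.
    """

    scenario_id: int
    n_individuals: int
    n_snps: int
    maf: np.ndarray
    ld_rho: float = 0.0
    eqtl_effects: dict[str, EqtlEffect] = field(default_factory=dict)
    mqtl_effects: dict[str, MqtlEffect] = field(default_factory=dict)
    mediation_effects: dict[str, float] = field(default_factory=dict)
    pleiotropy_effect: float = 0.0
    ld_pair: Optional[tuple[int, int, float]] = None
    noise_sds: dict[str, float] = field(default_factory=dict)
    covariate_effects: tuple[float, float] = (0.0, 0.0)
    age_range: tuple[float, float] = (7.0, 10.5)
    lognormal_traits: tuple[str, ...] = ()
    seed: int = 0
    chrom: str = "1"
    pos_start: int = 1_000_000
    pos_step: int = 5_000

    def __post_init__(self) -> None:
        self.maf = np.asarray(self.maf, dtype=float)
        if self.maf.shape != (self.n_snps,):
            if self.maf.size == 1:
                self.maf = np.full(self.n_snps, float(self.maf))
            else:
                raise ValueError(
                    f"maf has length {self.maf.size}, expected {self.n_snps}"
                )
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.scenario_id not in (1, 2, 3, 4, 5):
            raise ValueError(f"scenario_id must be 1-5, got {self.scenario_id}")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
            raise ValueError("all MAFs must lie in (0, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        for name, sd in self.noise_sds.items():
            if sd <= 0:
                raise ValueError(f"noise SD for {name!r} must be positive")
        for gene, eff in self.eqtl_effects.items():
            if not (0 <= eff.snp_index < self.n_snps):
                raise ValueError(f"eQTL snp_index out of range for gene {gene!r}")
        for cpg, eff in self.mqtl_effects.items():
            if not (0 <= eff.snp_index < self.n_snps):
                raise ValueError(f"mQTL snp_index out of range for CpG {cpg!r}")
        unknown = set(self.mediation_effects) - set(self.eqtl_effects)
        if unknown:
            raise ValueError(f"mediation effects for unsimulated genes: {unknown}")

        n_mediated = sum(1 for v in self.mediation_effects.values() if v != 0.0)
        sid = self.scenario_id
        if sid == 1 and n_mediated != 1:
            raise ValueError("scenario 1 requires exactly one mediated gene")
        if sid == 2 and n_mediated < 2:
            raise ValueError("scenario 2 requires >= 2 mediated genes")
        if sid == 3:
            if n_mediated != 1:
                raise ValueError("scenario 3 requires exactly one mediated gene")
            indices = [e.snp_index for e in self.eqtl_effects.values()]
            if len(indices) < 2 or len(set(indices)) != 1:
                raise ValueError(
                    "scenario 3 requires >= 2 genes co-regulated by one variant"
                )
        if sid == 4:
            if self.ld_pair is None:
                raise ValueError("scenario 4 requires ld_pair")
            i, j, r2 = self.ld_pair
            if i == j:
                raise ValueError("ld_pair indices must be distinct")
            if not (0 <= i < self.n_snps and 0 <= j < self.n_snps):
                raise ValueError("ld_pair indices out of range")
            if not (0.0 < r2 < 1.0):
                raise ValueError("ld_pair target r2 must lie in (0, 1)")
            if n_mediated != 0:
                raise ValueError("scenario 4 has no mediation")
            if self.pleiotropy_effect == 0.0:
                raise ValueError("scenario 4 requires a direct trait effect")
            drivers = {e.snp_index for e in self.eqtl_effects.values()}
            if drivers != {j}:
                raise ValueError(
                    "scenario 4: expression must be driven by the second "
                    "variant of ld_pair"
                )
        if sid == 5:
            if self.pleiotropy_effect == 0.0:
                raise ValueError("scenario 5 requires a nonzero pleiotropy effect")
            if n_mediated != 0:
                raise ValueError("scenario 5 has no mediation")

    # -- derived ------------------------------------------------------------
    @property
    def direct_snp_index(self) -> Optional[int]:
        """Variant carrying the direct (unmediated) trait effect, if any."""
        if self.pleiotropy_effect == 0.0:
            return None
        if self.scenario_id == 4:
            return self.ld_pair[0]
        # scenario 5: the shared eQTL variant (first gene by name)
        gene = sorted(self.eqtl_effects)[0]
        return self.eqtl_effects[gene].snp_index

    def noise_sd(self, name: str, default: float = 1.0) -> float:
        return self.noise_sds.get(name, default)

    def variant_ids(self) -> list[str]:
        return [f"snp{j}" for j in range(self.n_snps)]

    def positions(self) -> np.ndarray:
        return self.pos_start + self.pos_step * np.arange(self.n_snps)

    # -- config round-trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["maf"] = [float(x) for x in self.maf]
        d["ld_pair"] = list(self.ld_pair) if self.ld_pair else None
        d["covariate_effects"] = list(self.covariate_effects)
        d["age_range"] = list(self.age_range)
        d["lognormal_traits"] = list(self.lognormal_traits)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["eqtl_effects"] = {
            g: EqtlEffect(**v) for g, v in (d.get("eqtl_effects") or {}).items()
        }
        d["mqtl_effects"] = {
            c: MqtlEffect(**v) for c, v in (d.get("mqtl_effects") or {}).items()
        }
        if d.get("ld_pair"):
            d["ld_pair"] = tuple(d["ld_pair"])
        d["covariate_effects"] = tuple(d.get("covariate_effects", (0.0, 0.0)))
        d["age_range"] = tuple(d.get("age_range", (7.0, 10.5)))
        d["lognormal_traits"] = tuple(d.get("lognormal_traits", ()))
        return cls(**d)


@dataclass
class Cohort:
    """Individual-level synthetic data produced under a :class:`ScenarioSpec`."""

    dosages: np.ndarray  # (n, n_snps) int8 in {0,1,2}
    age: np.ndarray
    sex: np.ndarray
    expression: np.ndarray  # (n, n_genes)
    methylation: np.ndarray  # (n, n_cpgs) in (0,1)
    traits: dict[str, np.ndarray]
    gene_names: list[str]
    cpg_names: list[str]
    truth: ScenarioSpec

    def __post_init__(self) -> None:
        n = self.dosages.shape[0]
        for arr, label in [(self.age, "age"), (self.sex, "sex")]:
            if arr.shape[0] != n:
                raise ValueError(f"{label} length mismatch")
        if self.expression.shape != (n, len(self.gene_names)):
            raise ValueError("expression shape mismatch")
        if self.methylation.shape != (n, len(self.cpg_names)):
            raise ValueError("methylation shape mismatch")
        if self.methylation.size and not (
            (self.methylation > 0).all() and (self.methylation < 1).all()
        ):
            raise ValueError("methylation values must lie strictly in (0, 1)")
        for name, vec in self.traits.items():
            if vec.shape[0] != n:
                raise ValueError(f"trait {name!r} length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def covariates(self) -> np.ndarray:
        """(n, 2) age/sex design block."""
        return np.column_stack([self.age, self.sex])


# ---------------------------------------------------------------------------
# LD closed forms
# ---------------------------------------------------------------------------

def _bvn_lower(t1: float, t2: float, rho: float) -> float:
    """P(Z1 < t1, Z2 < t2) for standard bivariate normal with correlation rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    return float(
        stats.multivariate_normal(mean=[0.0, 0.0], cov=cov, allow_singular=True).cdf(
            [t1, t2]
        )
    )


def dosage_correlation(maf1: float, maf2: float, latent_rho: float) -> float:
    """Dosage (and haplotype-allele) correlation implied by a latent correlation.

    Alleles are indicators of a latent Gaussian falling below the allele
    frequency quantile; the dosage correlation equals the indicator
    correlation because dosages sum two independent haplotypes.
    """
    t1, t2 = stats.norm.ppf(maf1), stats.norm.ppf(maf2)
    p11 = _bvn_lower(t1, t2, latent_rho)
    num = p11 - maf1 * maf2
    den = math.sqrt(maf1 * (1 - maf1) * maf2 * (1 - maf2))
    return num / den


def latent_rho_for_r2(maf1: float, maf2: float, target_r2: float) -> float:
    """Latent correlation giving dosage r^2 = ``target_r2`` between two variants."""
    target_r = math.sqrt(target_r2)
    f = lambda rho: dosage_correlation(maf1, maf2, rho) - target_r
    hi = 1.0 - 1e-9
    if f(hi) < 0:
        raise ValueError(
            f"target r2 {target_r2} unattainable for MAFs {maf1}, {maf2}"
        )
    return brentq(f, 0.0, hi, xtol=1e-10)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_genotypes(
    n: int,
    maf,
    ld_rho: float,
    seed: Union[int, np.random.Generator],
    step_rhos: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Simulate an (n, m) dosage matrix with AR(1)-decaying LD.

    Each of 2n haplotypes carries, at variant j, the indicator of a latent
    AR(1) standard Gaussian falling below ``Phi^{-1}(maf_j)``; the latent
    correlation between adjacent variants is ``ld_rho`` (or the per-step
    ``step_rhos`` override, used to pin the LD of a chosen variant pair).
    Identical seeds give identical matrices.
    """
    maf = np.atleast_1d(np.asarray(maf, dtype=float))
    if n < 2:
        raise ValueError("n must be >= 2")
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ValueError("all MAFs must lie in (0, 0.5]")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must lie in [0, 1)")
    m = maf.size
    if step_rhos is None:
        step_rhos = np.full(max(m - 1, 0), ld_rho)
    else:
        step_rhos = np.asarray(step_rhos, dtype=float)
        if step_rhos.shape != (m - 1,):
            raise ValueError("step_rhos must have length m - 1")
        if np.any(step_rhos < 0) or np.any(step_rhos >= 1):
            raise ValueError("step correlations must lie in [0, 1)")

    rng = _as_rng(seed)
    thresholds = stats.norm.ppf(maf)
    latent = np.empty((2 * n, m))
    latent[:, 0] = rng.standard_normal(2 * n)
    for j in range(1, m):
        rho = step_rhos[j - 1]
        latent[:, j] = rho * latent[:, j - 1] + math.sqrt(
            1.0 - rho * rho
        ) * rng.standard_normal(2 * n)
    alleles = (latent < thresholds).astype(np.int8)
    return alleles[:n] + alleles[n:]


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

def simulate_cohort(spec: ScenarioSpec, tissue: Optional[str] = None) -> Cohort:
    """Simulate one cohort under ``spec``.

    Expression of each gene g is ``beta_g * G + noise`` (unit residual SD by
    default, so expression is on an approximately standardized scale);
    methylation effects act on the logit scale and are squashed into (0, 1);
    the trait sums mediated expression effects, any direct variant effect,
    age/sex covariate effects and Gaussian noise.  ``tissue`` selects the
    per-tissue eQTL scaling (None = unscaled).
    """
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    s_geno, s_cov, s_expr, s_meth, s_trait = [
        np.random.default_rng(s) for s in root.spawn(5)
    ]
    n = spec.n_individuals

    step_rhos = None
    if spec.ld_pair is not None:
        i, j, r2 = spec.ld_pair
        lo, hi = (i, j) if i < j else (j, i)
        gap = hi - lo
        pair_rho = latent_rho_for_r2(spec.maf[lo], spec.maf[hi], r2)
        step_rhos = np.full(max(spec.n_snps - 1, 0), spec.ld_rho)
        step_rhos[lo:hi] = pair_rho ** (1.0 / gap)

    dosages = simulate_genotypes(
        n, spec.maf, spec.ld_rho, s_geno, step_rhos=step_rhos
    )

    age = s_cov.uniform(*spec.age_range, size=n)
    sex = s_cov.integers(0, 2, size=n).astype(np.int8)

    gene_names = sorted(spec.eqtl_effects)
    expression = np.empty((n, len(gene_names)))
    for k, gene in enumerate(gene_names):
        eff = spec.eqtl_effects[gene]
        noise = s_expr.standard_normal(n) * spec.noise_sd(gene, 1.0)
        expression[:, k] = eff.beta_in(tissue) * dosages[:, eff.snp_index] + noise

    cpg_names = sorted(spec.mqtl_effects)
    methylation = np.empty((n, len(cpg_names)))
    for k, cpg in enumerate(cpg_names):
        eff = spec.mqtl_effects[cpg]
        latent = eff.beta * dosages[:, eff.snp_index] + s_meth.standard_normal(
            n
        ) * spec.noise_sd(cpg, 0.5)
        methylation[:, k] = expit(latent)

    age_beta, sex_beta = spec.covariate_effects
    trait = np.zeros(n)
    for gene, c in spec.mediation_effects.items():
        if c != 0.0:
            trait += c * expression[:, gene_names.index(gene)]
    if spec.pleiotropy_effect != 0.0:
        trait += spec.pleiotropy_effect * dosages[:, spec.direct_snp_index]
    trait += age_beta * (age - np.mean(spec.age_range)) + sex_beta * sex
    trait += s_trait.standard_normal(n) * spec.noise_sd("trait", 1.0)
    if "trait" in spec.lognormal_traits:
        trait = np.exp(trait)

    return Cohort(
        dosages=dosages,
        age=age,
        sex=sex,
        expression=expression,
        methylation=methylation,
        traits={"trait": trait},
        gene_names=gene_names,
        cpg_names=cpg_names,
        truth=spec,
    )


# ---------------------------------------------------------------------------
# Derived phenotypes
# ---------------------------------------------------------------------------

def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight [kg] / height [m]^2."""
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    out = weight / height**2
    return float(out) if out.ndim == 0 else out


def compute_friedewald_ldl(
    tc: float, hdl: float, tg: float, tg_limit: float = 4.52, divisor: float = 2.2
) -> float:
    """LDL cholesterol by the Friedewald equation, ``TC - HDL - TG/divisor``.

    Units are mmol/L by default (divisor 2.2; use 5.0 with mg/dL inputs).
    Triglycerides above ``tg_limit`` invalidate the approximation: the result
    is NaN (flagged missing), not an exception.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tc < 0) or np.any(hdl < 0) or np.any(tg < 0):
        raise ValueError("lipid concentrations must be non-negative")
    ldl = np.where(tg > tg_limit, np.nan, tc - hdl - tg / divisor)
    return float(ldl) if ldl.ndim == 0 else ldl


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def variant_metadata(spec: ScenarioSpec):
    """Variant table: chrom, 1-based pos, other/effect alleles, MAF."""
    import pandas as pd

    ids = spec.variant_ids()
    alleles = [_ALLELE_CYCLE[j % len(_ALLELE_CYCLE)] for j in range(spec.n_snps)]
    return pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": spec.chrom,
            "pos": spec.positions(),
            "other_allele": [a for a, _ in alleles],
            "effect_allele": [b for _, b in alleles],
            "maf": spec.maf,
        }
    )


def export_cohort_tsv(cohort: Cohort, prefix: str) -> dict[str, str]:
    """Write dosages, phenotypes and variant metadata as TSV files.

    Returns the mapping of table name to file path.  Dosage rows are
    individuals, columns variant IDs; phenotypes bundle covariates, molecular
    traits and complex traits.
    """
    import pandas as pd

    spec = cohort.truth
    paths = {}
    dos = pd.DataFrame(cohort.dosages, columns=spec.variant_ids())
    dos.insert(0, "individual_id", [f"id{i}" for i in range(cohort.n_individuals)])
    paths["dosages"] = f"{prefix}.dosages.tsv"
    dos.to_csv(paths["dosages"], sep="\t", index=False)

    pheno = pd.DataFrame(
        {"individual_id": dos["individual_id"], "age": cohort.age, "sex": cohort.sex}
    )
    for k, gene in enumerate(cohort.gene_names):
        pheno[f"expr_{gene}"] = cohort.expression[:, k]
    for k, cpg in enumerate(cohort.cpg_names):
        pheno[f"meth_{cpg}"] = cohort.methylation[:, k]
    for name, vec in cohort.traits.items():
        pheno[name] = vec
    paths["phenotypes"] = f"{prefix}.phenotypes.tsv"
    pheno.to_csv(paths["phenotypes"], sep="\t", index=False, na_rep="NA")

    paths["variants"] = f"{prefix}.variants.tsv"
    variant_metadata(spec).to_csv(paths["variants"], sep="\t", index=False)
    return paths


def export_vcf(cohort: Cohort, path: str) -> None:
    """Minimal VCF 4.2 export of dosages as unphased genotypes."""
    spec = cohort.truth
    meta = variant_metadata(spec)
    samples = [f"id{i}" for i in range(cohort.n_individuals)]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, row in meta.iterrows():
            gts = "\t".join(gt_map[int(d)] for d in cohort.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.other_allele}\t"
                f"{row.effect_allele}\t.\tPASS\t.\tGT\t{gts}\n"
            )
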