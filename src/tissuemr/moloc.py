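"""Bayesian multiple-trait colocalization over GWAS, expression and methylation.

For three traits — a complex trait G, gene expression E and CpG methylation M
measured over one genomic region — the method asks which traits share a
causal variant.  Each trait contributes per-variant approximate Bayes
factors (Wakefield's closed form from beta and SE); traits are then
partitioned into causal groups, each group assigned its own causal variant,
with *distinct* variants across groups.  For three traits there are 15 such
configurations (including the null).  The evidence for a configuration with
groups D_1..D_g is

    sum over distinct variants (j_1..j_g) of
        prod_h [ p_{|D_h|} * prod_{t in D_h} ABF_t(j_h) ],

with per-variant priors p_1, p_2, p_3 for variants causal for one, two or
three traits (defaults 1e-4, 1e-6, 1e-7).  Posterior probabilities of
association (PPAs) normalize these evidences over all 15 configurations; the
distinct-variant sums are evaluated exactly in log space by
inclusion-exclusion rather than by brute-force enumeration.

Decision rules follow the summed-PPA convention: evidence that G and E
colocalize when the PPAs of all configurations placing G and E in one group
sum to >= 0.8, and that methylation shares the same variant when the
all-share configuration reaches >= 0.8.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "TraitAssoc",
    "Configuration",
    "MolocResult",
    "wakefield_log_abf",
    "enumerate_configurations",
    "moloc_region",
    "summed_ppa",
    "map_cpg_to_genes",
]

DEFAULT_PRIORS = (1e-4, 1e-6, 1e-7)
DEFAULT_PRIOR_SD = 0.15
DEFAULT_MIN_SNPS = 50
DEFAULT_MAF_MIN = 0.05
NULL_LABEL = "null"


def wakefield_log_abf(beta, se, prior_sd: float = DEFAULT_PRIOR_SD):
    """Log approximate Bayes factor for one association, in favor of a signal.

    With V = se^2, W = prior_sd^2, shrinkage r = W / (V + W) and z = beta/se:

        log ABF = 1/2 log(1 - r) + r z^2 / 2.

    This is the reciprocal of Wakefield's original null-favoring ABF, i.e.
    large positive values support association.  Accepts scalars or arrays.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    z = beta / se
    out = 0.5 * np.log1p(-r) + 0.5 * r * z**2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Configuration:
    """One sharing configuration: a set partition of a subset of the traits.

    ``groups`` is a tuple of trait-label tuples; each group shares one causal
    variant, distinct across groups; traits absent from every group are
    unassociated.  The empty configuration is the null.
    """

    groups: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            if not g:
                raise ValueError("groups must be nonempty")
            if seen & set(g):
                raise ValueError("groups must be disjoint")
            seen |= set(g)

    @property
    def label(self) -> str:
        if not self.groups:
            return NULL_LABEL
        return ".".join("".join(g) for g in self.groups)

    def contains_together(self, subset) -> bool:
        """True when some group contains every trait in ``subset``."""
        want = set(subset)
        return any(want <= set(g) for g in self.groups)


def _partitions(items: tuple[str, ...]):
    """All set partitions of ``items``, preserving element order within groups."""
    if not items:
        yield ()
        return
    head, rest = items[0], items[1:]
    for part in _partitions(rest):
        yield ((head,),) + part
        for i, block in enumerate(part):
            yield part[:i] + ((head,) + block,) + part[i + 1 :]


def enumerate_configurations(
    n_traits: int, labels: tuple[str, ...] = ("G", "E", "M", "T4")
) -> list[Configuration]:
    """All sharing configurations for ``n_traits`` traits, null included.

    Counts follow sum over subsets of Bell numbers: 2 for one trait, 5 for
    two, 15 for three, 52 for four.  The ordering is deterministic: by the
    set of involved traits, then by partition coarseness.
    """
    if not (1 <= n_traits <= 4):
        raise ValueError("n_traits must lie in 1..4")
    traits = labels[:n_traits]
    configs = [Configuration(groups=())]
    for size in range(1, n_traits + 1):
        for subset in combinations(traits, size):
            block = sorted(
                {
                    Configuration(groups=tuple(sorted(p, key=lambda g: traits.index(g[0]))))
                    for p in _partitions(subset)
                },
                key=lambda c: (len(c.groups), c.label),
            )
            configs.extend(block)
    return configs


@dataclass
class TraitAssoc:
    """Per-variant summary statistics for one trait over one region.

    ``trait_label`` is the configuration letter (G, E or M); ``records`` a
    summary-statistics table with one row per variant; ``prior_sd`` the
    effect-scale prior for this trait's Bayes factors.
    """

    trait_label: str
    records: pd.DataFrame
    name: str = ""
    prior_sd: float = DEFAULT_PRIOR_SD
    sdY_known: bool = True

    def __post_init__(self) -> None:
        if self.records["variant_id"].duplicated().any():
            raise ValueError(
                f"trait {self.trait_label}: duplicate variants in the region"
            )
        usable = self.records["se"].dropna()
        if (usable <= 0).any():
            raise ValueError(f"trait {self.trait_label}: non-positive SEs")


@dataclass
class MolocResult:
    """PPAs over the 15 sharing configurations plus summed-PPA decisions."""

    ppa: dict[str, float]
    n_snps_used: int
    summed_ge: float
    gem: float
    decision_ge: bool
    decision_gem: bool
    skipped: bool = False
    reason: str = ""
    configurations: list[Configuration] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.skipped:
            return
        total = sum(self.ppa.values())
        if not math.isclose(total, 1.0, abs_tol=1e-8):
            raise ValueError(f"PPAs sum to {total}, not 1")
        if any(not (-1e-12 <= v <= 1 + 1e-12) for v in self.ppa.values()):
            raise ValueError("PPAs outside [0, 1]")
        if self.summed_ge < self.gem - 1e-12:
            raise ValueError("summed G-E PPA cannot be below the all-share PPA")


def _log_distinct_assignment_sum(log_w: list[np.ndarray]) -> float:
    """log of sum over distinct-variant assignments of prod_h w_h[j_h].

    Inclusion-exclusion over set partitions of the group indices: collapsing
    a block B of groups onto one shared variant contributes
    S_B = sum_j prod_{h in B} w_h[j], with Moebius weight
    (-1)^(|B|-1) (|B|-1)!.  For numerical stability each group's weights are
    first normalized to probabilities a_h (factoring out sum_j w_h[j]), so the
    alternating sum runs over quantities in [0, 1].  A sum that cancels below
    the floating-point floor corresponds to evidence many hundreds of log
    units below the dominant configurations; it is reported as -inf.
    """
    g = len(log_w)
    log_scales = [float(logsumexp(w)) for w in log_w]
    a = [np.exp(w - s) for w, s in zip(log_w, log_scales)]
    terms = []
    for part in _partitions(tuple(range(g))):
        sign = 1.0
        value = 1.0
        for block in part:
            b = len(block)
            if (b - 1) % 2 == 1:
                sign = -sign
            value *= math.factorial(b - 1)
            if b > 1:
                value *= float(np.prod([a[h] for h in block], axis=0).sum())
        terms.append(sign * value)
    total = math.fsum(terms)
    if total <= 0.0:
        return -np.inf
    return math.fsum(log_scales) + math.log(total)


def _harmonize_three(
    assocs: list[TraitAssoc], maf_min: float
) -> tuple[list[str], list[np.ndarray], list[np.ndarray]]:
    """Intersect variants after per-dataset MAF filtering and align alleles.

    The first dataset's effect allele is the reference orientation; swapped
    records in the others have their betas sign-flipped; variants with
    irreconcilable alleles are dropped.
    """
    filtered = []
    for a in assocs:
        df = a.records
        maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
        keep = (maf >= maf_min) & df["beta"].notna() & df["se"].notna()
        filtered.append(df[keep].set_index("variant_id"))
    common = sorted(set.intersection(*(set(df.index) for df in filtered)))
    ref = filtered[0]
    ids, betas, ses = [], [[] for _ in assocs], [[] for _ in assocs]
    for vid in common:
        ra = (ref.at[vid, "effect_allele"], ref.at[vid, "other_allele"])
        row_betas, row_ses, ok = [], [], True
        for df in filtered:
            ea, oa = df.at[vid, "effect_allele"], df.at[vid, "other_allele"]
            b, s = float(df.at[vid, "beta"]), float(df.at[vid, "se"])
            if (ea, oa) == ra:
                pass
            elif (oa, ea) == ra:
                b = -b
            else:
                ok = False
                break
            row_betas.append(b)
            row_ses.append(s)
        if not ok:
            logger.info("variant %s dropped: alleles irreconcilable", vid)
            continue
        ids.append(vid)
        for k in range(len(assocs)):
            betas[k].append(row_betas[k])
            ses[k].append(row_ses[k])
    return ids, [np.asarray(b) for b in betas], [np.asarray(s) for s in ses]


def moloc_region(
    g: TraitAssoc,
    e: TraitAssoc,
    m: TraitAssoc,
    priors: tuple[float, ...] = DEFAULT_PRIORS,
    min_snps: int = DEFAULT_MIN_SNPS,
    maf_min: float = DEFAULT_MAF_MIN,
    ppa_threshold: float = 0.8,
) -> MolocResult:
    """Colocalization of a complex trait, gene expression and methylation.

    Variants are MAF-filtered per dataset (MAF >= ``maf_min``, inclusive) and
    intersected; regions with fewer than ``min_snps`` common variants are
    skipped with a structured result rather than an exception.  PPAs over all
    15 configurations are returned together with the summed G-E PPA, the
    all-share (GEM) PPA and the two threshold decisions.
    """
    assocs = [g, e, m]
    labels = tuple(a.trait_label for a in assocs)
    if labels != ("G", "E", "M"):
        raise ValueError(f"expected trait labels (G, E, M), got {labels}")
    ids, betas, ses = _harmonize_three(assocs, maf_min)
    if len(ids) < min_snps:
        return MolocResult(
            ppa={},
            n_snps_used=len(ids),
            summed_ge=float("nan"),
            gem=float("nan"),
            decision_ge=False,
            decision_gem=False,
            skipped=True,
            reason=f"insufficient SNPs (<{min_snps})",
        )

    log_abf = {
        a.trait_label: wakefield_log_abf(b, s, a.prior_sd)
        for a, b, s in zip(assocs, betas, ses)
    }
    configs = enumerate_configurations(3)
    log_evidence = np.empty(len(configs))
    log_priors = np.log(np.asarray(priors, dtype=float))
    for i, cfg in enumerate(configs):
        if not cfg.groups:
            log_evidence[i] = 0.0  # null: empty product over an empty assignment
            continue
        log_w = [
            log_priors[len(grp) - 1] + np.sum([log_abf[t] for t in grp], axis=0)
            for grp in cfg.groups
        ]
        log_evidence[i] = _log_distinct_assignment_sum(log_w)
    ppa_vec = np.exp(log_evidence - logsumexp(log_evidence))
    ppa = {cfg.label: float(p) for cfg, p in zip(configs, ppa_vec)}

    ge = sum(
        p for cfg, p in zip(configs, ppa_vec) if cfg.contains_together(("G", "E"))
    )
    return MolocResult(
        ppa=ppa,
        n_snps_used=len(ids),
        summed_ge=float(ge),
        gem=ppa["GEM"],
        decision_ge=bool(ge >= ppa_threshold),
        decision_gem=bool(ppa["GEM"] >= ppa_threshold),
        configurations=configs,
    )


def summed_ppa(result: MolocResult, subset) -> float:
    """Total PPA of configurations where all traits in ``subset`` share a group."""
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    known = {t for cfg in result.configurations for grp in cfg.groups for t in grp}
    unknown = set(subset) - known
    if unknown:
        raise ValueError(f"unknown trait labels: {sorted(unknown)}")
    return float(
        sum(
            result.ppa[cfg.label]
            for cfg in result.configurations
            if cfg.contains_together(subset)
        )
    )


def map_cpg_to_genes(
    lead_pos: int,
    cpgs: dict[str, int],
    genes: dict[str, int],
    window: int = 1_000_000,
) -> list[tuple[str, str]]:
    """All (gene, CpG) pairs within ``window`` of the lead variant.

    ``cpgs`` maps CpG name to position, ``genes`` maps gene name to TSS; the
    boundary is inclusive.  Pairs are returned in sorted (gene, CpG) order.
    """
    in_genes = sorted(g for g, tss in genes.items() if abs(tss - lead_pos) <= window)
    in_cpgs = sorted(c for c, pos in cpgs.items() if abs(pos - lead_pos) <= window)
    return [(g, c) for g in in_genes for c in in_cpgs]
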