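"""Two-sample Mendelian randomization with a single cis-eQTL instrument.

For each gene x tissue, the lead cis-eQTL (p < 1e-4 within 1 Mb of the
transcription start site) instruments gene expression; the Wald ratio
``beta_outcome / beta_exposure`` estimates the causal effect of expression on
the complex trait, with a first-order delta-method standard error.  Effect
alleles of exposure and outcome are harmonized first (sign flips, strand
complements, palindromic resolution by allele frequency), and the Steiger
directionality test checks that the instrument explains more variance in the
exposure than in the outcome, guarding against reverse causation.  When an
instrument is absent from the outcome study, a proxy in LD (r^2 >= 0.8) may
substitute.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SummaryRecord

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizationError",
    "HarmonizedPair",
    "WaldResult",
    "SteigerResult",
    "select_instruments",
    "harmonize",
    "wald_ratio",
    "steiger_test",
    "find_proxy",
]

PALINDROMIC_EAF_LIMIT = 0.42
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class HarmonizationError(ValueError):
    """Exposure and outcome alleles cannot be reconciled."""


@dataclass
class HarmonizedPair:
    """Exposure and outcome records aligned to one effect allele."""

    variant_id: str
    exposure: SummaryRecord
    outcome: SummaryRecord
    aligned_effect_allele: str
    flips_applied: bool
    palindromic_status: str  # "not" | "resolved" | "dropped"

    def __post_init__(self) -> None:
        if self.palindromic_status != "dropped":
            if self.exposure.effect_allele != self.outcome.effect_allele:
                raise ValueError("pair not aligned to one effect allele")
            if not (self.exposure.se > 0 and self.outcome.se > 0):
                raise ValueError("both standard errors must be positive")


@dataclass
class WaldResult:
    """Single-instrument MR estimate: outcome units per unit exposure."""

    beta_mr: float
    se_mr: float
    p: float
    exposure_name: str = ""
    outcome_name: str = ""
    variant_id: str = ""

    def __post_init__(self) -> None:
        if not (self.se_mr > 0):
            raise ValueError("se_mr must be positive")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")


@dataclass
class SteigerResult:
    """Directionality verdict: does the variant explain more exposure variance?"""

    r2_exposure: float
    r2_outcome: float
    z_statistic: float
    p: float
    direction_ok: bool

    def __post_init__(self) -> None:
        for r2 in (self.r2_exposure, self.r2_outcome):
            if not (0.0 <= r2 <= 1.0):
                raise ValueError("r^2 values must lie in [0, 1]")


def select_instruments(
    eqtl: pd.DataFrame,
    tss: dict[str, int],
    p_threshold: float = 1e-4,
    cis_window: int = 1_000_000,
) -> pd.DataFrame:
    """Pick one lead cis instrument per gene x tissue.

    ``eqtl`` is a summary table annotated with ``gene`` and ``tissue``
    columns; ``tss`` maps gene to its transcription start site.  Records are
    kept when they fall within ``cis_window`` of the gene's TSS (inclusive at
    exactly the boundary) and have p strictly below ``p_threshold``; the
    smallest p per group wins, ties broken by variant_id.  Gene x tissue
    pairs with no passing record are absent from the result (logged).
    """
    for col in ("gene", "tissue"):
        if col not in eqtl.columns:
            raise ValueError(f"eqtl table lacks the {col!r} annotation column")
    df = eqtl.copy()
    df["_tss"] = df["gene"].map(tss)
    if df["_tss"].isna().any():
        missing = sorted(df.loc[df["_tss"].isna(), "gene"].unique())
        raise ValueError(f"no TSS for genes: {missing}")
    cis = (df["pos"] - df["_tss"]).abs() <= cis_window
    passing = df[cis & (df["p"] < p_threshold)]
    if passing.empty:
        logger.info("no instrument passed p < %g in the cis window", p_threshold)
        return passing.drop(columns="_tss")
    lead = (
        passing.sort_values(["gene", "tissue", "p", "variant_id"])
        .groupby(["gene", "tissue"], as_index=False)
        .first()
    )
    found = set(map(tuple, lead[["gene", "tissue"]].to_numpy()))
    for key in set(map(tuple, df[["gene", "tissue"]].to_numpy())) - found:
        logger.info("gene %s in tissue %s: no passing instrument", *key)
    return lead.drop(columns="_tss")


def _flip(record: SummaryRecord) -> SummaryRecord:
    return replace(
        record,
        effect_allele=record.other_allele,
        other_allele=record.effect_allele,
        beta=-record.beta,
        eaf=1.0 - record.eaf,
    )


def _complement(record: SummaryRecord) -> SummaryRecord:
    return replace(
        record,
        effect_allele=_COMPLEMENT[record.effect_allele],
        other_allele=_COMPLEMENT[record.other_allele],
    )


def harmonize(exposure: SummaryRecord, outcome: SummaryRecord) -> HarmonizedPair:
    """Align the outcome record to the exposure's effect allele.

    Tries, in order: direct match; allele swap (flip beta sign and EAF);
    strand complement; complement plus swap.  Palindromic pairs (A/T, C/G)
    carry no strand information, so they are resolved by allele frequency
    only when both minor-allele frequencies are below 0.42, and dropped
    otherwise.  Irreconcilable allele sets raise :class:`HarmonizationError`.
    """
    exp_alleles = (exposure.effect_allele, exposure.other_allele)
    if exposure.is_palindromic():
        if exposure.maf >= PALINDROMIC_EAF_LIMIT or outcome.maf >= PALINDROMIC_EAF_LIMIT:
            return HarmonizedPair(
                variant_id=exposure.variant_id,
                exposure=exposure,
                outcome=outcome,
                aligned_effect_allele=exposure.effect_allele,
                flips_applied=False,
                palindromic_status="dropped",
            )
        # frequencies are informative: align so the outcome's EAF matches
        out = outcome
        if (outcome.eaf < 0.5) != (exposure.eaf < 0.5):
            out = _flip(outcome)
        if (out.effect_allele, out.other_allele) != exp_alleles:
            out = _complement(out)
        if (out.effect_allele, out.other_allele) != exp_alleles:
            raise HarmonizationError(
                f"{exposure.variant_id}: alleles "
                f"{exposure.effect_allele}/{exposure.other_allele} vs "
                f"{outcome.effect_allele}/{outcome.other_allele}"
            )
        return HarmonizedPair(
            variant_id=exposure.variant_id,
            exposure=exposure,
            outcome=out,
            aligned_effect_allele=exposure.effect_allele,
            flips_applied=out is not outcome,
            palindromic_status="resolved",
        )

    for transform, flipped in (
        (lambda r: r, False),
        (_flip, True),
        (_complement, False),
        (lambda r: _flip(_complement(r)), True),
    ):
        candidate = transform(outcome)
        if (candidate.effect_allele, candidate.other_allele) == exp_alleles:
            return HarmonizedPair(
                variant_id=exposure.variant_id,
                exposure=exposure,
                outcome=candidate,
                aligned_effect_allele=exposure.effect_allele,
                flips_applied=flipped,
                palindromic_status="not",
            )
    raise HarmonizationError(
        f"{exposure.variant_id}: alleles "
        f"{exposure.effect_allele}/{exposure.other_allele} vs "
        f"{outcome.effect_allele}/{outcome.other_allele} irreconcilable"
    )


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> WaldResult:
    """Wald-ratio causal estimate from one harmonized instrument.

    ``beta_mr = beta_outcome / beta_exposure``.  The default standard error
    is the first-order delta approximation ``|se_outcome / beta_exposure|``
    (the single-instrument convention, ignoring exposure uncertainty);
    ``second_order`` adds the exposure-variance term.  The p-value is
    two-sided against the standard normal.
    """
    if pair.palindromic_status == "dropped":
        raise ValueError(f"{pair.variant_id}: pair was dropped at harmonization")
    bx, sx = pair.exposure.beta, pair.exposure.se
    by, sy = pair.outcome.beta, pair.outcome.se
    if bx == 0:
        raise ZeroDivisionError(f"{pair.variant_id}: exposure effect is zero")
    beta_mr = by / bx
    se_mr = abs(sy / bx)
    if second_order:
        se_mr = math.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    z = beta_mr / se_mr
    p = 2.0 * stats.norm.sf(abs(z))
    return WaldResult(
        beta_mr=beta_mr,
        se_mr=se_mr,
        p=max(p, np.nextafter(0, 1)),
        exposure_name=pair.exposure.trait,
        outcome_name=pair.outcome.trait,
        variant_id=pair.variant_id,
    )


def _r_from_t(beta: float, se: float, n: int) -> float:
    """Pearson correlation implied by a regression t statistic (df = n - 2)."""
    t = beta / se
    df = n - 2
    return t / math.sqrt(t * t + df)


def steiger_test(
    pair: HarmonizedPair, n_exp: int, n_out: int
) -> SteigerResult:
    """Two-sample Steiger directionality test.

    Reconstructs the variant-trait correlation in each study from the
    regression t statistic and compares Fisher-z transformed magnitudes:

        z = (atanh|r_exp| - atanh|r_out|) / sqrt(1/(n_exp-3) + 1/(n_out-3)).

    ``direction_ok`` is True when the instrument explains more variance in
    the exposure than in the outcome — the orientation required for the MR
    estimate to be causally interpretable.
    """
    if n_exp <= 3 or n_out <= 3:
        raise ValueError("both sample sizes must exceed 3")
    for rec, label in ((pair.exposure, "exposure"), (pair.outcome, "outcome")):
        if not (np.isfinite(rec.beta) and rec.se > 0):
            raise ValueError(f"{pair.variant_id}: {label} effect/SE unusable")
    r_exp = _r_from_t(pair.exposure.beta, pair.exposure.se, n_exp)
    r_out = _r_from_t(pair.outcome.beta, pair.outcome.se, n_out)
    denom = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (math.atanh(abs(r_exp)) - math.atanh(abs(r_out))) / denom
    p = 2.0 * stats.norm.sf(abs(z))
    return SteigerResult(
        r2_exposure=r_exp**2,
        r2_outcome=r_out**2,
        z_statistic=z,
        p=min(p, 1.0),
        direction_ok=abs(r_exp) > abs(r_out),
    )


def find_proxy(
    target: str,
    ld: pd.DataFrame | np.ndarray,
    available: set[str] | list[str],
    variant_ids: Optional[list[str]] = None,
    r2_min: float = 0.8,
) -> Optional[str]:
    """Best proxy for a variant missing from the outcome dataset.

    ``ld`` is either a square correlation DataFrame indexed by variant id, or
    a raw matrix with ``variant_ids`` supplied.  Returns the available
    candidate with maximal r^2 >= ``r2_min`` (ties broken by variant_id), or
    None when no candidate qualifies.  The target itself is never returned.
    """
    if isinstance(ld, pd.DataFrame):
        ids = list(ld.columns)
        R = ld.to_numpy(dtype=float)
    else:
        if variant_ids is None:
            raise ValueError("variant_ids required with a raw LD matrix")
        ids = list(variant_ids)
        R = np.asarray(ld, dtype=float)
    if target not in ids:
        raise KeyError(f"target {target} absent from the LD source")
    ti = ids.index(target)
    r2 = R[ti] ** 2
    avail = set(available)
    candidates = [
        (r2[j], ids[j])
        for j in range(len(ids))
        if ids[j] != target and ids[j] in avail and r2[j] >= r2_min
    ]
    if not candidates:
        return None
    best_r2 = max(c[0] for c in candidates)
    return min(vid for c_r2, vid in candidates if c_r2 == best_r2)
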