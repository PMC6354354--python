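"""GWAS-style summary statistics: the lingua franca between pipeline stages.

Every stage of the pipeline — association testing, fine-mapping, Mendelian
randomization and colocalization — exchanges per-variant association results
in a single tabular format: one row per (variant, trait) pair carrying the
effect allele, the other allele, the effect-allele frequency, the additive
effect estimate with its standard error, the two-sided p-value and the sample
size.  Files are tab-delimited text with ``NA`` for missing values and
1-based positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Canonical column order for summary-statistics tables.
SUMMARY_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "n",
    "trait",
    "info",
]

_VALID_ALLELES = frozenset("ACGT")


@dataclass
class SummaryRecord:
    """One variant's association with one trait.

    Parameters
    ----------
    variant_id : str
        Variant identifier (e.g. an rsID).
    chrom : str
        Chromosome label.
    pos : int
        1-based physical position.
    effect_allele, other_allele : str
        Alleles; ``beta`` is expressed per copy of ``effect_allele``.
    eaf : float
        Effect-allele frequency, in (0, 1).
    beta, se : float
        Additive effect estimate and its standard error (trait units).
        ``NaN`` marks a record whose effect could not be estimated.
    p : float
        Two-sided p-value in (0, 1].
    n : int
        Sample size behind the estimate.
    trait : str
        Trait (phenotype) name.
    info : float, optional
        Imputation quality in [0, 1]; ``None`` when the source omits it.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int
    trait: str = ""
    info: Optional[float] = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect and other allele are identical "
                f"({self.effect_allele})"
            )
        for allele in (self.effect_allele, self.other_allele):
            if not set(allele) <= _VALID_ALLELES:
                raise ValueError(f"{self.variant_id}: invalid allele {allele!r}")
        if not (0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.variant_id}: eaf {self.eaf} outside (0, 1)")
        if not math.isnan(self.beta):
            if not (self.se > 0):
                raise ValueError(f"{self.variant_id}: se must be > 0, got {self.se}")
            if not (0.0 < self.p <= 1.0):
                raise ValueError(f"{self.variant_id}: p {self.p} outside (0, 1]")

    @property
    def maf(self) -> float:
        """Minor-allele frequency, ``min(eaf, 1 - eaf)``."""
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        """True for A/T and C/G pairs, whose strand cannot be inferred."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


def records_to_frame(records: list[SummaryRecord]) -> pd.DataFrame:
    """Convert a list of :class:`SummaryRecord` into a canonical DataFrame."""
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "chrom": str(r.chrom),
                "pos": int(r.pos),
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "p": r.p,
                "n": r.n,
                "trait": r.trait,
                "info": np.nan if r.info is None else r.info,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SummaryRecord]:
    """Convert a canonical DataFrame into :class:`SummaryRecord` objects."""
    out = []
    for row in df.itertuples(index=False):
        info = getattr(row, "info", np.nan)
        out.append(
            SummaryRecord(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                p=float(row.p),
                n=int(row.n),
                trait=str(row.trait),
                info=None if pd.isna(info) else float(info),
            )
        )
    return out


def read_summary(path) -> pd.DataFrame:
    """Read a tab-delimited summary-statistics file.

    The file must carry at least the canonical header columns; extra columns
    (e.g. ``gene``, ``tissue`` annotations) are preserved.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns and c != "info"]
    if missing:
        raise ValueError(f"summary file {path} lacks required columns: {missing}")
    if "info" not in df.columns:
        df["info"] = np.nan
    return df


def write_summary(df: pd.DataFrame, path) -> None:
    """Write a summary-statistics table as tab-delimited text (missing = NA)."""
    cols = SUMMARY_COLUMNS + [c for c in df.columns if c not in SUMMARY_COLUMNS]
    df.loc[:, cols].to_csv(path, sep="\t", index=False, na_rep="NA")
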