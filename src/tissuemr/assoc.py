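"""Phenotype QC, variant filtering and the age/sex-adjusted eQTL-wide scan.

The association stage regresses each phenotype on each variant's additive
dosage with age and sex as covariates (ordinary least squares), after
removing phenotype outliers beyond a fixed number of standard deviations and
dropping poorly imputed or rare variants.  Multiple testing across the full
scan (instruments x traits) is controlled by Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SUMMARY_COLUMNS

logger = logging.getLogger(__name__)

# extreme t statistics underflow the survival function; keep p strictly > 0
_P_FLOOR = float(np.nextafter(0, 1))

__all__ = [
    "QCConfig",
    "clean_phenotypes",
    "filter_variants",
    "run_eqtlwas",
    "bonferroni_threshold",
    "count_signals",
    "manhattan_table",
    "load_example_hits",
]


@dataclass
class QCConfig:
    """Quality-control thresholds for phenotypes and variants.

    ``sd_limit``: phenotype values beyond this many SDs from the mean are set
    missing.  ``info_min``: minimum imputation quality (records without an
    info score pass, but are counted).  ``maf_min``: minor-allele frequency
    must strictly exceed this.  ``log_flags``: traits to log-transform before
    outlier detection.
    """

    sd_limit: float = 4.0
    info_min: float = 0.8
    maf_min: float = 0.01
    log_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sd_limit <= 0:
            raise ValueError("sd_limit must be positive")
        if not (0.0 <= self.info_min <= 1.0 and 0.0 <= self.maf_min <= 1.0):
            raise ValueError("info_min and maf_min must lie in [0, 1]")


def clean_phenotypes(
    values, config: QCConfig, trait: str = ""
) -> tuple[np.ndarray, list[int]]:
    """Remove phenotype outliers beyond ``sd_limit`` SDs from the mean.

    The mean and SD are computed once on the full non-missing sample (after
    log transform when the trait is flagged); flagged values are set to NaN.
    Returns the cleaned vector (on the analysis scale, i.e. log scale for
    flagged traits) and the list of removed indices.  A constant vector
    (SD = 0) is returned unchanged.
    """
    values = np.asarray(values, dtype=float)
    mask = np.isfinite(values)
    if mask.sum() < 10:
        raise ValueError(f"trait {trait!r}: fewer than 10 non-missing values")
    out = values.copy()
    if config.log_flags.get(trait, False):
        if np.any(values[mask] <= 0):
            raise ValueError(f"trait {trait!r}: log transform requires positive values")
        out[mask] = np.log(values[mask])
    mu = np.nanmean(out[mask])
    sd = np.nanstd(out[mask], ddof=1)
    if sd == 0.0:
        return out, []
    lo, hi = mu - config.sd_limit * sd, mu + config.sd_limit * sd
    removed = np.where(mask & ((out < lo) | (out > hi)))[0]
    out[removed] = np.nan
    return out, removed.tolist()


def filter_variants(
    df: pd.DataFrame, config: QCConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the post-imputation variant filters to a summary table.

    Keeps records with imputation info >= ``info_min`` (missing info passes,
    but is logged and counted) and minor-allele frequency strictly above
    ``maf_min``.  Returns the retained table and a counts report.
    """
    config = config or QCConfig()
    n_in = len(df)
    info = df["info"] if "info" in df.columns else pd.Series(np.nan, index=df.index)
    info_missing = info.isna()
    info_pass = info_missing | (info >= config.info_min)
    # round before the strict comparison so eaf = 0.99 lands exactly on the
    # 0.01 boundary instead of a float hair above it
    maf = np.round(np.minimum(df["eaf"], 1.0 - df["eaf"]), 12)
    maf_pass = maf > config.maf_min
    kept = df[info_pass & maf_pass].copy()
    counts = {
        "input": n_in,
        "kept": len(kept),
        "dropped_info": int((~info_pass).sum()),
        "dropped_maf": int((info_pass & ~maf_pass).sum()),
        "missing_info_passed": int((info_missing & maf_pass).sum()),
    }
    if counts["missing_info_passed"]:
        logger.info(
            "%d variants passed the info filter without an info score",
            counts["missing_info_passed"],
        )
    return kept, counts


def _ols_single(y, g, covariates):
    """OLS of y on [1, g, covariates]; returns (beta_g, se_g, p, n) or NaNs."""
    X = np.column_stack([np.ones_like(g), g, covariates])
    n, k = X.shape
    if n <= k:
        return np.nan, np.nan, np.nan, n
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        return np.nan, np.nan, np.nan, n
    resid = y - X @ beta
    df_resid = n - k
    sigma2 = resid @ resid / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = beta[1] / se
    p = max(2.0 * stats.t.sf(abs(t), df_resid), _P_FLOOR)
    return beta[1], se, p, n


def run_eqtlwas(
    dosages: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray,
    variant_meta: pd.DataFrame,
    trait: str = "trait",
) -> pd.DataFrame:
    """Per-variant OLS of phenotype on dosage, adjusted for age and sex.

    ``covariates`` is the (n, 2) age/sex block.  Rows with a missing
    phenotype or covariate are dropped listwise; a variant whose design is
    rank deficient (e.g. monomorphic) yields a record with missing beta/SE
    and a logged reason.  p-values come from the t distribution with the
    residual degrees of freedom.

    When no values are missing, all variants share one covariate projection
    and the scan is computed by the Frisch-Waugh-Lovell residualization,
    which is algebraically identical to per-variant OLS.
    """
    dosages = np.asarray(dosages, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    n, m = dosages.shape
    if phenotype.shape[0] != n or covariates.shape[0] != n:
        raise ValueError("row counts of dosages, phenotype and covariates differ")
    if len(variant_meta) != m:
        raise ValueError("variant_meta rows must match dosage columns")

    complete = np.isfinite(phenotype) & np.all(np.isfinite(covariates), axis=1)
    y = phenotype[complete]
    C = covariates[complete]
    G = dosages[complete]
    if np.unique(y).size < 2:
        raise ValueError("phenotype is constant after QC")

    n_used = y.shape[0]
    k = 4  # intercept + dosage + age + sex
    betas = np.full(m, np.nan)
    ses = np.full(m, np.nan)
    ps = np.full(m, np.nan)
    ns = np.full(m, n_used, dtype=int)

    g_missing = ~np.all(np.isfinite(G), axis=0)
    # fast path: residualize y and every complete-dosage variant on [1, C]
    Z = np.column_stack([np.ones(n_used), C])
    coef_y, *_ = np.linalg.lstsq(Z, y, rcond=None)
    ry = y - Z @ coef_y
    cols = np.where(~g_missing)[0]
    if cols.size:
        Gc = G[:, cols]
        coef_g, *_ = np.linalg.lstsq(Z, Gc, rcond=None)
        rg = Gc - Z @ coef_g
        sxx = np.einsum("ij,ij->j", rg, rg)
        ok = sxx > 0
        df_resid = n_used - k
        with np.errstate(divide="ignore", invalid="ignore"):
            b = np.einsum("ij,i->j", rg, ry) / sxx
            rss = ry @ ry - b * b * sxx
            sigma2 = rss / df_resid
            se = np.sqrt(sigma2 / sxx)
            t = b / se
        p = np.maximum(2.0 * stats.t.sf(np.abs(t), df_resid), _P_FLOOR)
        betas[cols[ok]] = b[ok]
        ses[cols[ok]] = se[ok]
        ps[cols[ok]] = p[ok]
        for j in cols[~ok]:
            logger.warning("variant %s: monomorphic, effect not estimable",
                           variant_meta["variant_id"].iloc[j])
    for j in np.where(g_missing)[0]:
        rows = np.isfinite(G[:, j])
        betas[j], ses[j], ps[j], ns[j] = _ols_single(y[rows], G[rows, j], C[rows])
        if not np.isfinite(betas[j]):
            logger.warning("variant %s: rank-deficient design, effect not estimable",
                           variant_meta["variant_id"].iloc[j])

    with np.errstate(invalid="ignore"):
        dose_mean = np.nanmean(np.where(np.isfinite(G), G, np.nan), axis=0)
    out = pd.DataFrame(
        {
            "variant_id": variant_meta["variant_id"].to_numpy(),
            "chrom": variant_meta["chrom"].astype(str).to_numpy(),
            "pos": variant_meta["pos"].to_numpy(),
            "effect_allele": variant_meta["effect_allele"].to_numpy(),
            "other_allele": variant_meta["other_allele"].to_numpy(),
            "eaf": dose_mean / 2.0,
            "beta": betas,
            "se": ses,
            "p": ps,
            "n": ns,
            "trait": trait,
            "info": variant_meta["info"].to_numpy()
            if "info" in variant_meta.columns
            else np.nan,
        },
        columns=SUMMARY_COLUMNS,
    )
    return out


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Bonferroni-corrected p-value threshold, alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_tests


def count_signals(df: pd.DataFrame, threshold: float) -> tuple[int, int]:
    """Count association signals below ``threshold`` and their distinct lead SNPs.

    A signal is a (variant, trait) record with p < threshold; the second
    count collapses signals sharing a tag variant, i.e. distinct loci.
    """
    hits = df[df["p"] < threshold]
    return len(hits), hits["variant_id"].nunique()


def manhattan_table(df: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Plot-ready table: chrom, pos, -log10 p, trait and threshold flag."""
    ok = df["p"].notna()
    out = pd.DataFrame(
        {
            "chrom": df.loc[ok, "chrom"],
            "pos": df.loc[ok, "pos"],
            "neg_log10_p": -np.log10(df.loc[ok, "p"]),
            "trait": df.loc[ok, "trait"],
            "above_threshold": df.loc[ok, "p"] < threshold,
        }
    )
    return out.reset_index(drop=True)


def load_example_hits() -> pd.DataFrame:
    """Bundled table of 11 published eQTL-trait association signals.

    Eleven associations between cis-eQTLs and cardiovascular traits across
    eight loci, used as a worked example and test fixture.  The ``p`` column
    holds usable p-values; ``p_as_printed`` preserves each value exactly as
    printed at source (one entry there carries an obvious lost-minus-sign
    typo in its exponent, corrected in ``p``).
    """
    ref = resources.files("tissuemr.data").joinpath("cardio_eqtlwas_hits.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
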