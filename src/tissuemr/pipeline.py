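"""Orchestration of the discovery workflow and the genome-wide scan.

Discovery mode runs, in order: phenotype QC, the age/sex-adjusted eQTL-wide
association scan per trait, a Bonferroni gate at alpha / (instruments x
traits), fine-mapping of the 1-Mb region around each gated lead variant,
single-instrument Mendelian randomization per gene x tissue x trait with the
Steiger directionality test, and multiple-trait colocalization for every
gene-CpG combination in the region.

Genome-wide mode takes lead cis-eQTLs per gene x tissue from an expression
catalog, looks each up (or a proxy at r^2 >= 0.8) in every GWAS, applies a
Bonferroni gate at the total lookup count, and runs MR plus colocalization
on the survivors; fine-mapping is deliberately skipped in this mode because
it would require individual-level LD the consortium data cannot provide.
A locus whose branch fails is logged and reported, never fatal to the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.special import logit

from . import __version__
from .assoc import (
    QCConfig,
    bonferroni_threshold,
    clean_phenotypes,
    count_signals,
    run_eqtlwas,
)
from .finemap import enumerate_posteriors, ld_from_dosages, region_from_summary
from .moloc import TraitAssoc, map_cpg_to_genes, moloc_region
from .mr import (
    HarmonizationError,
    find_proxy,
    harmonize,
    select_instruments,
    steiger_test,
    wald_ratio,
)
from .simulate import Cohort, variant_metadata
from .sumstats import frame_to_records

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_discovery", "run_genomewide",
           "write_report"]


@dataclass
class PipelineConfig:
    """All pipeline thresholds, with the analysis' canonical defaults."""

    alpha: float = 0.05
    instrument_p: float = 1e-4
    ppa_threshold: float = 0.8
    r2_proxy: float = 0.8
    window: int = 1_000_000
    min_snps: int = 50
    maf_moloc: float = 0.05
    info_min: float = 0.8
    maf_assoc: float = 0.01
    sd_limit: float = 4.0
    k_max: int = 5
    priors: tuple[float, float, float] = (1e-4, 1e-6, 1e-7)
    finemap_prior_sd: float = 0.05
    abf_prior_sd: float = 0.15
    tissues: tuple[str, ...] = ("cohort",)
    traits: tuple[str, ...] = ("trait",)
    log_flags: dict[str, bool] = field(default_factory=dict)
    seed: int = 0
    run_finemap: bool = True
    run_mr: bool = True
    run_moloc: bool = True
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, lo, hi in [
            ("alpha", 0.0, 1.0),
            ("instrument_p", 0.0, 1.0),
            ("ppa_threshold", 0.0, 1.0),
            ("r2_proxy", 0.0, 1.0),
            ("maf_moloc", 0.0, 0.5),
            ("info_min", 0.0, 1.0),
            ("maf_assoc", 0.0, 0.5),
        ]:
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v} outside ({lo}, {hi}]")
        if self.sd_limit <= 0 or self.k_max < 1 or self.window < 1:
            raise ValueError("sd_limit, k_max and window must be positive")
        if len(self.priors) != 3 or any(p <= 0 for p in self.priors):
            raise ValueError("priors must be three positive probabilities")

    @property
    def qc(self) -> QCConfig:
        return QCConfig(
            sd_limit=self.sd_limit,
            info_min=self.info_min,
            maf_min=self.maf_assoc,
            log_flags=dict(self.log_flags),
        )

    def fingerprint(self) -> str:
        payload = json.dumps(
            {"config": _jsonable(asdict(self)), "version": __version__},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for key in ("priors", "tissues", "traits"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    mode: str
    scheduled_tests: int
    threshold: float
    n_signals: int
    n_unique_lead_snps: int
    mr_scheduled: int = 0
    mr_threshold: float = float("nan")
    mr_findings: int = 0
    skipped: list[dict] = field(default_factory=list)
    stage_notes: dict[str, str] = field(default_factory=dict)
    fingerprint: str = ""

    def to_dict(self) -> dict:
        return _jsonable(asdict(self))


# ---------------------------------------------------------------------------
# Discovery mode
# ---------------------------------------------------------------------------

def _molecular_summaries(cohort: Cohort, meta: pd.DataFrame, tissue: str):
    """eQTL and mQTL summary scans computed from the cohort's molecular data."""
    eqtl_frames = []
    for k, gene in enumerate(cohort.gene_names):
        df = run_eqtlwas(
            cohort.dosages, cohort.expression[:, k], cohort.covariates, meta,
            trait=f"expr_{gene}",
        )
        df["gene"] = gene
        df["tissue"] = tissue
        eqtl_frames.append(df)
    mqtl_frames = []
    for k, cpg in enumerate(cohort.cpg_names):
        df = run_eqtlwas(
            cohort.dosages, logit(cohort.methylation[:, k]), cohort.covariates,
            meta, trait=f"meth_{cpg}",
        )
        df["cpg"] = cpg
        mqtl_frames.append(df)
    eqtl = pd.concat(eqtl_frames, ignore_index=True) if eqtl_frames else pd.DataFrame()
    mqtl = pd.concat(mqtl_frames, ignore_index=True) if mqtl_frames else pd.DataFrame()
    return eqtl, mqtl


def run_discovery(
    config: PipelineConfig,
    cohort: Cohort,
    tissue: Optional[str] = None,
) -> tuple[RunReport, dict]:
    """Full discovery workflow on one (synthetic) cohort.

    Gene TSSs and CpG positions are taken at each feature's causal variant,
    so every simulated feature is cis to its driver.  Returns the run report
    and a dict of stage outputs (summary tables, fine-mapping results, MR
    rows, colocalization rows).
    """
    if not config.traits:
        raise ValueError("trait list is empty")
    spec = cohort.truth
    if not spec.eqtl_effects:
        raise ValueError("instrument list is empty: cohort has no eQTL genes")
    tissue = tissue or config.tissues[0]
    meta = variant_metadata(spec)
    meta["info"] = 1.0
    positions = spec.positions()
    tss = {
        g: int(positions[eff.snp_index]) for g, eff in spec.eqtl_effects.items()
    }
    cpg_pos = {
        c: int(positions[eff.snp_index]) for c, eff in spec.mqtl_effects.items()
    }

    outputs: dict = {}
    report = RunReport(
        mode="discovery",
        scheduled_tests=spec.n_snps * len(config.traits),
        threshold=bonferroni_threshold(spec.n_snps * len(config.traits), config.alpha),
        n_signals=0,
        n_unique_lead_snps=0,
        fingerprint=config.fingerprint(),
    )

    # QC + trait scans
    trait_scans = []
    for trait in config.traits:
        values = cohort.traits[trait]
        cleaned, removed = clean_phenotypes(values, config.qc, trait)
        if removed:
            report.stage_notes[f"qc_{trait}"] = f"{len(removed)} outliers removed"
        scan = run_eqtlwas(cohort.dosages, cleaned, cohort.covariates, meta, trait)
        trait_scans.append(scan)
    gwas = pd.concat(trait_scans, ignore_index=True)
    outputs["gwas"] = gwas

    n_sig, n_lead = count_signals(gwas, report.threshold)
    report.n_signals, report.n_unique_lead_snps = n_sig, n_lead
    hits = gwas[gwas["p"] < report.threshold]
    leads = (
        hits.sort_values(["trait", "p", "variant_id"])
        .groupby("trait", as_index=False)
        .first()
    )
    outputs["leads"] = leads

    # fine-mapping around each gated lead
    finemap_results = {}
    if config.run_finemap:
        for row in leads.itertuples(index=False):
            in_window = gwas[
                (gwas["trait"] == row.trait)
                & ((gwas["pos"] - row.pos).abs() <= config.window)
            ].reset_index(drop=True)
            cols = [list(meta["variant_id"]).index(v) for v in in_window["variant_id"]]
            try:
                R = ld_from_dosages(cohort.dosages[:, cols])
                region = region_from_summary(
                    in_window, R, center=row.variant_id, window=config.window
                )
                finemap_results[(row.trait, row.variant_id)] = enumerate_posteriors(
                    region, k_max=config.k_max, prior_sd=config.finemap_prior_sd
                )
            except (ValueError, np.linalg.LinAlgError) as err:
                report.skipped.append(
                    {"stage": "finemap", "locus": row.variant_id, "reason": str(err)}
                )
    outputs["finemap"] = finemap_results

    # molecular scans + MR
    eqtl, mqtl = _molecular_summaries(cohort, meta, tissue)
    outputs["eqtl"], outputs["mqtl"] = eqtl, mqtl
    mr_rows = []
    if config.run_mr and not eqtl.empty:
        instruments = select_instruments(
            eqtl, tss, p_threshold=config.instrument_p, cis_window=config.window
        )
        report.mr_scheduled = max(len(instruments), 1) * len(config.traits) \
            if len(instruments) else 0
        if len(instruments):
            report.mr_threshold = bonferroni_threshold(
                len(instruments) * len(config.traits), config.alpha
            )
        gwas_idx = gwas.set_index(["trait", "variant_id"])
        for inst in instruments.itertuples(index=False):
            exp_rec = frame_to_records(
                pd.DataFrame([inst._asdict()]).drop(columns=["gene", "tissue"])
            )[0]
            for trait in config.traits:
                try:
                    out_row = gwas_idx.loc[(trait, inst.variant_id)]
                except KeyError:
                    report.skipped.append(
                        {"stage": "mr", "locus": inst.variant_id,
                         "reason": f"variant absent from {trait} scan"}
                    )
                    continue
                out_rec = frame_to_records(
                    out_row.to_frame().T.reset_index(names=["trait", "variant_id"])
                )[0]
                try:
                    pair = harmonize(exp_rec, out_rec)
                    if pair.palindromic_status == "dropped":
                        report.skipped.append(
                            {"stage": "mr", "locus": inst.variant_id,
                             "reason": "palindromic, frequencies uninformative"}
                        )
                        continue
                    wald = wald_ratio(pair)
                    steiger = steiger_test(pair, n_exp=exp_rec.n, n_out=out_rec.n)
                except (HarmonizationError, ZeroDivisionError, ValueError) as err:
                    report.skipped.append(
                        {"stage": "mr", "locus": inst.variant_id, "reason": str(err)}
                    )
                    continue
                mr_rows.append(
                    {
                        "exposure": inst.gene,
                        "tissue": inst.tissue,
                        "outcome": trait,
                        "variant_id": inst.variant_id,
                        "beta_mr": wald.beta_mr,
                        "se_mr": wald.se_mr,
                        "p": wald.p,
                        "steiger_p": steiger.p,
                        "direction_ok": steiger.direction_ok,
                        "proxy_used": "",
                    }
                )
    mr_table = pd.DataFrame(mr_rows)
    if len(mr_table):
        report.mr_findings = int((mr_table["p"] < report.mr_threshold).sum())
    outputs["mr"] = mr_table

    # moloc per gene-CpG combination around each lead
    moloc_rows = []
    if config.run_moloc and not eqtl.empty and not mqtl.empty:
        for row in leads.itertuples(index=False):
            combos = map_cpg_to_genes(row.pos, cpg_pos, tss, window=config.window)
            gwas_region = gwas[gwas["trait"] == row.trait]
            for gene, cpg in combos:
                res = moloc_region(
                    TraitAssoc("G", gwas_region, name=row.trait),
                    TraitAssoc("E", eqtl[eqtl["gene"] == gene], name=gene,
                               prior_sd=config.abf_prior_sd),
                    TraitAssoc("M", mqtl[mqtl["cpg"] == cpg], name=cpg,
                               prior_sd=config.abf_prior_sd),
                    priors=config.priors,
                    min_snps=config.min_snps,
                    maf_min=config.maf_moloc,
                    ppa_threshold=config.ppa_threshold,
                )
                if res.skipped:
                    report.skipped.append(
                        {"stage": "moloc", "locus": f"{gene}:{cpg}",
                         "reason": res.reason}
                    )
                    continue
                moloc_rows.append(
                    {
                        "region": row.variant_id,
                        "gene": gene,
                        "cpg": cpg,
                        "tissue": tissue,
                        "n_snps": res.n_snps_used,
                        **{f"ppa_{k}": v for k, v in res.ppa.items()},
                        "summed_ge": res.summed_ge,
                        "gem": res.gem,
                        "decision_ge": res.decision_ge,
                        "decision_gem": res.decision_gem,
                    }
                )
    outputs["moloc"] = pd.DataFrame(moloc_rows)
    return report, outputs


# ---------------------------------------------------------------------------
# Genome-wide mode
# ---------------------------------------------------------------------------

def run_genomewide(
    config: PipelineConfig,
    eqtl_catalog: pd.DataFrame,
    gwas: dict[str, pd.DataFrame],
    mqtl: Optional[pd.DataFrame] = None,
    ld: Optional[pd.DataFrame] = None,
) -> tuple[RunReport, pd.DataFrame]:
    """Genome-wide scan from summary data alone (no fine-mapping).

    ``eqtl_catalog`` holds lead cis-eQTLs with ``gene`` and ``tissue``
    columns (one row per gene x tissue).  Each lead is looked up in every
    GWAS table, falling back to a proxy at r^2 >= ``r2_proxy`` from ``ld``
    when absent; the Bonferroni gate uses the total number of lookups.
    Survivors get MR (with Steiger) and, when ``mqtl`` is given,
    colocalization; a reported finding needs both the gate and a summed G-E
    PPA >= the threshold.
    """
    for col in ("gene", "tissue"):
        if col not in eqtl_catalog.columns:
            raise ValueError(f"eqtl_catalog lacks the {col!r} column")
    lookups = 0
    rows = []
    report = RunReport(
        mode="genomewide", scheduled_tests=0, threshold=float("nan"),
        n_signals=0, n_unique_lead_snps=0, fingerprint=config.fingerprint(),
    )
    gwas_idx = {t: df.set_index("variant_id") for t, df in gwas.items()}
    for inst in eqtl_catalog.itertuples(index=False):
        for trait, out_df in gwas_idx.items():
            lookups += 1
            vid, proxy_used = inst.variant_id, ""
            if vid not in out_df.index:
                if ld is None:
                    report.skipped.append(
                        {"stage": "lookup", "locus": vid,
                         "reason": f"absent from {trait}, no LD source"}
                    )
                    continue
                proxy = find_proxy(
                    vid, ld, available=set(out_df.index), r2_min=config.r2_proxy
                )
                if proxy is None:
                    report.skipped.append(
                        {"stage": "lookup", "locus": vid,
                         "reason": f"absent from {trait}, no proxy at "
                                   f"r2>={config.r2_proxy}"}
                    )
                    continue
                vid, proxy_used = proxy, proxy
            rows.append(
                {"gene": inst.gene, "tissue": inst.tissue, "trait": trait,
                 "variant_id": vid, "proxy_used": proxy_used,
                 "outcome_p": float(out_df.at[vid, "p"])}
            )
    report.scheduled_tests = lookups
    report.threshold = bonferroni_threshold(max(lookups, 1), config.alpha)
    lookup_table = pd.DataFrame(rows)
    if lookup_table.empty:
        return report, lookup_table

    survivors = lookup_table[lookup_table["outcome_p"] < report.threshold]
    report.n_signals = len(survivors)
    report.n_unique_lead_snps = survivors["variant_id"].nunique()

    results = []
    eqtl_idx = eqtl_catalog.set_index(["gene", "tissue"])
    for row in survivors.itertuples(index=False):
        try:
            exp_df = eqtl_idx.loc[[(row.gene, row.tissue)]].reset_index()
            # MR always instruments the original lead; the proxy only locates
            # the outcome record
            exp_rec = frame_to_records(exp_df.drop(columns=["gene", "tissue"]))[0]
            out_df = gwas_idx[row.trait]
            out_rec = frame_to_records(
                out_df.loc[[row.variant_id]].reset_index()
            )[0]
            pair = harmonize(exp_rec, out_rec)
            if pair.palindromic_status == "dropped":
                raise HarmonizationError("palindromic, frequencies uninformative")
            wald = wald_ratio(pair)
            steiger = steiger_test(pair, n_exp=exp_rec.n, n_out=out_rec.n)
        except (HarmonizationError, ZeroDivisionError, ValueError, KeyError) as err:
            report.skipped.append(
                {"stage": "mr", "locus": row.variant_id, "reason": str(err)}
            )
            continue
        rec = {
            "gene": row.gene, "tissue": row.tissue, "trait": row.trait,
            "variant_id": row.variant_id, "proxy_used": row.proxy_used,
            "beta_mr": wald.beta_mr, "se_mr": wald.se_mr, "p": wald.p,
            "steiger_p": steiger.p, "direction_ok": steiger.direction_ok,
            "summed_ge": float("nan"), "gem": float("nan"), "reported": False,
        }
        if mqtl is not None:
            gwas_region = gwas[row.trait]
            eqtl_region = _region_records(eqtl_catalog, row.gene, row.tissue)
            res = moloc_region(
                TraitAssoc("G", gwas_region, name=row.trait),
                TraitAssoc("E", eqtl_region, name=row.gene,
                           prior_sd=config.abf_prior_sd),
                TraitAssoc("M", mqtl, name="methylation",
                           prior_sd=config.abf_prior_sd),
                priors=config.priors, min_snps=config.min_snps,
                maf_min=config.maf_moloc, ppa_threshold=config.ppa_threshold,
            )
            if res.skipped:
                report.skipped.append(
                    {"stage": "moloc", "locus": row.variant_id,
                     "reason": res.reason}
                )
            else:
                rec["summed_ge"], rec["gem"] = res.summed_ge, res.gem
                rec["reported"] = bool(res.decision_ge)
        results.append(rec)
    out = pd.DataFrame(results)
    if len(out):
        report.mr_findings = int(out["reported"].sum())
    return report, out


def _region_records(catalog: pd.DataFrame, gene: str, tissue: str) -> pd.DataFrame:
    """All catalog records for one gene x tissue (regional scan, if present)."""
    sub = catalog[(catalog["gene"] == gene) & (catalog["tissue"] == tissue)]
    return sub.drop(columns=["gene", "tissue"])


def write_report(report: RunReport, prefix: str) -> dict[str, str]:
    """Write the run report as JSON (machine) and aligned text (human)."""
    paths = {"json": f"{prefix}.report.json", "txt": f"{prefix}.report.txt"}
    with open(paths["json"], "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    d = report.to_dict()
    lines = [f"tissuemr run report ({d['mode']} mode)"]
    lines.append(f"  config fingerprint : {d['fingerprint']}")
    lines.append(f"  scheduled tests    : {d['scheduled_tests']}")
    lines.append(f"  threshold          : {_fmt_threshold(d['threshold'])}")
    lines.append(f"  signals            : {d['n_signals']} "
                 f"({d['n_unique_lead_snps']} unique lead variants)")
    if d["mr_scheduled"]:
        lines.append(f"  MR tests scheduled : {d['mr_scheduled']} "
                     f"(threshold {_fmt_threshold(d['mr_threshold'])})")
        lines.append(f"  MR findings        : {d['mr_findings']}")
    for item in d["skipped"]:
        lines.append(f"  skipped [{item['stage']}] {item['locus']}: {item['reason']}")
    with open(paths["txt"], "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return paths


def _fmt_threshold(x: float) -> str:
    """Two-significant-figure display (round half to even); storage stays exact."""
    if not np.isfinite(x):
        return "NA"
    return np.format_float_scientific(x, precision=1, unique=False)
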