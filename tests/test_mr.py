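"""Mendelian randomization: instruments, harmonization, Wald, Steiger, proxies."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from tissuemr.assoc import run_eqtlwas
from tissuemr.mr import (
    HarmonizationError,
    HarmonizedPair,
    find_proxy,
    harmonize,
    select_instruments,
    steiger_test,
    wald_ratio,
)
from tissuemr.simulate import simulate_cohort, variant_metadata
from tissuemr.sumstats import SummaryRecord
from conftest import make_scenario1


def record(vid="rs1", ea="A", oa="G", eaf=0.3, beta=0.5, se=0.05, p=1e-8,
           n=5000, trait="expr", pos=100):
    return SummaryRecord(vid, "1", pos, ea, oa, eaf, beta, se, p, n, trait)


class TestSelectInstruments:
    def frame(self, rows):
        base = dict(chrom="1", effect_allele="A", other_allele="G", eaf=0.3,
                    beta=0.3, se=0.05, n=500, info=1.0)
        return pd.DataFrame([{**base, **r} for r in rows])

    def test_window_and_threshold_rules(self):
        tss = {"g": 1_000_000}
        df = self.frame([
            # exactly 1 Mb away: inclusive, kept
            dict(variant_id="a", pos=2_000_000, p=1e-6, trait="e", gene="g",
                 tissue="liver"),
            # 1 bp beyond: excluded
            dict(variant_id="b", pos=2_000_001, p=1e-10, trait="e", gene="g",
                 tissue="liver"),
            # p exactly at threshold: excluded (strict <)
            dict(variant_id="c", pos=1_000_500, p=1e-4, trait="e", gene="g",
                 tissue="liver"),
        ])
        lead = select_instruments(df, tss)
        assert list(lead["variant_id"]) == ["a"]

    def test_smallest_p_wins_ties_by_id(self):
        tss = {"g": 1_000_000}
        df = self.frame([
            dict(variant_id="x", pos=1_000_100, p=1e-6, trait="e", gene="g",
                 tissue="liver"),
            dict(variant_id="y", pos=1_000_200, p=1e-8, trait="e", gene="g",
                 tissue="liver"),
            dict(variant_id="z", pos=1_000_300, p=1e-8, trait="e", gene="g",
                 tissue="pancreas"),
            dict(variant_id="a", pos=1_000_400, p=1e-8, trait="e", gene="g",
                 tissue="pancreas"),
        ])
        lead = select_instruments(df, tss).set_index("tissue")
        assert lead.at["liver", "variant_id"] == "y"
        assert lead.at["pancreas", "variant_id"] == "a"  # tie -> lexicographic

    def test_no_passing_records_empty(self):
        df = self.frame([
            dict(variant_id="a", pos=1_000_100, p=0.5, trait="e", gene="g",
                 tissue="liver"),
        ])
        assert select_instruments(df, {"g": 1_000_000}).empty


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp = record(beta=0.2)
        out = record(ea="G", oa="A", eaf=0.7, beta=-0.1, trait="trait")
        pair = harmonize(exp, out)
        assert pair.outcome.beta == pytest.approx(0.1)
        assert pair.outcome.eaf == pytest.approx(0.3)
        assert pair.flips_applied
        assert pair.palindromic_status == "not"

    def test_strand_complement_resolved(self):
        exp = record(ea="A", oa="G", beta=0.2)
        out = record(ea="T", oa="C", beta=0.15, trait="trait")
        pair = harmonize(exp, out)
        assert pair.outcome.beta == pytest.approx(0.15)
        assert pair.aligned_effect_allele == "A"

    def test_palindromic_ambiguous_dropped(self):
        exp = record(ea="A", oa="T", eaf=0.5)
        out = record(ea="A", oa="T", eaf=0.49, trait="trait")
        assert harmonize(exp, out).palindromic_status == "dropped"

    def test_palindromic_resolved_by_frequency(self):
        exp = record(ea="A", oa="T", eaf=0.2, beta=0.2)
        out = record(ea="T", oa="A", eaf=0.8, beta=-0.1, trait="trait")
        pair = harmonize(exp, out)
        assert pair.palindromic_status == "resolved"
        assert pair.outcome.beta == pytest.approx(0.1)

    def test_irreconcilable_alleles_error(self):
        with pytest.raises(HarmonizationError):
            harmonize(record(ea="A", oa="G"), record(ea="A", oa="C", trait="t"))


class TestWaldRatio:
    def test_arithmetic(self):
        pair = harmonize(
            record(beta=0.5, se=0.05),
            record(beta=0.25, se=0.05, trait="trait"),
        )
        res = wald_ratio(pair)
        assert res.beta_mr == pytest.approx(0.5)
        assert res.se_mr == pytest.approx(0.1)
        z = 0.5 / 0.1
        assert res.p == pytest.approx(2 * stats.norm.sf(z), rel=1e-10)

    def test_zero_outcome_effect(self):
        pair = harmonize(record(beta=0.5), record(beta=0.0, se=0.05, p=1.0,
                                                  trait="trait"))
        assert wald_ratio(pair).beta_mr == 0.0

    def test_zero_exposure_effect_raises(self):
        pair = HarmonizedPair(
            variant_id="rs1",
            exposure=record(beta=0.0, p=1.0),
            outcome=record(beta=0.1, trait="trait"),
            aligned_effect_allele="A",
            flips_applied=False,
            palindromic_status="not",
        )
        with pytest.raises(ZeroDivisionError):
            wald_ratio(pair)

    def test_second_order_se_larger(self):
        pair = harmonize(record(beta=0.5, se=0.1),
                         record(beta=0.25, se=0.05, trait="trait"))
        assert wald_ratio(pair, second_order=True).se_mr > wald_ratio(pair).se_mr

    @settings(deadline=None, derandomize=True)
    @given(k=st.floats(0.1, 10))
    def test_equivariance_in_exposure_scale(self, k):
        base_exp = record(beta=0.5, se=0.05)
        scaled_exp = record(beta=0.5 * k, se=0.05 * k)
        out = record(beta=0.25, se=0.05, trait="trait")
        r1 = wald_ratio(harmonize(base_exp, out))
        r2 = wald_ratio(harmonize(scaled_exp, out))
        assert r2.beta_mr == pytest.approx(r1.beta_mr / k, rel=1e-12)
        assert r2.se_mr == pytest.approx(r1.se_mr / k, rel=1e-12)

    def test_recovers_mediation_effect(self):
        """Mean Wald estimate over replicates matches the generative
        expression->trait coefficient (0.3)."""
        estimates = []
        for seed in range(40):
            spec = make_scenario1(n=5000, n_snps=3, causal=1, seed=300 + seed,
                                  with_cpg=False)
            cohort = simulate_cohort(spec)
            meta = variant_metadata(spec)
            exp_scan = run_eqtlwas(cohort.dosages, cohort.expression[:, 0],
                                   cohort.covariates, meta, "expr")
            out_scan = run_eqtlwas(cohort.dosages, cohort.traits["trait"],
                                   cohort.covariates, meta, "trait")
            pair = harmonize(
                SummaryRecord(**exp_scan.iloc[1].drop("info").to_dict()),
                SummaryRecord(**out_scan.iloc[1].drop("info").to_dict()),
            )
            estimates.append(wald_ratio(pair).beta_mr)
        mc_se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 0.3) < 3 * mc_se


class TestSteiger:
    def test_equal_correlations_null(self):
        pair = harmonize(record(beta=0.3, se=0.05, n=5000),
                         record(beta=0.3, se=0.05, n=5000, trait="trait"))
        res = steiger_test(pair, 5000, 5000)
        assert res.z_statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry_under_swap(self):
        exp = record(beta=0.4, se=0.05, n=5000)
        out = record(beta=0.1, se=0.05, n=50000, trait="trait")
        fwd = steiger_test(harmonize(exp, out), 5000, 50000)
        rev = steiger_test(
            harmonize(out, exp.__class__(**{**exp.__dict__})), 50000, 5000
        )
        assert fwd.direction_ok != rev.direction_ok
        assert abs(fwd.z_statistic) == pytest.approx(abs(rev.z_statistic))

    def test_strong_exposure_weak_outcome(self):
        """r_exp=0.10 at n=5000 vs r_out=0.01 at n=50000: clear verdict.

        Effect sizes are constructed so the regression t statistics imply
        exactly those correlations; the Fisher-z formula gives p << 1e-6.
        """
        def rec_for_r(r, n, trait):
            t = r * math.sqrt((n - 2) / (1 - r * r))
            return record(beta=t * 0.01, se=0.01, n=n, trait=trait,
                          p=2 * stats.t.sf(abs(t), n - 2))

        pair = harmonize(rec_for_r(0.10, 5000, "expr"),
                         rec_for_r(0.01, 50000, "trait"))
        res = steiger_test(pair, 5000, 50000)
        assert res.direction_ok
        assert res.p < 1e-6
        # cross-check z against the direct formula
        z_expected = (math.atanh(0.10) - math.atanh(0.01)) / math.sqrt(
            1 / 4997 + 1 / 49997
        )
        assert res.z_statistic == pytest.approx(z_expected, rel=1e-3)

    def test_mediated_cohorts_oriented_correctly(self):
        """Under single-gene mediation the exposure r^2 dominates."""
        ok = 0
        n_rep = 20
        for seed in range(n_rep):
            spec = make_scenario1(n=5000, n_snps=3, causal=1, seed=600 + seed,
                                  with_cpg=False)
            cohort = simulate_cohort(spec)
            meta = variant_metadata(spec)
            exp_scan = run_eqtlwas(cohort.dosages, cohort.expression[:, 0],
                                   cohort.covariates, meta, "expr")
            out_scan = run_eqtlwas(cohort.dosages, cohort.traits["trait"],
                                   cohort.covariates, meta, "trait")
            pair = harmonize(
                SummaryRecord(**exp_scan.iloc[1].drop("info").to_dict()),
                SummaryRecord(**out_scan.iloc[1].drop("info").to_dict()),
            )
            ok += steiger_test(pair, 5000, 5000).direction_ok
        assert ok >= 0.95 * n_rep


class TestFindProxy:
    def ld(self):
        ids = ["t", "p1", "p2", "p3"]
        R = np.array([
            [1.0, 1.0, 0.975, 0.6],
            [1.0, 1.0, 0.975, 0.6],
            [0.975, 0.975, 1.0, 0.6],
            [0.6, 0.6, 0.6, 1.0],
        ])
        return pd.DataFrame(R, index=ids, columns=ids)

    def test_perfect_duplicate_wins(self):
        assert find_proxy("t", self.ld(), {"p1", "p2", "p3"}) == "p1"

    def test_best_below_threshold_none(self):
        assert find_proxy("t", self.ld(), {"p3"}) is None  # r2 = 0.36

    def test_max_r2_selected(self):
        assert find_proxy("t", self.ld(), {"p2", "p3"}) == "p2"

    def test_absent_target_raises(self):
        with pytest.raises(KeyError):
            find_proxy("absent", self.ld(), {"p1"})
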