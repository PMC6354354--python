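"""Synthetic-cohort generator: moments, LD, scenarios and derived phenotypes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tissuemr.simulate import (
    Cohort,
    EqtlEffect,
    MqtlEffect,
    ScenarioSpec,
    compute_bmi,
    compute_friedewald_ldl,
    dosage_correlation,
    latent_rho_for_r2,
    simulate_cohort,
    simulate_genotypes,
    variant_metadata,
)
from conftest import make_scenario1


class TestGenotypes:
    def test_values_and_determinism(self):
        G1 = simulate_genotypes(200, np.full(6, 0.2), 0.5, seed=42)
        G2 = simulate_genotypes(200, np.full(6, 0.2), 0.5, seed=42)
        assert set(np.unique(G1)) <= {0, 1, 2}
        np.testing.assert_array_equal(G1, G2)
        G3 = simulate_genotypes(200, np.full(6, 0.2), 0.5, seed=43)
        assert not np.array_equal(G1, G3)

    def test_independence_when_rho_zero(self):
        G = simulate_genotypes(5000, np.full(8, 0.3), 0.0, seed=1)
        R = np.corrcoef(G, rowvar=False)
        off = np.abs(R[~np.eye(8, dtype=bool)])
        assert off.mean() < 0.05

    def test_empirical_maf(self):
        G = simulate_genotypes(10000, np.full(5, 0.3), 0.2, seed=2)
        emp = G.mean(axis=0) / 2.0
        assert np.all(np.abs(emp - 0.3) < 0.02)

    def test_ld_decay_matches_closed_form(self):
        rho = 0.6
        G = simulate_genotypes(50000, np.full(4, 0.25), rho, seed=3)
        R = np.corrcoef(G, rowvar=False)
        for lag in (1, 2, 3):
            expected = dosage_correlation(0.25, 0.25, rho**lag)
            assert abs(R[0, lag] - expected) < 0.02

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 1, "maf": [0.3], "ld_rho": 0.0},
            {"n": 100, "maf": [0.6], "ld_rho": 0.0},
            {"n": 100, "maf": [0.0], "ld_rho": 0.0},
            {"n": 100, "maf": [0.3], "ld_rho": 1.0},
            {"n": 100, "maf": [0.3], "ld_rho": -0.1},
        ],
    )
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ValueError):
            simulate_genotypes(seed=0, **kwargs)


class TestLdClosedForm:
    def test_inversion_round_trip(self):
        rho = latent_rho_for_r2(0.3, 0.2, 0.4)
        assert dosage_correlation(0.3, 0.2, rho) ** 2 == pytest.approx(0.4, abs=1e-8)

    def test_unattainable_r2_raises(self):
        # very different MAFs bound the attainable correlation well below 1
        with pytest.raises(ValueError):
            latent_rho_for_r2(0.5, 0.01, 0.95)


class TestScenarioValidation:
    def test_scenario1_requires_single_mediator(self):
        with pytest.raises(ValueError, match="exactly one mediated"):
            ScenarioSpec(
                scenario_id=1, n_individuals=100, n_snps=2, maf=[0.3, 0.3],
                eqtl_effects={"a": EqtlEffect(0, 0.4), "b": EqtlEffect(1, 0.4)},
                mediation_effects={"a": 0.3, "b": 0.2},
            )

    def test_scenario4_requires_distinct_pair(self):
        with pytest.raises(ValueError, match="distinct"):
            ScenarioSpec(
                scenario_id=4, n_individuals=100, n_snps=3, maf=np.full(3, 0.3),
                eqtl_effects={"a": EqtlEffect(1, 0.4)},
                ld_pair=(1, 1, 0.5), pleiotropy_effect=0.1,
            )

    def test_scenario5_requires_pleiotropy(self):
        with pytest.raises(ValueError, match="pleiotropy"):
            ScenarioSpec(
                scenario_id=5, n_individuals=100, n_snps=2, maf=[0.3, 0.3],
                eqtl_effects={"a": EqtlEffect(0, 0.4)},
            )

    def test_bad_maf_rejected(self):
        with pytest.raises(ValueError, match="MAF"):
            make_scenario1() and ScenarioSpec(
                scenario_id=1, n_individuals=100, n_snps=1, maf=[0.7],
                eqtl_effects={"a": EqtlEffect(0, 0.4)},
                mediation_effects={"a": 0.3},
            )


class TestCohort:
    def test_determinism(self):
        spec = make_scenario1(n=500, seed=9)
        c1, c2 = simulate_cohort(spec), simulate_cohort(spec)
        np.testing.assert_array_equal(c1.dosages, c2.dosages)
        np.testing.assert_array_equal(c1.expression, c2.expression)
        np.testing.assert_array_equal(c1.traits["trait"], c2.traits["trait"])

    def test_truth_round_trips(self, scenario1_cohort):
        assert scenario1_cohort.truth.scenario_id == 1
        assert scenario1_cohort.truth.mediation_effects == {"geneA": 0.3}

    def test_methylation_in_open_unit_interval(self, scenario1_cohort):
        m = scenario1_cohort.methylation
        assert m.min() > 0 and m.max() < 1

    def test_path_coefficient_product(self, scenario1_cohort):
        # trait ~ dosage slope equals eqtl_beta * mediation = 0.4 * 0.3
        g = scenario1_cohort.dosages[:, 5].astype(float)
        y = scenario1_cohort.traits["trait"]
        slope = np.polyfit(g, y, 1)[0]
        se = y.std() / (g.std() * np.sqrt(len(y)))
        assert abs(slope - 0.12) < 3 * se

    def test_null_scenario_pvalues_uniform(self):
        """With all effects zero the variant-trait p-values are U(0, 1)."""
        from scipy import stats
        from tissuemr.assoc import run_eqtlwas

        pvals = []
        for seed in range(20):
            spec = ScenarioSpec(
                scenario_id=1, n_individuals=400, n_snps=25,
                maf=np.full(25, 0.3), ld_rho=0.0,
                eqtl_effects={"a": EqtlEffect(0, 0.4)},
                mediation_effects={"a": 1e-12},  # effectively null
                seed=seed,
            )
            c = simulate_cohort(spec)
            meta = variant_metadata(spec)
            scan = run_eqtlwas(c.dosages, c.traits["trait"], c.covariates, meta)
            pvals.extend(scan["p"].dropna())
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_scenario4_ld_target(self):
        spec = ScenarioSpec(
            scenario_id=4, n_individuals=20000, n_snps=6, maf=np.full(6, 0.3),
            ld_rho=0.2, eqtl_effects={"a": EqtlEffect(3, 0.4)},
            ld_pair=(2, 3, 0.5), pleiotropy_effect=0.15, seed=3,
        )
        c = simulate_cohort(spec)
        r2 = np.corrcoef(c.dosages[:, 2], c.dosages[:, 3])[0, 1] ** 2
        assert abs(r2 - 0.5) < 0.05

    def test_scenario5_wald_bias(self):
        """With no mediation, expression->trait Wald ratio converges to
        pleiotropy / eqtl_beta, the analytic confounding bias."""
        ratios = []
        for seed in range(30):
            spec = ScenarioSpec(
                scenario_id=5, n_individuals=5000, n_snps=2, maf=[0.3, 0.3],
                eqtl_effects={"a": EqtlEffect(0, 0.5)},
                pleiotropy_effect=0.2, seed=seed,
            )
            c = simulate_cohort(spec)
            g = c.dosages[:, 0].astype(float)
            b_exp = np.polyfit(g, c.expression[:, 0], 1)[0]
            b_out = np.polyfit(g, c.traits["trait"], 1)[0]
            ratios.append(b_out / b_exp)
        assert np.mean(ratios) == pytest.approx(0.2 / 0.5, abs=0.05)

    def test_lognormal_switch(self):
        spec = make_scenario1(n=500, seed=4)
        spec.lognormal_traits = ("trait",)
        c = simulate_cohort(spec)
        assert (c.traits["trait"] > 0).all()


class TestDerivedPhenotypes:
    def test_bmi_values(self):
        assert compute_bmi(50, 1.25) == pytest.approx(32.0)
        for h in (1.2, 1.5, 1.9):
            assert compute_bmi(h * h * 22, h) == pytest.approx(22.0)

    def test_bmi_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            compute_bmi(0, 1.7)

    def test_friedewald(self):
        assert compute_friedewald_ldl(5.0, 1.0, 2.2) == pytest.approx(3.0)
        assert compute_friedewald_ldl(4.0, 4.0, 0.0) == pytest.approx(0.0)
        assert np.isnan(compute_friedewald_ldl(5.0, 1.0, 6.0))

    def test_friedewald_mgdl_divisor(self):
        assert compute_friedewald_ldl(
            200.0, 50.0, 100.0, tg_limit=400.0, divisor=5.0
        ) == pytest.approx(130.0)


class TestExports:
    def test_tsv_round_trip(self, tmp_path):
        import pandas as pd
        from tissuemr.simulate import export_cohort_tsv

        spec = make_scenario1(n=50, seed=2)
        c = simulate_cohort(spec)
        paths = export_cohort_tsv(c, str(tmp_path / "coh"))
        dos = pd.read_csv(paths["dosages"], sep="\t")
        np.testing.assert_array_equal(
            dos.drop(columns="individual_id").to_numpy(), c.dosages
        )
        meta = pd.read_csv(paths["variants"], sep="\t")
        assert list(meta.columns) == [
            "variant_id", "chrom", "pos", "other_allele", "effect_allele", "maf",
        ]

    def test_vcf_export(self, tmp_path):
        from tissuemr.simulate import export_vcf

        c = simulate_cohort(make_scenario1(n=10, seed=2))
        out = tmp_path / "coh.vcf"
        export_vcf(c, str(out))
        lines = out.read_text().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        assert len([l for l in lines if not l.startswith("#")]) == 10

    def test_spec_yaml_round_trip(self, tmp_path):
        spec = ScenarioSpec(
            scenario_id=4, n_individuals=100, n_snps=4, maf=np.full(4, 0.2),
            ld_rho=0.3, eqtl_effects={"a": EqtlEffect(2, 0.4, {"liver": 1.5})},
            mqtl_effects={"cg": MqtlEffect(2, 0.3)},
            ld_pair=(1, 2, 0.5), pleiotropy_effect=0.1, seed=7,
        )
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = ScenarioSpec.from_yaml(path)
        assert back.ld_pair == (1, 2, 0.5)
        assert back.eqtl_effects["a"].tissue_scaling == {"liver": 1.5}
        np.testing.assert_allclose(back.maf, spec.maf)


@settings(deadline=None, derandomize=True)
@given(
    weight=st.floats(20, 200),
    height=st.floats(0.5, 2.5),
)
def test_bmi_positive_and_monotone_in_weight(weight, height):
    b = compute_bmi(weight, height)
    assert b > 0
    assert compute_bmi(weight + 1, height) > b
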