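import numpy as np
import pytest

from tissuemr.assoc import run_eqtlwas
from tissuemr.simulate import (
    EqtlEffect,
    MqtlEffect,
    ScenarioSpec,
    simulate_cohort,
    variant_metadata,
)


def make_scenario1(
    n=20000,
    n_snps=10,
    causal=5,
    eqtl_beta=0.4,
    mediation=0.3,
    ld_rho=0.4,
    seed=11,
    with_cpg=True,
    cpg_beta=0.5,
):
    """Single-gene mediation scenario used across test modules."""
    mqtl = {"cg1": MqtlEffect(causal, cpg_beta)} if with_cpg else {}
    return ScenarioSpec(
        scenario_id=1,
        n_individuals=n,
        n_snps=n_snps,
        maf=np.full(n_snps, 0.3),
        ld_rho=ld_rho,
        eqtl_effects={"geneA": EqtlEffect(causal, eqtl_beta)},
        mqtl_effects=mqtl,
        mediation_effects={"geneA": mediation},
        covariate_effects=(0.01, 0.2),
        seed=seed,
    )


@pytest.fixture(scope="session")
def scenario1_cohort():
    return simulate_cohort(make_scenario1())


@pytest.fixture(scope="session")
def scenario1_scan(scenario1_cohort):
    """Trait association scan over the scenario-1 region."""
    spec = scenario1_cohort.truth
    meta = variant_metadata(spec)
    meta["info"] = 1.0
    return run_eqtlwas(
        scenario1_cohort.dosages,
        scenario1_cohort.traits["trait"],
        scenario1_cohort.covariates,
        meta,
    )
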