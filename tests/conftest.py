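import pytest

from gpgemr.simulate import SimulationConfig, simulate_expression_models, simulate_ld_panel
from gpgemr.sumstats import AssociationRecord, Variant


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_individuals=3_000,
        n_variants=60,
        n_genes=3,
        n_tissues=3,
        weights_per_gene=3,
        ld_rho=0.4,
        expr_trait_effect={"outcome": {"G000": -0.3}, "indication": {"G000": 0.4}},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_ld_panel(small_config)


@pytest.fixture(scope="session")
def small_models(small_config, small_panel):
    models, truth = simulate_expression_models(small_config, small_panel)
    return models, truth


def make_record(vid, ea="A", oa="G", beta=0.1, se=0.05, p=None, eaf=0.3, pos=1000, trait="t"):
    from gpgemr._stats import pvalue_from_z

    if p is None:
        p = max(float(pvalue_from_z(beta / se)), 5e-324) if se > 0 else 1.0
    return AssociationRecord(
        variant=Variant(vid, "1", pos, ea, oa),
        beta=beta,
        se=se,
        pvalue=p,
        eaf=eaf,
        trait_id=trait,
    )
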