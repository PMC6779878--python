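import pytest

from rhucscreen.founder_screen import classify_panel, default_panel
from rhucscreen.recessive_filter import (
    FilterConfig,
    filter_by_maf,
    filter_consequence,
    filter_inhouse,
    run_cascade,
)
from rhucscreen.synthetic_cohort import SimulationConfig, make_reference_cohort, simulate_cohort


@pytest.fixture(scope="session")
def discovery_cohort():
    return make_reference_cohort("discovery")


@pytest.fixture(scope="session")
def replication_cohort():
    return make_reference_cohort("replication")


@pytest.fixture(scope="session")
def discovery_diagnoses(discovery_cohort):
    individuals, variants = discovery_cohort
    return run_cascade(individuals, variants)


@pytest.fixture(scope="session")
def discovery_classifications(discovery_cohort):
    individuals, variants = discovery_cohort
    config = FilterConfig()
    qualifying = filter_consequence(
        filter_inhouse(filter_by_maf(variants, config)), config
    )
    panel = default_panel()
    return [classify_panel(i, panel, variants, qualifying) for i in individuals]


@pytest.fixture(scope="session")
def replication_classifications(replication_cohort):
    individuals, variants = replication_cohort
    panel = default_panel()
    return [classify_panel(i, panel, variants, None) for i in individuals]


@pytest.fixture(scope="session")
def small_sim_cohort():
    config = SimulationConfig(
        n_individuals=300,
        seed=11,
        panel_freqs={"trp258_stop": 0.06, "arg90_his": 0.03},
        other_pathogenic_freq=0.01,
        other_gene_fraction=0.01,
        transient_rate=0.02,
        exclusion_flag_rate=0.05,
    )
    return simulate_cohort(config)
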