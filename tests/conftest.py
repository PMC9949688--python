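import pytest

from tepselect.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A down-scaled cohort (10 patients, ~150 class I peptides/sample)
    shared by tests that only need structural realism, not cohort scale."""
    cfg = SimulationConfig(
        n_patients=10,
        mean_ligandome_size_i=150.0,
        mean_ligandome_size_ii=80.0,
        shared_peptide_pool_size=300,
        benign_background_factor=1.0,
        seed=7,
    )
    return simulate_cohort(cfg)
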