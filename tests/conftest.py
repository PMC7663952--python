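import pytest

from arcgait import CohortConfig, DropoutConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort_config() -> CohortConfig:
    """A reduced cohort that keeps full-pipeline tests fast."""
    return CohortConfig(
        n_participants_by_level={"intermediate": 10, "high": 8, "dementia": 6},
        n_facilities=4,
        mu_by_level={"intermediate": 6.0, "high": 5.8, "dementia": 5.9},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cohort_config):
    return generate_cohort(small_cohort_config)


@pytest.fixture(scope="session")
def no_dropout_cohort():
    """Every participant wears the device for the full week."""
    cfg = CohortConfig(
        n_participants_by_level={"intermediate": 8, "high": 6, "dementia": 4},
        n_facilities=3,
        mu_by_level={"intermediate": 6.0, "high": 5.8, "dementia": 5.9},
        dropout=DropoutConfig(p_full=1.0, p_partial=0.0, p_zero=0.0),
        seed=21,
    )
    return cfg, generate_cohort(cfg)
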