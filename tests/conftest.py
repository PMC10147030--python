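import pytest

from nupeval import TrialSimConfig, case_study_fixtures, default_scales, simulate_trial


@pytest.fixture(scope="session")
def scales():
    return {s.attribute_id: s for s in default_scales()}


@pytest.fixture(scope="session")
def fixtures():
    return case_study_fixtures()


@pytest.fixture(scope="session")
def effect_config():
    """Trial config with a strong fertilization effect relative to noise."""
    return TrialSimConfig(
        seed=7, n_genotypes=1,
        monthly_growth_cm={"control": 8.0, "conventional": 16.0, "organic": 12.0},
        replicate_sd_cm=5.0, measurement_sd_cm=5.0,
    )


@pytest.fixture(scope="session")
def effect_dataset(effect_config):
    return simulate_trial(effect_config)
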