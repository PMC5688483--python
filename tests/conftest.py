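import pytest

from liststill import (
    CountryProfile,
    Scenario,
    load_default_interventions,
)


@pytest.fixture(scope="session")
def registry():
    return load_default_interventions()


@pytest.fixture(scope="session")
def registry_by_id(registry):
    return {s.id: s for s in registry}


def make_worked_profile(**overrides) -> CountryProfile:
    """Profile used for the printed worked examples: explicit zero baseline
    coverage for every non-childbirth intervention, known envelope split."""
    kwargs = dict(
        name="worked-example",
        births_per_year=1_000_000.0,
        stillbirths=20_000.0,
        prop_intrapartum=0.40,
        prevalences={
            "untreated_syphilis": 0.03,
            "diabetes": 0.04,
            "severe_hdp": 0.03,
            "malaria_exposure": 0.30,
            "poverty": 0.20,
            "prolonged_pregnancy": 0.075,
        },
        baseline_indicators={
            "anc4": 0.50,
            "sba": 0.50,
            "facility_delivery": 0.40,
            "iptp_or_itn": 0.20,
            # explicit per-intervention baselines (override proxy rules)
            "syphilis": 0.0,
            "malaria": 0.0,
            "micronutrient": 0.0,
            "balanced_energy": 0.0,
            "diabetes": 0.0,
            "hdp": 0.0,
            "induction": 0.0,
        },
    )
    kwargs.update(overrides)
    return CountryProfile(**kwargs)


@pytest.fixture
def worked_profile() -> CountryProfile:
    return make_worked_profile()


def single_target_scenario(intervention: str, target: float) -> Scenario:
    return Scenario(base_year=2025, end_year=2030, targets={intervention: target})
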