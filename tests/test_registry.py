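"""Registry defaults: effectiveness points, timing applicability, validation."""

import pytest

from liststill.registry import (
    AFRule,
    CoverageRule,
    EffectEstimate,
    RiskMeasure,
    SourceKind,
    load_default_interventions,
    override,
    registry_from_config,
    registry_hash,
    registry_to_config,
    validate_spec,
)

EXPECTED_POINTS = {
    "micronutrient": 0.92,
    "malaria": 0.67,
    "balanced_energy": 0.60,
    "syphilis": 0.18,
    "induction": 0.31,
    "sba_outside": 0.77,
}
DELPHI_POINTS = {"diabetes": 0.10, "hdp": 0.20, "bemoc": 0.45, "cemoc": 0.75}


def test_ten_current_interventions(registry):
    assert len(registry) == 10
    assert all(s.status == "current" for s in registry)
    assert len({s.id for s in registry}) == 10


@pytest.mark.parametrize("spec_id,rr", sorted(EXPECTED_POINTS.items()))
def test_rr_sourced_effect_is_one_minus_rr(registry_by_id, spec_id, rr):
    spec = registry_by_id[spec_id]
    eff = spec.antepartum_effect or spec.intrapartum_effect
    assert eff.risk_measure == RiskMeasure.RR
    assert eff.point == pytest.approx(1.0 - rr, abs=1e-12)
    assert eff.lower <= eff.point <= eff.upper


@pytest.mark.parametrize("spec_id,point", sorted(DELPHI_POINTS.items()))
def test_delphi_effects_use_stated_percentage(registry_by_id, spec_id, point):
    spec = registry_by_id[spec_id]
    eff = spec.intrapartum_effect or spec.antepartum_effect
    assert eff.source_kind == SourceKind.DELPHI
    assert eff.point == point


def test_timing_applicability(registry_by_id):
    """Antepartum-only: syphilis, malaria; intrapartum-only: the three
    childbirth packages; the rest act on both compartments."""
    timings = {
        sid: (s.antepartum_effect is not None, s.intrapartum_effect is not None)
        for sid, s in registry_by_id.items()
    }
    assert timings["syphilis"] == (True, False)
    assert timings["malaria"] == (True, False)
    for sid in ("sba_outside", "bemoc", "cemoc"):
        assert timings[sid] == (False, True)
    for sid in ("micronutrient", "balanced_energy", "diabetes", "hdp", "induction"):
        assert timings[sid] == (True, True)


def test_effect_points_in_unit_interval(registry):
    for spec in registry:
        for eff in (spec.antepartum_effect, spec.intrapartum_effect):
            if eff is not None:
                assert 0.0 < eff.point <= 1.0


def test_childbirth_rows_affect_all_intrapartum(registry_by_id):
    for sid in ("sba_outside", "bemoc", "cemoc"):
        assert registry_by_id[sid].af_spec.rule == AFRule.ALL
        assert registry_by_id[sid].coverage_rule == CoverageRule.CHILDBIRTH_MIX


def test_balanced_energy_uses_poverty_proxy(registry_by_id):
    af = registry_by_id["balanced_energy"].af_spec
    assert af.rule == AFRule.PREVALENCE_PROXY
    assert af.prevalence_key == "poverty"
    assert registry_by_id["balanced_energy"].antepartum_effect.point == pytest.approx(0.40)


def test_syphilis_spec_example(registry_by_id):
    spec = registry_by_id["syphilis"]
    assert spec.antepartum_effect.point == pytest.approx(0.82)
    assert spec.intrapartum_effect is None
    assert spec.af_spec.relative_risk == pytest.approx(10.89)


def test_cemoc_spec_example(registry_by_id):
    spec = registry_by_id["cemoc"]
    assert spec.intrapartum_effect.point == 0.75
    assert spec.intrapartum_effect.source_kind == SourceKind.DELPHI
    assert spec.af_spec.rule == AFRule.ALL


def test_defaults_pass_validation(registry):
    for spec in registry:
        assert validate_spec(spec) == []


def test_validation_flags_out_of_bound_effect(registry_by_id):
    bad = override(
        registry_by_id["syphilis"],
        antepartum_effect=EffectEstimate(
            point=1.3, source_kind=SourceKind.META_ANALYSIS, risk_measure=RiskMeasure.RR
        ),
    )
    violations = validate_spec(bad)
    assert len(violations) == 1
    assert "[0, 1]" in violations[0]


def test_validation_flags_paf_without_relative_risk(registry_by_id):
    from liststill.registry import AffectedFractionSpec

    bad = override(
        registry_by_id["syphilis"],
        af_spec=AffectedFractionSpec(rule=AFRule.PAF, prevalence_key="untreated_syphilis"),
    )
    violations = validate_spec(bad)
    assert len(violations) == 1
    assert "relative_risk" in violations[0]


def test_legacy_interventions_excluded_by_default():
    default_ids = {s.id for s in load_default_interventions()}
    assert "folic_acid" not in default_ids
    with_legacy = load_default_interventions(include_legacy=True)
    legacy = {s.id: s for s in with_legacy if s.status == "legacy"}
    assert set(legacy) == {"folic_acid", "fgr_detection"}
    assert legacy["fgr_detection"].antepartum_effect.point == 0.20


def test_registry_config_round_trip(registry):
    doc = registry_to_config(registry)
    again = registry_from_config(doc)
    assert again == registry
    assert registry_hash(again) == registry_hash(registry)


def test_registry_hash_changes_with_parameters(registry, registry_by_id):
    variant = [
        override(s, notes="x") if s.id == "syphilis" else s for s in registry
    ]
    assert registry_hash(variant) != registry_hash(registry)
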