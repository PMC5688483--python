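"""Default intervention registry for the stillbirth deaths-averted model.

Eight interventions are currently modelled, with childbirth care counted as
three mutually exclusive packages (skilled attendance outside emergency
obstetric care facilities, BEmOC and CEmOC), giving ten current specs.
Effectiveness is stored as a fraction-reduction in stillbirth risk: 1 - RR
for meta-analytic relative risks, or the elicited percentage for Delphi
estimates.  Each spec also carries its affected-fraction rule (which subset
of antepartum/intrapartum stillbirths it can act on) and the rule used to
impute baseline coverage when no direct indicator is available.

Two legacy interventions (periconceptual folic acid supplementation and
fetal growth restriction detection/management) were removed from the model
as the evidence base changed; they ship with ``status="legacy"`` and are
only returned when explicitly requested.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Any, Mapping


class SourceKind(str, Enum):
    META_ANALYSIS = "meta-analysis"
    DELPHI = "delphi"


class RiskMeasure(str, Enum):
    RR = "RR"
    OR = "OR"
    PERCENT = "percent"


class AFRule(str, Enum):
    """How the affected fraction for an intervention is obtained."""

    ALL = "ALL"                            # every stillbirth in the compartment
    PREVALENCE_PROXY = "PREVALENCE_PROXY"  # AF = risk-factor prevalence (RR unknown)
    PAF = "PAF"                            # population attributable fraction
    MALARIA_COMPOSITE = "MALARIA_COMPOSITE"  # exposure x placental-malaria rate, then PAF


class Period(str, Enum):
    PERICONCEPTUAL = "periconceptual"
    PREGNANCY = "pregnancy"
    CHILDBIRTH = "childbirth"


class Timing(str, Enum):
    ANTEPARTUM = "antepartum"
    INTRAPARTUM = "intrapartum"


class CoverageRule(str, Enum):
    """How baseline coverage is imputed when the profile has no direct value."""

    DIRECT = "DIRECT"                # read a named baseline indicator
    ZERO_DEFAULT = "ZERO_DEFAULT"    # assume zero baseline coverage
    SYPHILIS_ANC4 = "SYPHILIS_ANC4"  # stepwise share of ANC4+ attendance
    ANC4_SHARE = "ANC4_SHARE"        # fixed small share (5%) of ANC4+ attendance
    CEMOC_SHARE = "CEMOC_SHARE"      # share of births delivering in CEmOC facilities
    CHILDBIRTH_MIX = "CHILDBIRTH_MIX"  # handled via the four-way delivery mix


CAP_RULE_CEMOC = "CEMOC_CAP"


@dataclass(frozen=True)
class EffectEstimate:
    """Fraction-reduction in stillbirth risk attributable to an intervention.

    ``point`` is 1 - RR for relative-risk sources, or the stated percentage
    (as a fraction) for Delphi sources.  ``lower``/``upper`` are the bounds
    implied by the 95% CI or IQR; Delphi IQRs may dip below zero.
    """

    point: float
    source_kind: SourceKind
    risk_measure: RiskMeasure
    lower: float | None = None
    upper: float | None = None


@dataclass(frozen=True)
class AffectedFractionSpec:
    """Rule and inputs for the affected fraction of one intervention."""

    rule: AFRule
    prevalence_key: str | None = None
    relative_risk: float | None = None
    extra: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class InterventionSpec:
    id: str
    name: str
    period: Period
    af_spec: AffectedFractionSpec
    antepartum_effect: EffectEstimate | None = None
    intrapartum_effect: EffectEstimate | None = None
    coverage_rule: CoverageRule = CoverageRule.DIRECT
    coverage_key: str | None = None     # indicator name for DIRECT
    cap_rule: str | None = None
    status: str = "current"
    notes: str = ""

    def effect(self, timing: Timing) -> EffectEstimate | None:
        if timing == Timing.ANTEPARTUM:
            return self.antepartum_effect
        return self.intrapartum_effect


def _rr_effect(rr: float, lo: float, hi: float) -> EffectEstimate:
    return EffectEstimate(
        point=1.0 - rr,
        lower=1.0 - hi,
        upper=1.0 - lo,
        source_kind=SourceKind.META_ANALYSIS,
        risk_measure=RiskMeasure.RR,
    )


def _delphi_effect(point: float, lo: float, hi: float) -> EffectEstimate:
    return EffectEstimate(
        point=point,
        lower=lo,
        upper=hi,
        source_kind=SourceKind.DELPHI,
        risk_measure=RiskMeasure.PERCENT,
    )


# Risk-factor relative risks used for attributable fractions.
RR_UNTREATED_SYPHILIS = 10.89
RR_DIABETES = 3.38
RR_SEVERE_HDP = 2.1          # source reference unavailable; order of magnitude
                             # consistent with high-income aOR 1.3-2.2
RR_PROLONGED_PREGNANCY = 1.8
OR_PLACENTAL_MALARIA = 2.19  # odds ratio, used as an RR approximation
PLACENTAL_MALARIA_RATE = 0.278          # primigravidae
PLACENTAL_MALARIA_RATE_SECOND = 0.208   # second pregnancy
PLACENTAL_MALARIA_RATE_MULTI = 0.156    # higher-order pregnancies
PROLONGED_PREGNANCY_PREVALENCE = 0.075

# Delphi effectiveness of the three childbirth-care packages on intrapartum
# stillbirths, relative to home delivery without a skilled attendant.
CHILDBIRTH_EFFECTS = {"sba_outside": 0.23, "bemoc": 0.45, "cemoc": 0.75}


def _default_specs() -> list[InterventionSpec]:
    af_all = AffectedFractionSpec(rule=AFRule.ALL)
    return [
        InterventionSpec(
            id="micronutrient",
            name="Multiple micronutrient supplementation",
            period=Period.PREGNANCY,
            antepartum_effect=_rr_effect(0.92, 0.86, 0.99),
            intrapartum_effect=_rr_effect(0.92, 0.86, 0.99),
            af_spec=af_all,
            coverage_rule=CoverageRule.ZERO_DEFAULT,
            notes=(
                "Updated Cochrane evidence (RR 0.97, 0.87-1.09) suggests no "
                "effect; kept pending a technical working group decision."
            ),
        ),
        InterventionSpec(
            id="malaria",
            name="Malaria prevention with IPTp or ITN",
            period=Period.PREGNANCY,
            antepartum_effect=_rr_effect(0.67, 0.47, 0.97),
            intrapartum_effect=None,
            af_spec=AffectedFractionSpec(
                rule=AFRule.MALARIA_COMPOSITE,
                prevalence_key="malaria_exposure",
                relative_risk=OR_PLACENTAL_MALARIA,
                extra={"placental_malaria_rate": PLACENTAL_MALARIA_RATE},
            ),
            coverage_rule=CoverageRule.DIRECT,
            coverage_key="iptp_or_itn",
            notes="Effectiveness evidence is from ITN trials alone.",
        ),
        InterventionSpec(
            id="balanced_energy",
            name="Balanced energy supplementation",
            period=Period.PREGNANCY,
            antepartum_effect=_rr_effect(0.60, 0.39, 0.94),
            intrapartum_effect=_rr_effect(0.60, 0.39, 0.94),
            af_spec=AffectedFractionSpec(
                rule=AFRule.PREVALENCE_PROXY, prevalence_key="poverty"
            ),
            coverage_rule=CoverageRule.ZERO_DEFAULT,
            notes="Share of population living <$1.90/day proxies food insecurity.",
        ),
        InterventionSpec(
            id="syphilis",
            name="Syphilis detection and treatment",
            period=Period.PREGNANCY,
            antepartum_effect=_rr_effect(0.18, 0.10, 0.33),
            intrapartum_effect=None,
            af_spec=AffectedFractionSpec(
                rule=AFRule.PAF,
                prevalence_key="untreated_syphilis",
                relative_risk=RR_UNTREATED_SYPHILIS,
            ),
            coverage_rule=CoverageRule.SYPHILIS_ANC4,
        ),
        InterventionSpec(
            id="diabetes",
            name="Diabetes screening and management",
            period=Period.PREGNANCY,
            antepartum_effect=_delphi_effect(0.10, -0.05, 0.30),
            intrapartum_effect=_delphi_effect(0.10, 0.035, 0.25),
            af_spec=AffectedFractionSpec(
                rule=AFRule.PAF,
                prevalence_key="diabetes",
                relative_risk=RR_DIABETES,
            ),
            coverage_rule=CoverageRule.ANC4_SHARE,
        ),
        InterventionSpec(
            id="hdp",
            name="Management of hypertensive disorders of pregnancy",
            period=Period.PREGNANCY,
            antepartum_effect=_delphi_effect(0.20, -0.10, 0.30),
            intrapartum_effect=_delphi_effect(0.20, 0.10, 0.40),
            af_spec=AffectedFractionSpec(
                rule=AFRule.PAF,
                prevalence_key="severe_hdp",
                relative_risk=RR_SEVERE_HDP,
            ),
            coverage_rule=CoverageRule.ANC4_SHARE,
            notes="Modelled for severe forms (pre-eclampsia/eclampsia) only.",
        ),
        InterventionSpec(
            id="induction",
            name="Induction of labour for pregnancies lasting >41 weeks",
            period=Period.CHILDBIRTH,
            antepartum_effect=_rr_effect(0.31, 0.12, 0.88),
            intrapartum_effect=_rr_effect(0.31, 0.12, 0.88),
            af_spec=AffectedFractionSpec(
                rule=AFRule.PAF,
                prevalence_key="prolonged_pregnancy",
                relative_risk=RR_PROLONGED_PREGNANCY,
            ),
            coverage_rule=CoverageRule.CEMOC_SHARE,
            cap_rule=CAP_RULE_CEMOC,
            notes=(
                "Effect is the all-cause perinatal-death RR 0.31; the "
                "stillbirth-only estimate (RR 0.30) was underpowered. "
                "Coverage is capped at the CEmOC delivery share."
            ),
        ),
        InterventionSpec(
            id="sba_outside",
            name="Skilled attendance outside BEmOC or CEmOC facilities",
            period=Period.CHILDBIRTH,
            antepartum_effect=None,
            intrapartum_effect=_rr_effect(0.77, 0.69, 0.85),
            af_spec=af_all,
            coverage_rule=CoverageRule.CHILDBIRTH_MIX,
        ),
        InterventionSpec(
            id="bemoc",
            name="Childbirth care in BEmOC facility",
            period=Period.CHILDBIRTH,
            antepartum_effect=None,
            intrapartum_effect=_delphi_effect(0.45, 0.30, 0.70),
            af_spec=af_all,
            coverage_rule=CoverageRule.CHILDBIRTH_MIX,
        ),
        InterventionSpec(
            id="cemoc",
            name="Childbirth care in CEmOC facility",
            period=Period.CHILDBIRTH,
            antepartum_effect=None,
            intrapartum_effect=_delphi_effect(0.75, 0.50, 0.87),
            af_spec=af_all,
            coverage_rule=CoverageRule.CHILDBIRTH_MIX,
        ),
    ]


def _legacy_specs() -> list[InterventionSpec]:
    return [
        InterventionSpec(
            id="folic_acid",
            name="Periconceptual folic acid supplementation",
            period=Period.PERICONCEPTUAL,
            antepartum_effect=_rr_effect(0.59, 0.52, 0.68),
            intrapartum_effect=_rr_effect(0.59, 0.52, 0.68),
            af_spec=AffectedFractionSpec(
                rule=AFRule.PREVALENCE_PROXY,
                prevalence_key="neural_tube_defect",
            ),
            coverage_rule=CoverageRule.ZERO_DEFAULT,
            status="legacy",
            notes=(
                "Removed Feb 2016: supplementation assumed interchangeable "
                "with fortification, but supplementation shows no stillbirth "
                "effect (RR 1.05, 0.54-2.05) as it is rarely started "
                "periconceptually."
            ),
        ),
        InterventionSpec(
            id="fgr_detection",
            name="Fetal growth restriction detection and management",
            period=Period.PREGNANCY,
            antepartum_effect=_delphi_effect(0.20, 0.0, 0.20),
            intrapartum_effect=_delphi_effect(0.20, 0.0, 0.20),
            af_spec=AffectedFractionSpec(
                rule=AFRule.PREVALENCE_PROXY,
                prevalence_key="fgr_high_risk",
            ),
            coverage_rule=CoverageRule.ZERO_DEFAULT,
            status="legacy",
            notes=(
                "Removed May 2015: screening package and setting-specific "
                "effectiveness poorly defined."
            ),
        ),
    ]


def load_default_interventions(include_legacy: bool = False) -> list[InterventionSpec]:
    """Return the intervention registry with all default parameters.

    The ten current specs are the eight modelled interventions with
    childbirth care split into its three mutually exclusive packages.
    ``include_legacy=True`` appends the removed interventions (marked
    ``status="legacy"``); they are never part of a default projection.
    """
    specs = _default_specs()
    if include_legacy:
        specs += _legacy_specs()
    return specs


def validate_spec(spec: InterventionSpec) -> list[str]:
    """Check one spec against the type invariants; return violations.

    Violations are returned as human-readable strings (not raised) so a
    whole registry override can be validated and reported in one pass.
    """
    out: list[str] = []
    if spec.antepartum_effect is None and spec.intrapartum_effect is None:
        out.append(f"{spec.id}: at least one timing must have an effect")
    for label, eff in (
        ("antepartum_effect", spec.antepartum_effect),
        ("intrapartum_effect", spec.intrapartum_effect),
    ):
        if eff is None:
            continue
        if not 0.0 <= eff.point <= 1.0:
            out.append(f"{spec.id}.{label}.point={eff.point} outside [0, 1]")
        if eff.lower is not None and eff.upper is not None:
            if not eff.lower <= eff.point <= eff.upper:
                out.append(
                    f"{spec.id}.{label}: point {eff.point} outside bounds "
                    f"[{eff.lower}, {eff.upper}]"
                )
    af = spec.af_spec
    needs_rr = af.rule in (AFRule.PAF, AFRule.MALARIA_COMPOSITE)
    if needs_rr and af.relative_risk is None:
        out.append(f"{spec.id}.af_spec: rule {af.rule.value} requires relative_risk")
    if not needs_rr and af.relative_risk is not None:
        out.append(f"{spec.id}.af_spec: rule {af.rule.value} must not set relative_risk")
    if af.relative_risk is not None and af.relative_risk <= 0:
        out.append(f"{spec.id}.af_spec.relative_risk={af.relative_risk} must be > 0")
    if af.rule != AFRule.ALL and af.prevalence_key is None:
        out.append(f"{spec.id}.af_spec: rule {af.rule.value} requires prevalence_key")
    if spec.coverage_rule == CoverageRule.DIRECT and spec.coverage_key is None:
        out.append(f"{spec.id}: coverage_rule DIRECT requires coverage_key")
    return out


# ---------------------------------------------------------------------------
# Structured-config export/import so users can run sensitivity variants.

def _effect_to_dict(eff: EffectEstimate | None) -> dict[str, Any] | None:
    if eff is None:
        return None
    return {
        "point": eff.point,
        "lower": eff.lower,
        "upper": eff.upper,
        "source_kind": eff.source_kind.value,
        "risk_measure": eff.risk_measure.value,
    }


def _effect_from_dict(d: dict[str, Any] | None) -> EffectEstimate | None:
    if d is None:
        return None
    return EffectEstimate(
        point=float(d["point"]),
        lower=None if d.get("lower") is None else float(d["lower"]),
        upper=None if d.get("upper") is None else float(d["upper"]),
        source_kind=SourceKind(d["source_kind"]),
        risk_measure=RiskMeasure(d["risk_measure"]),
    )


def spec_to_dict(spec: InterventionSpec) -> dict[str, Any]:
    return {
        "id": spec.id,
        "name": spec.name,
        "period": spec.period.value,
        "antepartum_effect": _effect_to_dict(spec.antepartum_effect),
        "intrapartum_effect": _effect_to_dict(spec.intrapartum_effect),
        "af_spec": {
            "rule": spec.af_spec.rule.value,
            "prevalence_key": spec.af_spec.prevalence_key,
            "relative_risk": spec.af_spec.relative_risk,
            "extra": dict(spec.af_spec.extra),
        },
        "coverage_rule": spec.coverage_rule.value,
        "coverage_key": spec.coverage_key,
        "cap_rule": spec.cap_rule,
        "status": spec.status,
        "notes": spec.notes,
    }


def spec_from_dict(d: dict[str, Any]) -> InterventionSpec:
    af = d["af_spec"]
    return InterventionSpec(
        id=d["id"],
        name=d.get("name", d["id"]),
        period=Period(d["period"]),
        antepartum_effect=_effect_from_dict(d.get("antepartum_effect")),
        intrapartum_effect=_effect_from_dict(d.get("intrapartum_effect")),
        af_spec=AffectedFractionSpec(
            rule=AFRule(af["rule"]),
            prevalence_key=af.get("prevalence_key"),
            relative_risk=None
            if af.get("relative_risk") is None
            else float(af["relative_risk"]),
            extra={k: float(v) for k, v in (af.get("extra") or {}).items()},
        ),
        coverage_rule=CoverageRule(d.get("coverage_rule", "DIRECT")),
        coverage_key=d.get("coverage_key"),
        cap_rule=d.get("cap_rule"),
        status=d.get("status", "current"),
        notes=d.get("notes", ""),
    )


def registry_to_config(specs: list[InterventionSpec]) -> dict[str, Any]:
    return {"interventions": [spec_to_dict(s) for s in specs]}


def registry_from_config(doc: dict[str, Any]) -> list[InterventionSpec]:
    return [spec_from_dict(d) for d in doc["interventions"]]


def registry_hash(specs: list[InterventionSpec]) -> str:
    """Stable content hash of a registry, recorded in run manifests."""
    blob = json.dumps(registry_to_config(specs), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def override(spec: InterventionSpec, **changes: Any) -> InterventionSpec:
    """Return a copy of ``spec`` with fields replaced (sensitivity variants)."""
    return replace(spec, **changes)
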