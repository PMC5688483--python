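"""Core deaths-averted arithmetic and multi-year scenario projection.

The model is linear and deterministic: a fixed stillbirth envelope is split
into antepartum and intrapartum compartments, and for each intervention the
fraction of a compartment averted is

    effectiveness x (change in coverage) x affected fraction.

Within a compartment, multiple interventions combine as a multiplicative
residual cascade, residual = envelope x prod_i (1 - E_i AF_i dC_i), which is
order-free and can never avert more than 100% of the compartment; jointly
averted deaths are attributed to interventions in proportion to their
single-intervention averted fractions.  Childbirth care acts on the
intrapartum compartment first, through shifts in the four-way delivery mix;
the remaining interventions then cascade on the residual.

Mortality rates and the envelope are static: with no coverage change, the
stillbirth rate is constant across all projection years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .coverage import (
    ChildbirthMix,
    anc_condition_coverage,
    childbirth_mix_from_facility,
    induction_coverage_cap,
    syphilis_coverage_from_anc4,
)
from .epi import resolve_affected_fraction
from .errors import ConfigurationError, InputDomainError
from .registry import (
    CHILDBIRTH_EFFECTS,
    CoverageRule,
    InterventionSpec,
    Timing,
    load_default_interventions,
)

ENAP_TARGET_SBR = 12.0  # stillbirths per 1000 total births, 2030 target

_CHILDBIRTH_IDS = ("sba_outside", "bemoc", "cemoc")


# ---------------------------------------------------------------------------
# Input documents


@dataclass(frozen=True)
class CountryProfile:
    """Demography, stillbirth envelope, risk-factor prevalences and baseline
    coverage indicators for one country or subnational unit.

    ``births_per_year`` counts total births (live births plus stillbirths).
    The stillbirth envelope may be given as a count (``stillbirths``) or as
    a rate per 1000 total births (``sbr``); counts take precedence.
    """

    births_per_year: float
    prop_intrapartum: float
    stillbirths: float | None = None
    sbr: float | None = None
    prevalences: Mapping[str, float] = field(default_factory=dict)
    baseline_indicators: Mapping[str, float] = field(default_factory=dict)
    name: str = ""

    def stillbirth_count(self) -> float:
        if self.stillbirths is not None:
            return float(self.stillbirths)
        if self.sbr is not None:
            return self.sbr / 1000.0 * self.births_per_year
        raise ConfigurationError(
            "profile supplies neither 'stillbirths' nor 'sbr'"
        )


@dataclass(frozen=True)
class Scenario:
    """Target coverages at ``end_year``, reached from baseline per trajectory.

    ``targets`` maps intervention ids (or the childbirth keys
    ``facility_delivery``/``sba``, or the three delivery-package ids) to
    target coverage fractions.  ``trajectory`` is ``linear`` (interpolate
    each year) or ``step`` (jump to target the year after base_year).
    """

    base_year: int
    end_year: int
    targets: Mapping[str, float] = field(default_factory=dict)
    trajectory: str = "linear"
    name: str = ""


def validate_profile(profile: CountryProfile) -> list[str]:
    """Return invariant violations with field paths (empty list iff valid)."""
    out: list[str] = []
    if profile.births_per_year <= 0:
        out.append(f"births_per_year={profile.births_per_year} must be > 0")
    if profile.stillbirths is None and profile.sbr is None:
        out.append("one of 'stillbirths' or 'sbr' is required; both absent")
    if profile.stillbirths is not None:
        if profile.stillbirths < 0:
            out.append(f"stillbirths={profile.stillbirths} must be >= 0")
        elif profile.stillbirths > profile.births_per_year:
            out.append("stillbirths exceeds births_per_year")
    if profile.sbr is not None and not 0 <= profile.sbr <= 1000:
        out.append(f"sbr={profile.sbr} outside [0, 1000]")
    if not 0.0 <= profile.prop_intrapartum <= 1.0:
        out.append(f"prop_intrapartum={profile.prop_intrapartum} outside [0, 1]")
    for group_name, group in (
        ("prevalences", profile.prevalences),
        ("baseline_indicators", profile.baseline_indicators),
    ):
        for key, value in group.items():
            if not 0.0 <= float(value) <= 1.0:
                out.append(f"{group_name}.{key}={value} outside [0, 1]")
    ind = profile.baseline_indicators
    if "facility_delivery" in ind and "sba" in ind:
        if float(ind["facility_delivery"]) > float(ind["sba"]) + 1e-12:
            out.append("baseline_indicators.facility_delivery exceeds .sba")
    return out


def validate_scenario(scenario: Scenario) -> list[str]:
    out: list[str] = []
    if scenario.base_year >= scenario.end_year:
        out.append(
            f"base_year {scenario.base_year} must precede end_year "
            f"{scenario.end_year}"
        )
    if scenario.trajectory not in ("linear", "step"):
        out.append(f"trajectory={scenario.trajectory!r} not in {{linear, step}}")
    for key, value in scenario.targets.items():
        if not 0.0 <= float(value) <= 1.0:
            out.append(f"targets.{key}={value} outside [0, 1]")
    return out


# ---------------------------------------------------------------------------
# Elementary operations


def averted_fraction(
    effectiveness: float, cov_base: float, cov_target: float, af: float
) -> float:
    """Fraction of a compartment averted by one intervention.

    May be negative when coverage falls (deaths increase symmetrically).
    """
    for name, value in (
        ("effectiveness", effectiveness),
        ("cov_base", cov_base),
        ("cov_target", cov_target),
        ("af", af),
    ):
        if not 0.0 <= value <= 1.0:
            raise InputDomainError(f"{name}={value} outside [0, 1]")
    return effectiveness * (cov_target - cov_base) * af


def compartment_cascade(
    deaths: float,
    terms: Sequence[tuple[float, float, float, float]],
) -> tuple[list[float], float]:
    """Combine several interventions on one compartment.

    Each term is (effectiveness, affected fraction, baseline coverage,
    target coverage).  The residual is multiplicative over the terms'
    single-intervention averted fractions, so it is independent of term
    order and cannot go below zero for valid inputs; the jointly averted
    total is attributed to terms in proportion to those fractions.  The sum
    of attributed deaths plus the residual reproduces ``deaths`` exactly.
    """
    if deaths < 0:
        raise InputDomainError(f"deaths={deaths} must be >= 0")
    fracs = []
    for e, af, cb, ct in terms:
        f = averted_fraction(e, cb, ct, af)
        if f > 1.0:
            raise InputDomainError(
                f"single-intervention averted fraction {f} exceeds 1"
            )
        fracs.append(f)
    if not fracs:
        return [], deaths
    # multiply in sorted order: bit-for-bit order invariance
    residual_frac = 1.0
    for f in sorted(fracs):
        residual_frac *= 1.0 - f
    residual = deaths * residual_frac
    total_averted = deaths - residual
    weight_sum = sum(fracs)
    if abs(weight_sum) > 1e-300:
        averted = [total_averted * f / weight_sum for f in fracs]
    else:
        abs_sum = sum(abs(f) for f in fracs)
        if abs_sum == 0.0:
            return [0.0] * len(fracs), deaths
        averted = [total_averted * abs(f) / abs_sum for f in fracs]
    # force exact conservation against float round-off
    averted[-1] += total_averted - sum(averted)
    return averted, residual


def childbirth_impact(
    ip_deaths: float,
    base_mix: ChildbirthMix,
    target_mix: ChildbirthMix,
    renormalise: bool = False,
    effects: Mapping[str, float] = CHILDBIRTH_EFFECTS,
) -> float:
    """Intrapartum stillbirths averted by shifting the childbirth-care mix.

    The default (plain linear) form is ``ip_deaths x sum_c E_c dC_c`` with
    package effectivenesses relative to home delivery without a skilled
    attendant.  ``renormalise=True`` divides by ``1 - sum_c E_c C_c(base)``,
    which re-expresses the effect on an envelope that already reflects the
    baseline mix; the two coincide when the baseline is all-home.  Clamped
    to [-ip_deaths, ip_deaths].
    """
    by_cat = childbirth_impact_by_category(
        ip_deaths, base_mix, target_mix, renormalise, effects
    )
    return sum(by_cat.values())


def childbirth_impact_by_category(
    ip_deaths: float,
    base_mix: ChildbirthMix,
    target_mix: ChildbirthMix,
    renormalise: bool = False,
    effects: Mapping[str, float] = CHILDBIRTH_EFFECTS,
) -> dict[str, float]:
    """Per-package attribution of the childbirth-care impact."""
    if ip_deaths < 0:
        raise InputDomainError(f"ip_deaths={ip_deaths} must be >= 0")
    base = base_mix.as_dict()
    target = target_mix.as_dict()
    scale = 1.0
    if renormalise:
        baseline_load = sum(effects[c] * base[c] for c in effects)
        if baseline_load < 1.0:
            scale = 1.0 / (1.0 - baseline_load)
    by_cat = {
        c: ip_deaths * effects[c] * (target[c] - base[c]) * scale for c in effects
    }
    total = sum(by_cat.values())
    if abs(total) > ip_deaths > 0:
        shrink = ip_deaths / abs(total)
        by_cat = {c: v * shrink for c, v in by_cat.items()}
    return by_cat


def sbr(stillbirths: float, total_births: float) -> float:
    """Stillbirth rate per 1000 total births (live + still)."""
    if total_births <= 0:
        raise InputDomainError(f"total_births={total_births} must be > 0")
    if stillbirths < 0:
        raise InputDomainError(f"stillbirths={stillbirths} must be >= 0")
    return 1000.0 * stillbirths / total_births


def enap_met(rate: float) -> bool:
    """Whether a stillbirth rate meets the 2030 target of <=12 per 1000."""
    return rate <= ENAP_TARGET_SBR


# ---------------------------------------------------------------------------
# Baseline-coverage resolution


def resolve_base_mix(profile: CountryProfile) -> ChildbirthMix:
    """Baseline childbirth-care mix: direct indicators if all three package
    shares are supplied, otherwise imputed from facility/SBA rates."""
    ind = profile.baseline_indicators
    if all(k in ind for k in _CHILDBIRTH_IDS):
        shares = {k: float(ind[k]) for k in _CHILDBIRTH_IDS}
        home = 1.0 - sum(shares.values())
        if home < -1e-9:
            raise ConfigurationError(
                "childbirth package indicators sum to more than 1"
            )
        return ChildbirthMix(home_no_sba=max(0.0, home), **shares)
    for key in ("facility_delivery", "sba"):
        if key not in ind:
            raise ConfigurationError(
                f"profile does not supply baseline indicator {key!r} needed "
                "to impute the childbirth-care mix"
            )
    return childbirth_mix_from_facility(
        float(ind["facility_delivery"]), float(ind["sba"])
    )


def resolve_target_mix(
    scenario: Scenario, profile: CountryProfile, base_mix: ChildbirthMix
) -> ChildbirthMix:
    """End-year childbirth-care mix implied by the scenario targets.

    Direct package targets (all three of sba_outside/bemoc/cemoc) win;
    otherwise facility_delivery/sba targets are pushed through the same
    imputation rule as the baseline; otherwise the mix is unchanged.
    """
    targets = scenario.targets
    direct = [k for k in _CHILDBIRTH_IDS if k in targets]
    if direct:
        if len(direct) != len(_CHILDBIRTH_IDS):
            raise ConfigurationError(
                "childbirth package targets must set all three of "
                f"{_CHILDBIRTH_IDS}; got only {direct}"
            )
        shares = {k: float(targets[k]) for k in _CHILDBIRTH_IDS}
        home = 1.0 - sum(shares.values())
        if home < -1e-9:
            raise ConfigurationError("childbirth package targets sum to more than 1")
        return ChildbirthMix(home_no_sba=max(0.0, home), **shares)
    if "facility_delivery" in targets or "sba" in targets:
        ind = profile.baseline_indicators
        facility = float(targets.get("facility_delivery", ind.get("facility_delivery", 0.0)))
        sba_rate = float(targets.get("sba", ind.get("sba", facility)))
        sba_rate = max(sba_rate, facility)
        return childbirth_mix_from_facility(facility, sba_rate)
    return base_mix


def baseline_coverage(
    spec: InterventionSpec, profile: CountryProfile, base_mix: ChildbirthMix
) -> float:
    """Baseline coverage for one non-childbirth intervention.

    A direct entry in ``baseline_indicators`` under the intervention id
    always overrides the imputation rule.
    """
    ind = profile.baseline_indicators
    if spec.id in ind:
        return float(ind[spec.id])
    rule = spec.coverage_rule
    if rule == CoverageRule.ZERO_DEFAULT:
        return 0.0
    if rule == CoverageRule.CEMOC_SHARE:
        return base_mix.cemoc
    if rule == CoverageRule.SYPHILIS_ANC4:
        return syphilis_coverage_from_anc4(_require(ind, "anc4", spec.id))
    if rule == CoverageRule.ANC4_SHARE:
        return anc_condition_coverage(_require(ind, "anc4", spec.id))
    if rule == CoverageRule.DIRECT:
        return _require(ind, spec.coverage_key, spec.id)
    raise ConfigurationError(
        f"intervention {spec.id!r} uses coverage rule {rule.value}, which is "
        "resolved through the childbirth mix, not per-intervention coverage"
    )


def _require(ind: Mapping[str, float], key: str, owner: str) -> float:
    if key not in ind:
        raise ConfigurationError(
            f"profile does not supply baseline indicator {key!r} required "
            f"for intervention {owner!r}"
        )
    return float(ind[key])


# ---------------------------------------------------------------------------
# Projection


@dataclass
class ImpactResult:
    """Per-year, per-intervention, per-timing stillbirths averted.

    ``detail`` has one row per (year, intervention, timing) with the
    averted count; ``summary`` has one row per year with compartment
    envelopes, total averted, residual stillbirths, the stillbirth rate per
    1000 total births and whether it meets the <=12 target.  Fractional
    deaths are carried at full precision.
    """

    detail: pd.DataFrame
    summary: pd.DataFrame
    births_per_year: float
    envelope: float
    prop_intrapartum: float
    baseline_coverage: dict[str, float]
    target_coverage: dict[str, float]

    def conservation_errors(self) -> pd.Series:
        """Per-year |averted + residual - envelope| (should be ~0)."""
        totals = self.detail.groupby("year")["averted"].sum()
        merged = self.summary.set_index("year")
        return (totals + merged["residual"] - self.envelope).abs()


def _year_fraction(scenario: Scenario, year: int) -> float:
    if scenario.trajectory == "step":
        return 0.0 if year == scenario.base_year else 1.0
    return (year - scenario.base_year) / (scenario.end_year - scenario.base_year)


def _lerp_mix(a: ChildbirthMix, b: ChildbirthMix, t: float) -> ChildbirthMix:
    def mix(x: float, y: float) -> float:
        return min(1.0, max(0.0, x + t * (y - x)))

    return ChildbirthMix(
        home_no_sba=mix(a.home_no_sba, b.home_no_sba),
        sba_outside=mix(a.sba_outside, b.sba_outside),
        bemoc=mix(a.bemoc, b.bemoc),
        cemoc=mix(a.cemoc, b.cemoc),
    )


def run_scenario(
    profile: CountryProfile,
    scenario: Scenario,
    registry: Iterable[InterventionSpec] | None = None,
    renormalise_childbirth: bool = False,
) -> ImpactResult:
    """Project stillbirths averted for each year of a coverage scenario.

    Each year the coverage of every targeted intervention is interpolated
    between baseline and target, the envelope is split by timing, childbirth
    care is applied to the intrapartum compartment, and the remaining
    interventions cascade within each compartment (the post-term induction
    coverage is capped at that year's CEmOC share).
    """
    problems = validate_profile(profile) + validate_scenario(scenario)
    if problems:
        raise InputDomainError("; ".join(problems))
    specs = [
        s
        for s in (registry if registry is not None else load_default_interventions())
        if s.status == "current"
    ]
    cascade_specs = [s for s in specs if s.coverage_rule != CoverageRule.CHILDBIRTH_MIX]
    cb_effects = {
        s.id: s.intrapartum_effect.point
        for s in specs
        if s.coverage_rule == CoverageRule.CHILDBIRTH_MIX
    }

    envelope = profile.stillbirth_count()
    ip_envelope = envelope * profile.prop_intrapartum
    ap_envelope = envelope - ip_envelope

    base_mix = resolve_base_mix(profile)
    target_mix = resolve_target_mix(scenario, profile, base_mix)
    cov_base = {s.id: baseline_coverage(s, profile, base_mix) for s in cascade_specs}
    cov_target = {
        s.id: float(scenario.targets.get(s.id, cov_base[s.id])) for s in cascade_specs
    }

    af_cache = {
        (s.id, timing): resolve_affected_fraction(s.af_spec, profile, timing).value
        for s in cascade_specs
        for timing in Timing
        if s.effect(timing) is not None
    }

    detail_rows: list[dict] = []
    summary_rows: list[dict] = []
    for year in range(scenario.base_year, scenario.end_year + 1):
        t = _year_fraction(scenario, year)
        mix_y = _lerp_mix(base_mix, target_mix, t)
        cov_y = {
            i: cov_base[i] + t * (cov_target[i] - cov_base[i]) for i in cov_base
        }

        def effective_coverage(spec_id: str, cov: float, mix: ChildbirthMix) -> float:
            if spec_id == "induction":
                return induction_coverage_cap(cov, mix.cemoc)
            return cov

        total_averted = 0.0

        # childbirth care on the intrapartum compartment, first
        cb_by_cat = childbirth_impact_by_category(
            ip_envelope, base_mix, mix_y, renormalise_childbirth, cb_effects
        )
        cb_total = sum(cb_by_cat.values())
        for cat, averted in cb_by_cat.items():
            detail_rows.append(
                {
                    "year": year,
                    "intervention": cat,
                    "timing": Timing.INTRAPARTUM.value,
                    "averted": averted,
                }
            )
        total_averted += cb_total

        # remaining interventions cascade per compartment
        for timing, compartment in (
            (Timing.ANTEPARTUM, ap_envelope),
            (Timing.INTRAPARTUM, ip_envelope - cb_total),
        ):
            active = [s for s in cascade_specs if s.effect(timing) is not None]
            terms = []
            for s in active:
                cb_eff = effective_coverage(s.id, cov_base[s.id], base_mix)
                cy_eff = effective_coverage(s.id, cov_y[s.id], mix_y)
                terms.append(
                    (s.effect(timing).point, af_cache[(s.id, timing)], cb_eff, cy_eff)
                )
            averted_list, _ = compartment_cascade(max(0.0, compartment), terms)
            for s, averted in zip(active, averted_list):
                detail_rows.append(
                    {
                        "year": year,
                        "intervention": s.id,
                        "timing": timing.value,
                        "averted": averted,
                    }
                )
            total_averted += sum(averted_list)

        residual = envelope - total_averted
        rate = sbr(max(0.0, residual), profile.births_per_year)
        summary_rows.append(
            {
                "year": year,
                "antepartum_deaths": ap_envelope,
                "intrapartum_deaths": ip_envelope,
                "averted": total_averted,
                "residual": residual,
                "sbr": rate,
                "enap_met": enap_met(rate),
            }
        )

    return ImpactResult(
        detail=pd.DataFrame(detail_rows),
        summary=pd.DataFrame(summary_rows),
        births_per_year=profile.births_per_year,
        envelope=envelope,
        prop_intrapartum=profile.prop_intrapartum,
        baseline_coverage=cov_base,
        target_coverage=cov_target,
    )
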