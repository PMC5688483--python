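"""Affected fractions: the share of a timing compartment's stillbirths an
intervention can act on.

Where a risk factor's prevalence p and relative risk RR are both known, the
affected fraction is the population attributable fraction

    PAF = p (RR - 1) / (1 + p (RR - 1)).

Where only prevalence is known, the stillbirth risk in the exposed is
assumed equal to the general population and the prevalence itself is used
(an underestimate of the true attributable share).  Malaria uses a composite
exposure: the fraction of pregnancies exposed to falciparum malaria times
the placental-malaria rate among the exposed, with the placental-malaria
odds ratio treated as a relative risk (stillbirth is rare enough for the
two to be interchangeable here).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError, InputDomainError
from .registry import (
    AFRule,
    AffectedFractionSpec,
    OR_PLACENTAL_MALARIA,
    PLACENTAL_MALARIA_RATE,
    PROLONGED_PREGNANCY_PREVALENCE,
    Timing,
)

# Prevalences assumed when a profile does not supply them; post-term
# progression is a biological constant rather than a country indicator.
DEFAULT_PREVALENCES = {"prolonged_pregnancy": PROLONGED_PREGNANCY_PREVALENCE}


@dataclass(frozen=True)
class AffectedFraction:
    value: float
    timing: Timing
    rule_used: AFRule


def paf(prevalence: float, relative_risk: float) -> float:
    """Population attributable fraction p(RR-1)/(1+p(RR-1)).

    Clamped to 0 for protective exposures (RR < 1): an affected fraction is
    a proportion of deaths and cannot be negative.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise InputDomainError(f"prevalence {prevalence} outside [0, 1]")
    if relative_risk <= 0.0:
        raise InputDomainError(f"relative risk {relative_risk} must be > 0")
    excess = prevalence * (relative_risk - 1.0)
    return max(0.0, excess / (1.0 + excess))


def prevalence_proxy_af(prevalence: float) -> float:
    """Affected fraction when exposed risk is assumed equal to baseline."""
    if not 0.0 <= prevalence <= 1.0:
        raise InputDomainError(f"prevalence {prevalence} outside [0, 1]")
    return prevalence


def malaria_af(
    exposure_fraction: float,
    placental_rate: float = PLACENTAL_MALARIA_RATE,
    odds_ratio: float = OR_PLACENTAL_MALARIA,
) -> float:
    """Fraction of antepartum stillbirths attributable to placental malaria.

    ``placental_rate`` defaults to the primigravida figure (27.8%); lower
    parity-specific rates (20.8% second pregnancy, 15.6% higher order) can
    be substituted via the registry config.
    """
    if not 0.0 <= placental_rate <= 1.0:
        raise InputDomainError(f"placental rate {placental_rate} outside [0, 1]")
    return paf(exposure_fraction * placental_rate, odds_ratio)


def resolve_affected_fraction(
    spec: AffectedFractionSpec, profile, timing: Timing
) -> AffectedFraction:
    """Dispatch an affected-fraction rule against a country profile.

    ``profile`` must expose a ``prevalences`` mapping (a CountryProfile or
    anything duck-typed like one).
    """
    if spec.rule == AFRule.ALL:
        return AffectedFraction(1.0, timing, spec.rule)

    key = spec.prevalence_key
    prevalences = profile.prevalences
    if key in prevalences:
        p = float(prevalences[key])
    elif key in DEFAULT_PREVALENCES:
        p = DEFAULT_PREVALENCES[key]
    else:
        raise ConfigurationError(
            f"profile does not supply prevalence field {key!r} required by "
            f"affected-fraction rule {spec.rule.value}"
        )

    if spec.rule == AFRule.PREVALENCE_PROXY:
        value = prevalence_proxy_af(p)
    elif spec.rule == AFRule.PAF:
        value = paf(p, spec.relative_risk)
    elif spec.rule == AFRule.MALARIA_COMPOSITE:
        rate = spec.extra.get("placental_malaria_rate", PLACENTAL_MALARIA_RATE)
        value = malaria_af(p, placental_rate=rate, odds_ratio=spec.relative_risk)
    else:  # pragma: no cover - enum is exhaustive
        raise ConfigurationError(f"unknown affected-fraction rule {spec.rule}")
    return AffectedFraction(value, timing, spec.rule)
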