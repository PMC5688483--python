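"""Baseline-coverage proxy rules.

Population-based coverage data exist for almost none of the modelled
interventions, so baseline coverage is imputed from antenatal-care and
facility-delivery indicators using expert-opinion step rules.  All rules
are pure functions; the engine echoes their outputs into reports so the
imputation is transparent.

Tier boundaries are half-open with the boundary assigned to the upper tier
(the published labels overlap at 30/50/95% and 40/75/95%), which makes the
rules deterministic at the cut points.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputDomainError

#: (facility-delivery threshold, BEmOC share, CEmOC share) - shares are of
#: facility deliveries, evaluated bottom tier first.
_EMOC_TIERS = [
    (0.30, 0.00, 0.10),
    (0.50, 0.30, 0.20),
    (0.95, 0.15, 0.60),
    (float("inf"), 0.00, 1.00),
]

#: (ANC4+ threshold, share of ANC4+ attenders screened and treated)
_SYPHILIS_TIERS = [
    (0.40, 0.20),
    (0.75, 0.50),
    (0.95, 0.70),
    (float("inf"), 1.00),
]


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise InputDomainError(f"{name}={value} outside [0, 1]")


@dataclass(frozen=True)
class ChildbirthMix:
    """Four-way, mutually exclusive split of all births by childbirth care.

    Components are fractions of all births and sum to 1: home delivery
    without a skilled attendant, skilled attendance outside emergency
    obstetric care facilities, BEmOC facility and CEmOC facility.
    """

    home_no_sba: float
    sba_outside: float
    bemoc: float
    cemoc: float

    def __post_init__(self) -> None:
        for name in ("home_no_sba", "sba_outside", "bemoc", "cemoc"):
            _check_fraction(name, getattr(self, name))
        total = self.home_no_sba + self.sba_outside + self.bemoc + self.cemoc
        if abs(total - 1.0) > 1e-9:
            raise InputDomainError(f"childbirth mix sums to {total}, not 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "home_no_sba": self.home_no_sba,
            "sba_outside": self.sba_outside,
            "bemoc": self.bemoc,
            "cemoc": self.cemoc,
        }


def syphilis_coverage_from_anc4(anc4: float) -> float:
    """Baseline syphilis screening/treatment coverage as a step share of ANC4+.

    The share of ANC4+ attenders assumed to receive the intervention rises
    with ANC4+ coverage itself: 20% below 40% ANC4+, 50% to 75%, 70% to
    95%, and 100% above 95%.
    """
    _check_fraction("anc4", anc4)
    for threshold, share in _SYPHILIS_TIERS:
        if anc4 < threshold:
            return share * anc4
    raise AssertionError("unreachable")  # pragma: no cover


def anc_condition_coverage(anc4: float, share: float = 0.05) -> float:
    """Baseline coverage of ANC-detected conditions (diabetes, hypertensive
    disorders): a small fixed share of ANC4+ attenders."""
    _check_fraction("anc4", anc4)
    _check_fraction("share", share)
    return share * anc4


def childbirth_mix_from_facility(facility_rate: float, sba_rate: float) -> ChildbirthMix:
    """Impute the four-way childbirth-care mix from facility and SBA rates.

    BEmOC/CEmOC shares of *facility* deliveries step with the facility
    delivery rate; skilled attendance outside those facilities absorbs the
    remaining skilled births and home-without-SBA the rest.  Components are
    floored at zero and renormalised to sum to one.
    """
    _check_fraction("facility_rate", facility_rate)
    _check_fraction("sba_rate", sba_rate)
    if facility_rate > sba_rate:
        raise InputDomainError(
            f"facility_rate {facility_rate} exceeds sba_rate {sba_rate}"
        )
    for threshold, bemoc_share, cemoc_share in _EMOC_TIERS:
        if facility_rate < threshold:
            break
    bemoc = bemoc_share * facility_rate
    cemoc = cemoc_share * facility_rate
    sba_outside = sba_rate - (bemoc + cemoc)
    home = 1.0 - sba_rate
    parts = [max(0.0, x) for x in (home, sba_outside, bemoc, cemoc)]
    total = sum(parts)
    parts = [x / total for x in parts]
    return ChildbirthMix(
        home_no_sba=parts[0], sba_outside=parts[1], bemoc=parts[2], cemoc=parts[3]
    )


def induction_coverage_cap(requested: float, cemoc: float) -> float:
    """Cap post-term induction coverage at the CEmOC delivery share.

    Induction without accurate pregnancy dating and surgical back-up risks
    iatrogenic harm, so the model only allows it for CEmOC-facility births.
    """
    _check_fraction("requested", requested)
    _check_fraction("cemoc", cemoc)
    return min(requested, cemoc)
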