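"""Individual-level Monte-Carlo oracle for the deterministic engine, plus a
synthetic country-profile generator.

Each simulated pregnancy draws risk-factor exposures independently
(Bernoulli at the profile prevalences), a childbirth-care package from the
four-way delivery mix, and intervention receipt (Bernoulli at coverage,
independent of exposure by default).  Risks multiply on the probability
scale, clamped at 1.  For attributable-fraction interventions the received
intervention scales the *excess* risk of exposed pregnancies,
(RR - 1) -> (RR - 1)(1 - E): effectiveness is defined against the deaths
attributable to the exposure, so a fully covered population returns exposed
women to an RR of 1 + (RR - 1)(1 - E), not to (1 - E) times the exposed
risk.  For whole-population interventions the received intervention scales
the whole risk by (1 - E).

With independent exposures these semantics reproduce the engine's
multiplicative residual cascade in expectation, which is what makes the
cohort a valid oracle for the deterministic arithmetic.

All draws come from one seeded generator per cohort; the draw order is
fixed and independent of parameter values, so two configs differing only in
coverage share every exposure and outcome uniform (common random numbers),
which the agreement suite exploits for variance reduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .coverage import ChildbirthMix, childbirth_mix_from_facility
from .engine import (
    CountryProfile,
    averted_fraction,
    baseline_coverage,
    childbirth_impact,
    resolve_base_mix,
)
from .epi import DEFAULT_PREVALENCES, resolve_affected_fraction
from .errors import InputDomainError
from .registry import (
    AFRule,
    CoverageRule,
    InterventionSpec,
    PLACENTAL_MALARIA_RATE,
    Timing,
    load_default_interventions,
)


@dataclass(frozen=True)
class SimConfig:
    """One cohort run: who is exposed, who is covered, at what baseline risk.

    ``baseline_risk_ap`` is the antepartum stillbirth probability for an
    unexposed pregnancy; ``baseline_risk_ip`` the intrapartum probability
    for a home delivery without a skilled attendant, applied to pregnancies
    that survive the antepartum period.
    """

    n: int
    seed: int
    baseline_risk_ap: float
    baseline_risk_ip: float
    profile: CountryProfile
    coverage: Mapping[str, float] = field(default_factory=dict)
    mix: ChildbirthMix | None = None
    registry: tuple[InterventionSpec, ...] | None = None
    #: receipt probability among the exposed = coverage x this ratio
    #: (1.0 = receipt independent of exposure)
    exposure_coverage_ratio: float = 1.0


@dataclass(frozen=True)
class StratumCounts:
    exposed_n: int
    unexposed_n: int
    exposed_ap: int
    unexposed_ap: int
    exposed_ip: int
    unexposed_ip: int


@dataclass(frozen=True)
class CohortCounts:
    n: int
    antepartum: int
    intrapartum: int
    livebirths: int
    strata: Mapping[str, StratumCounts]
    delivery: Mapping[str, tuple[int, int]]  # category -> (births, ip deaths)


def _current_specs(config: SimConfig) -> list[InterventionSpec]:
    specs = (
        list(config.registry)
        if config.registry is not None
        else load_default_interventions()
    )
    return [s for s in specs if s.status == "current"]


def simulate_cohort(config: SimConfig) -> CohortCounts:
    """Simulate one pregnancy cohort; fully determined by ``config.seed``."""
    if config.n < 1:
        raise InputDomainError(f"n={config.n} must be >= 1")
    for name in ("baseline_risk_ap", "baseline_risk_ip"):
        value = getattr(config, name)
        if not 0.0 <= value <= 1.0:
            raise InputDomainError(f"{name}={value} outside [0, 1]")

    n = config.n
    rng = np.random.default_rng(config.seed)
    prevalences = dict(DEFAULT_PREVALENCES)
    prevalences.update(config.profile.prevalences)

    mult_ap = np.ones(n)
    mult_ip = np.ones(n)
    exposure_masks: dict[str, np.ndarray] = {}

    specs = [
        s
        for s in _current_specs(config)
        if s.coverage_rule != CoverageRule.CHILDBIRTH_MIX
    ]
    # fixed draw order per spec, independent of coverage values (CRN-safe)
    for spec in specs:
        cov = float(config.coverage.get(spec.id, 0.0))
        rule = spec.af_spec.rule
        u_receipt = rng.random(n)
        if rule == AFRule.ALL:
            got = u_receipt < cov
            exposed = np.ones(n, dtype=bool)
        else:
            p = float(prevalences.get(spec.af_spec.prevalence_key, 0.0))
            exposed = rng.random(n) < p
            if rule == AFRule.MALARIA_COMPOSITE:
                rate = spec.af_spec.extra.get(
                    "placental_malaria_rate", PLACENTAL_MALARIA_RATE
                )
                exposed &= rng.random(n) < rate
            cov_exposed = min(1.0, cov * config.exposure_coverage_ratio)
            got = np.where(exposed, u_receipt < cov_exposed, u_receipt < cov)
        exposure_masks[spec.id] = exposed

        e_ap = spec.antepartum_effect.point if spec.antepartum_effect else None
        e_ip = spec.intrapartum_effect.point if spec.intrapartum_effect else None
        for e, mult in ((e_ap, mult_ap), (e_ip, mult_ip)):
            if e is None:
                continue
            if rule in (AFRule.PAF, AFRule.MALARIA_COMPOSITE):
                rr = spec.af_spec.relative_risk
                m = np.where(exposed, 1.0 + (rr - 1.0) * (1.0 - e * got), 1.0)
            elif rule == AFRule.PREVALENCE_PROXY:
                m = np.where(exposed & got, 1.0 - e, 1.0)
            else:  # ALL
                m = np.where(got, 1.0 - e, 1.0)
            mult *= m

    # childbirth-care package, relative risks vs home delivery without SBA
    mix = config.mix if config.mix is not None else resolve_base_mix(config.profile)
    cb_specs = {
        s.id: s.intrapartum_effect.point
        for s in _current_specs(config)
        if s.coverage_rule == CoverageRule.CHILDBIRTH_MIX
    }
    categories = ["home_no_sba", "sba_outside", "bemoc", "cemoc"]
    shares = np.array([getattr(mix, c) for c in categories])
    edges = np.cumsum(shares)
    cat_index = np.searchsorted(edges, rng.random(n), side="right")
    cat_index = np.minimum(cat_index, len(categories) - 1)
    cat_mult = np.array([1.0] + [1.0 - cb_specs[c] for c in categories[1:]])
    mult_ip = mult_ip * cat_mult[cat_index]

    risk_ap = np.clip(config.baseline_risk_ap * mult_ap, 0.0, 1.0)
    risk_ip = np.clip(config.baseline_risk_ip * mult_ip, 0.0, 1.0)
    ap_death = rng.random(n) < risk_ap
    ip_death = ~ap_death & (rng.random(n) < risk_ip)

    strata = {}
    for spec_id, exposed in exposure_masks.items():
        strata[spec_id] = StratumCounts(
            exposed_n=int(exposed.sum()),
            unexposed_n=int((~exposed).sum()),
            exposed_ap=int(ap_death[exposed].sum()),
            unexposed_ap=int(ap_death[~exposed].sum()),
            exposed_ip=int(ip_death[exposed].sum()),
            unexposed_ip=int(ip_death[~exposed].sum()),
        )
    delivery = {
        c: (int((cat_index == i).sum()), int(ip_death[cat_index == i].sum()))
        for i, c in enumerate(categories)
    }
    ap = int(ap_death.sum())
    ip = int(ip_death.sum())
    return CohortCounts(
        n=n,
        antepartum=ap,
        intrapartum=ip,
        livebirths=n - ap - ip,
        strata=strata,
        delivery=delivery,
    )


# ---------------------------------------------------------------------------
# Synthetic country profiles

_ARCHETYPES = ("high-burden", "transition", "low-burden")


def _round6(x: float) -> float:
    return float(round(float(x), 6))


def generate_profile_fixture(seed: int, archetype: str = "high-burden") -> CountryProfile:
    """Deterministic, archetype-plausible synthetic country profile.

    Archetypes bracket the settings the model is used in: ``high-burden``
    (SBR 20-35, weak antenatal and childbirth care, endemic malaria),
    ``transition`` (SBR 10-20) and ``low-burden`` (SBR 3-10, near-universal
    skilled attendance).  The same seed always yields the same profile.
    """
    if archetype not in _ARCHETYPES:
        raise InputDomainError(f"archetype {archetype!r} not in {_ARCHETYPES}")
    rng = np.random.default_rng([seed, _ARCHETYPES.index(archetype)])

    def u(lo: float, hi: float) -> float:
        return _round6(rng.uniform(lo, hi))

    if archetype == "high-burden":
        sbr_value = u(20.0, 35.0)
        prop_ip = u(0.35, 0.60)
        anc4 = u(0.30, 0.60)
        sba_rate = u(0.30, 0.65)
        facility = _round6(sba_rate * rng.uniform(0.55, 0.90))
        iptp = u(0.10, 0.50)
        prev = {
            "untreated_syphilis": u(0.010, 0.050),
            "diabetes": u(0.020, 0.080),
            "severe_hdp": u(0.020, 0.060),
            "malaria_exposure": u(0.20, 0.60),
            "poverty": u(0.30, 0.70),
        }
    elif archetype == "transition":
        sbr_value = u(10.0, 20.0)
        prop_ip = u(0.25, 0.45)
        anc4 = u(0.50, 0.80)
        sba_rate = u(0.60, 0.90)
        facility = _round6(sba_rate * rng.uniform(0.70, 0.95))
        iptp = u(0.05, 0.30)
        prev = {
            "untreated_syphilis": u(0.005, 0.020),
            "diabetes": u(0.030, 0.090),
            "severe_hdp": u(0.020, 0.050),
            "malaria_exposure": u(0.05, 0.30),
            "poverty": u(0.10, 0.40),
        }
    else:
        sbr_value = u(3.0, 10.0)
        prop_ip = u(0.10, 0.30)
        anc4 = u(0.80, 0.98)
        sba_rate = u(0.90, 1.00)
        facility = _round6(sba_rate * rng.uniform(0.90, 1.00))
        iptp = u(0.00, 0.10)
        prev = {
            "untreated_syphilis": u(0.001, 0.010),
            "diabetes": u(0.040, 0.100),
            "severe_hdp": u(0.015, 0.040),
            "malaria_exposure": u(0.00, 0.05),
            "poverty": u(0.00, 0.10),
        }
    prev["prolonged_pregnancy"] = DEFAULT_PREVALENCES["prolonged_pregnancy"]
    return CountryProfile(
        name=f"synthetic-{archetype}-{seed}",
        births_per_year=float(int(rng.uniform(2e5, 2e6))),
        sbr=sbr_value,
        prop_intrapartum=prop_ip,
        prevalences=prev,
        baseline_indicators={
            "anc4": anc4,
            "sba": sba_rate,
            "facility_delivery": facility,
            "iptp_or_itn": iptp,
        },
    )


# ---------------------------------------------------------------------------
# Engine-vs-microsim agreement suite

#: scale-up targets used by the agreement suite (fixed study conditions)
_CHECK_TARGET = 0.9
_CHECK_FACILITY_TARGET = 0.95
_CHECK_SBA_TARGET = 0.98


def engine_microsim_agreement(
    profile: CountryProfile,
    n: int = 1_000_000,
    seed: int = 0,
    registry: Iterable[InterventionSpec] | None = None,
) -> pd.DataFrame:
    """Compare deterministic per-intervention averted counts with the cohort.

    For each intervention a baseline and a scaled-up cohort are simulated
    with common random numbers (same seed); the microsim averted count is
    the paired difference in deaths, and the engine's count is its averted
    fraction applied to the simulated baseline compartment.  The ``se``
    column is the count-based Monte-Carlo standard error
    sqrt(D_base + D_target) summed over the timings the intervention
    touches, which is conservative for the paired estimator.  Childbirth
    care is compared through the renormalised impact form, the one that
    matches individual-level incremental deaths at non-zero baseline
    facility coverage.
    """
    specs = [
        s
        for s in (
            list(registry) if registry is not None else load_default_interventions()
        )
        if s.status == "current"
    ]
    cascade_specs = [s for s in specs if s.coverage_rule != CoverageRule.CHILDBIRTH_MIX]

    base_mix = resolve_base_mix(profile)
    cov_base = {s.id: baseline_coverage(s, profile, base_mix) for s in cascade_specs}
    # the induction default baseline saturates its CEmOC cap; use a sub-cap
    # baseline so the intervention has room to move
    if "induction" in cov_base:
        cov_base["induction"] = 0.5 * base_mix.cemoc
    cov_target = {}
    for s in cascade_specs:
        target = max(_CHECK_TARGET, cov_base[s.id])
        if s.id == "induction":
            target = min(target, base_mix.cemoc)  # cap binds, mix is static
        cov_target[s.id] = target
    target_mix = childbirth_mix_from_facility(
        _CHECK_FACILITY_TARGET, _CHECK_SBA_TARGET
    )

    overall = profile.sbr if profile.sbr is not None else sbr_from_counts(profile)
    q = overall / 1000.0
    risk_ap = q * (1.0 - profile.prop_intrapartum)
    risk_ip = q * profile.prop_intrapartum

    def cfg(coverage: Mapping[str, float], mix: ChildbirthMix) -> SimConfig:
        return SimConfig(
            n=n,
            seed=seed,
            baseline_risk_ap=risk_ap,
            baseline_risk_ip=risk_ip,
            profile=profile,
            coverage=coverage,
            mix=mix,
            registry=tuple(specs),
        )

    base = simulate_cohort(cfg(cov_base, base_mix))
    rows = []
    for s in cascade_specs:
        cov = dict(cov_base)
        cov[s.id] = cov_target[s.id]
        run = simulate_cohort(cfg(cov, base_mix))
        engine = sim = 0.0
        var = 0.0
        for timing, d_base, d_run in (
            (Timing.ANTEPARTUM, base.antepartum, run.antepartum),
            (Timing.INTRAPARTUM, base.intrapartum, run.intrapartum),
        ):
            eff = s.effect(timing)
            if eff is None:
                continue
            af = resolve_affected_fraction(s.af_spec, profile, timing).value
            frac = averted_fraction(eff.point, cov_base[s.id], cov_target[s.id], af)
            engine += frac * d_base
            sim += d_base - d_run
            var += d_base + d_run
        rows.append((s.id, engine, sim, float(np.sqrt(var))))

    run = simulate_cohort(cfg(cov_base, target_mix))
    frac = (
        childbirth_impact(base.intrapartum, base_mix, target_mix, renormalise=True)
        / base.intrapartum
        if base.intrapartum
        else 0.0
    )
    rows.append(
        (
            "childbirth",
            frac * base.intrapartum,
            float(base.intrapartum - run.intrapartum),
            float(np.sqrt(base.intrapartum + run.intrapartum)),
        )
    )

    df = pd.DataFrame(rows, columns=["intervention", "engine", "microsim", "se"])
    df["z"] = np.where(df["se"] > 0, (df["engine"] - df["microsim"]) / df["se"], 0.0)
    df["within_3se"] = (df["engine"] - df["microsim"]).abs() <= 3.0 * df["se"]
    return df


def sbr_from_counts(profile: CountryProfile) -> float:
    return 1000.0 * profile.stillbirth_count() / profile.births_per_year
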