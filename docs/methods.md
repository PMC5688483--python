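# Methods

## Model structure

The model is linear and deterministic. A country-year has a fixed
stillbirth envelope (≥28 weeks / ≥1000 g), supplied either as a count or as
a rate per 1000 total births, and split by a single `prop_intrapartum`
parameter into antepartum and intrapartum compartments. Mortality rates and
the envelope are static: nothing changes dynamically except intervention
coverage, so with no coverage change the projected stillbirth rate is
constant across all years.

For each intervention and compartment the single-intervention averted
fraction is `E × ΔC × AF`:

* **E (effectiveness)** — fraction-reduction in stillbirth risk, stored in
  the registry. For relative-risk sources E = 1 − RR (so micronutrient
  supplementation carries E = 0.08 from RR 0.92, despite a narrative "9%
  reduction" rounding elsewhere; the RR is the primary estimate). For
  Delphi sources E is the elicited percentage. Post-term induction uses the
  all-cause perinatal-death RR 0.31 (E = 0.69) rather than the underpowered
  stillbirth-only estimate.
* **ΔC (coverage change)** — target minus baseline coverage, interpolated
  linearly across projection years (or a step jump). Negative changes are
  allowed and increase deaths symmetrically.
* **AF (affected fraction)** — the share of the compartment's stillbirths
  the intervention can act on: 1.0 for whole-population interventions and
  childbirth care; the population attributable fraction
  `p(RR−1)/(1+p(RR−1))` where prevalence and relative risk are known
  (clamped at 0 for RR < 1 — an AF is a proportion of deaths); the bare
  prevalence where only prevalence is known (a deliberate underestimate);
  and for malaria a composite of falciparum-exposure fraction × the
  placental-malaria rate (default 27.8%, the primigravida figure; 20.8%
  and 15.6% parity-specific alternatives are exposed as overrides), with
  the placental-malaria odds ratio 2.19 used directly as a relative risk
  (stillbirth is rare enough for OR ≈ RR). Malaria impact applies
  regardless of parity; the hypertensive-disorders relative risk (2.1) has
  no citable source and should be treated as soft.

Timing applicability: syphilis and malaria act on antepartum stillbirths
only; the three childbirth packages on intrapartum only; micronutrient,
balanced energy, diabetes, hypertensive-disorder management and induction
on both compartments. The post-term prevalence defaults to 7.5% of
pregnancies when a profile does not supply it.

## Combining interventions

The source arithmetic is defined only for single interventions. Within a
compartment this package combines interventions as a multiplicative
residual cascade:

    residual = deaths × Π_i (1 − E_i AF_i ΔC_i)

which is independent of intervention order (the product is evaluated over
sorted factors, making it bit-for-bit order-invariant) and can never avert
more than the compartment. The jointly averted total is attributed to
interventions in proportion to their single-intervention fractions, and the
attributed sum plus the residual reproduces the envelope exactly (the last
attribution absorbs float round-off). When coverage falls, the residual may
exceed the envelope; we keep exact conservation rather than clamping the
residual at the envelope, since the two are incompatible and a symmetric,
conserving account is the more transparent one.

Childbirth care is applied to the intrapartum compartment *first*, as a
linear sum over the three package coverage shifts, and the remaining
interventions then cascade on what is left. Because the childbirth form is
linear while the cascade is multiplicative, this order matters and is
fixed.

### Plain vs renormalised childbirth impact

The default childbirth form, `ip_deaths × Σ_c E_c ΔC_c`, applies coverage
changes directly to the observed envelope. When baseline facility coverage
is substantial, the observed envelope already reflects the baseline mix, so
the same absolute shift corresponds to more incremental deaths among those
still at home-level risk; the renormalised mode divides by
`1 − Σ_c E_c C_c(base)` to express exactly that. Both coincide when the
baseline is all-home (as in the canonical worked examples). The plain form
is the default because it mirrors the published arithmetic; the
renormalised mode (`--renormalise-childbirth`) is the one that matches an
individual-level cohort and is used by the microsimulation agreement suite.
The analogous renormalisation for the cascade interventions is negligible
at realistic parameter values (the correction is of order `AF·E·C_base`,
a few percent of an already small term) and is not applied.

## Coverage imputation

Direct coverage data exist essentially only for malaria (IPTp 2+ doses,
else ITN use). Other baselines are imputed by expert-opinion step rules,
echoed into reports for transparency:

* syphilis screening/treatment: a stepwise share of ANC4+ coverage
  (20% of ANC4+ below 40%, 50% to 75%, 70% to 95%, 100% above 95%);
* diabetes and hypertensive-disorder management: 5% of ANC4+;
* micronutrient and balanced energy supplementation: zero;
* induction: the CEmOC delivery share (all CEmOC births assumed to have
  access), and *capped* at the CEmOC share in scenarios — without reliable
  pregnancy dating and surgical backup the intervention can harm;
* childbirth mix: BEmOC/CEmOC shares of *facility* deliveries step with the
  facility-delivery rate (0%/10% below 30% facility delivery, 30%/20% to
  50%, 15%/60% to 95%, 0%/100% above). Interpreting the shares as shares of
  all births would exceed the facility rate in low-coverage tiers, so the
  facility-delivery interpretation is used. Facility births not assigned to
  BEmOC/CEmOC are counted with "skilled attendance outside BEmOC/CEmOC",
  and the four components are floored at zero and renormalised to sum to 1.
  Published tier labels overlap at the boundaries; boundaries (0.30, 0.50,
  0.95 facility; 0.40, 0.75, 0.95 ANC4+) belong to the upper tier.

A profile may override any imputation with a direct per-intervention entry
in `baseline_indicators`.

## Microsimulation oracle

`microsim.simulate_cohort` draws, per pregnancy: independent Bernoulli
risk-factor exposures at profile prevalences; a childbirth-care package
from the four-way mix; and Bernoulli intervention receipt at coverage,
independent of exposure by default (`exposure_coverage_ratio` lets users
model the likely lower receipt among exposed women). Risks multiply on the
probability scale and are clamped at 1. Receipt semantics follow the
definition of effectiveness: for attributable-fraction interventions the
intervention scales the *excess* risk of exposed pregnancies,
(RR−1) → (RR−1)(1−E) — effectiveness is defined against attributable
deaths, and this is the semantics under which full coverage of a
0.82-effective intervention averts 82% of attributable deaths, matching
the worked example. Whole-population interventions scale the whole risk by
(1−E). With independent exposures, expected deaths factorise per risk
factor, which reproduces the engine's multiplicative cascade in
expectation — this is what makes the cohort a valid oracle.

The agreement suite simulates, per profile, one baseline cohort and one
scaled-up cohort per intervention with **common random numbers** (same
seed, fixed draw order), so the paired difference in deaths is a low-noise
estimate of deaths averted. The acceptance band is 3× the count-based
Monte-Carlo standard error `sqrt(D_base + D_target)` per timing — the
standard error of the unpaired cohort estimate, conservative for the
paired one. Cohorts are 10^6 pregnancies across 20 synthetic profiles;
baseline antepartum/intrapartum risks are taken directly from the profile
SBR and timing split (for the unexposed, home-delivery stratum, so
realised cohort SBRs sit slightly above the nominal value — immaterial to
the agreement check). The induction default baseline saturates its CEmOC
cap, so the suite sets a sub-cap baseline (0.5× the CEmOC share) to give
the intervention room to move.

## Synthetic profiles

`generate_profile_fixture` emits deterministic profiles in three
archetypes — high-burden (SBR 20–35, ANC4+ 30–60%, endemic malaria),
transition (SBR 10–20) and low-burden (SBR 3–10, near-universal skilled
attendance) — with risk-factor prevalences in ranges a field
epidemiologist would recognise for each setting. They emulate the *inputs*
of real country profiles, not their correlation structure: exposures are
drawn independently, coverage indicators are not correlated with poverty,
and the envelope is internally consistent by construction. Passing tests
on these fixtures therefore validate the arithmetic and its
implementation, not the realism of any particular country estimate.

## Numerical choices and limitations

* Fractional deaths are carried at full precision; the CSV report keeps
  full precision (so the conservation invariant survives a round-trip) and
  only the human-readable summary rounds to whole deaths.
* Affected fractions of 1.0 are representable (childbirth care: "all
  intrapartum stillbirths").
* Cascade attribution with terms of mixed sign falls back to
  absolute-value weights when the signed weights cancel.
* Uncertainty intervals are out of scope: effect-estimate bounds are
  stored in the registry but not propagated.
* Stillbirth/early-neonatal misclassification, gestational-age-resolved
  survival, competing neonatal risks, and dynamic prevalence trends are
  not modelled.
* Country-level results depend entirely on the quality of user-supplied
  envelopes, timing splits and prevalences; the proxy coverage rules are
  expert opinion and known to correlate poorly with measured coverage
  (e.g. syphilis screening vs ANC4+).
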