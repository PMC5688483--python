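# liststill

Deterministic modelling of stillbirths averted by scaling up health
interventions, in the style of the Lives Saved Tool (LiST) stillbirth
sub-model, with an individual-level Monte-Carlo oracle for validation.

## Who this is for

An estimated 2.6 million babies are stillborn each year, half of them during
labour, and the Every Newborn Action Plan (ENAP) sets a target stillbirth
rate of ≤12 per 1000 total births in every country by 2030. Programme
planners need to ask: *if we scale up intervention X from its current
coverage to some target, how many stillbirths are averted, and does the
projected rate meet the target?* Because stillbirths lack cause-of-death
data, the model works with a fixed country "envelope" of stillbirths
(≥28 weeks), split only by timing — antepartum (before labour) and
intrapartum (during labour).

## The model

For one intervention acting on one timing compartment, the fraction of that
compartment averted is

    averted fraction = E × (C_target − C_base) × AF

where *E* is effectiveness (1 − RR from meta-analysis, or an expert Delphi
percentage), *C* is coverage, and *AF* is the **affected fraction** — the
share of the compartment's stillbirths the intervention can act on. Where a
risk factor's prevalence *p* and relative risk *RR* are known, the affected
fraction is the population attributable fraction

    PAF = p (RR − 1) / (1 + p (RR − 1));

where only prevalence is known, *AF = p*; for childbirth care, *AF = 1* (all
intrapartum stillbirths). The two canonical worked examples: syphilis
detection and treatment (E = 0.82) scaled 0 → 50% averts
0.82 × 0.5 = **41%** of syphilis-attributable antepartum stillbirths;
balanced energy supplementation (E = 0.40, AF = 20% food-insecure) scaled
0 → 50% averts 0.40 × 0.5 × 0.20 = **4%** of all antepartum stillbirths.

Eight interventions are modelled: multiple micronutrient supplementation,
balanced energy supplementation, malaria prevention (ITN/IPTp), syphilis
detection and treatment, diabetes management, management of hypertensive
disorders, induction for post-term pregnancy (capped at the CEmOC delivery
share), and childbirth care as three mutually exclusive packages (skilled
attendance outside emergency obstetric facilities, BEmOC, CEmOC; E = 0.23,
0.45, 0.75 vs home birth without a skilled attendant). Within a
compartment, interventions combine as a multiplicative residual cascade
(order-free, never averting more than 100%). Baseline coverages are imputed
from ANC4+ and facility-delivery indicators via documented step rules when
no direct data are supplied.

The `microsim` module is an independent oracle: it simulates individual
pregnancies (Bernoulli exposures, multiplicative risks, Bernoulli
intervention receipt) and checks that the deterministic arithmetic matches
cohort outcomes within Monte-Carlo error.

## Worked example

```bash
liststill run --profile examples/profile_highburden.yaml \
              --scenario examples/scenario_scaleup.yaml --out out/
```

prints (synthetic high-burden profile: 1 000 000 births/year, SBR 25, 45%
intrapartum; all eight interventions scaled up linearly to 2030):

```
Stillbirths averted projection
Envelope: 25000 stillbirths/year (45% intrapartum), 1000000 total births/year

  year   averted  residual     SBR  ENAP<=12
  2025         0     25000    25.0  no
  2026      1797     23203    23.2  no
  2027      3511     21489    21.5  no
  2028      5145     19855    19.9  no
  2029      6701     18299    18.3  no
  2030      8180     16820    16.8  no

Final-year stillbirth rate: 16.8 per 1000 total births (does not meet the
ENAP target of <=12 per 1000).
```

By 2030 the scenario averts ~8 180 of 25 000 annual stillbirths (33%),
taking the rate from 25.0 to 16.8 per 1000 — a large improvement that still
misses the ≤12 target, a typical finding for high-burden settings. The
accompanying `impact.csv` breaks the total down by year × intervention ×
timing (e.g. in 2030: CEmOC childbirth care ~3 341, balanced energy ~2 197
across both timings, syphilis ~1 159 antepartum), and `manifest.json`
records everything needed to reproduce the run.

Other subcommands: `liststill compare` (diff two scenarios),
`liststill validate` (check config files), `liststill fixtures` (emit
synthetic profiles), `liststill microsim-check` (engine-vs-cohort
agreement).

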