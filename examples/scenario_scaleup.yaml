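# Ambitious linear scale-up of all eight interventions to 2030.
name: demo-scaleup-2030
base_year: 2025
end_year: 2030
trajectory: linear
targets:
  syphilis: 0.80
  malaria: 0.80
  micronutrient: 0.50
  balanced_energy: 0.50
  diabetes: 0.30
  hdp: 0.30
  induction: 0.90          # capped at the CEmOC delivery share each year
  facility_delivery: 0.80  # drives the childbirth-care mix
  sba: 0.90
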