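# Synthetic high-burden country profile (illustrative values, not any real
# country). All fractions are decimals in [0, 1].
name: demo-high-burden
births_per_year: 1000000
sbr: 25.0                 # stillbirths per 1000 total births (>=28 weeks)
prop_intrapartum: 0.45    # share of stillbirths occurring during labour
prevalences:
  untreated_syphilis: 0.025
  diabetes: 0.04
  severe_hdp: 0.035
  malaria_exposure: 0.45
  poverty: 0.55
  prolonged_pregnancy: 0.075
baseline_indicators:
  anc4: 0.45
  sba: 0.50
  facility_delivery: 0.42
  iptp_or_itn: 0.25
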