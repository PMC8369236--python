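{
  "field_t": 3.0,
  "required_wd_cm": 2.0,
  "required_ddd_cm": 0.25,
  "energy_from_wd_mev": 141,
  "energy_from_ddd_mev": 148,
  "mc_wd_cm": 2.0,
  "mc_ddd_cm": 0.24
}
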