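{
  "label": "female",
  "total_energy_rate": 75.7,
  "cho_ox_rate": 4.4,
  "fat_ox_rate": 0.06,
  "glycogen_capacity": 499,
  "liver_glucose_total": 49,
  "duration": 120
}
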