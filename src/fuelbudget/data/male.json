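{
  "label": "male",
  "total_energy_rate": 88.3,
  "cho_ox_rate": 5.1,
  "fat_ox_rate": 0.07,
  "glycogen_capacity": 690,
  "liver_glucose_total": 68,
  "duration": 120
}
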