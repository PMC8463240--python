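# Mixed reference solution: mg of each diterpenoid per mL of methanol.
standards:
  L1: 0.1008
  L3: 0.1005
  L4: 0.1505
sample_prep:
  sample_mass: 0.5     # g of dried seed powder
  extract_volume: 50.0 # mL of 70% aqueous methanol
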