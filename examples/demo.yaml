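# Demo pipeline: toy pore with a 2 kBT hydrophobic water barrier and
# field-driven ions, followed by every analysis stage.
seed: 1
synth:
  n_waters: 400
  n_ions: 12
  water_barrier: 2.0
  field_tilt: 1.0
  n_steps: 20000
  save_stride: 40
stages: [hydration, current, pmf, conform, chain]
pmf_reference_slab: [0.5, 2.0]
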