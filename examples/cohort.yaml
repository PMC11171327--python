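# Demo cohort: a non-responding control arm and a deeply regressing
# combination arm, 8 animals each, weekly measurements to day 84.
model: DEMO-MRT
seed: 11
arms:
  - {name: control, n_animals: 8, archetype: PD}
  - {name: combo, n_animals: 8, archetype: MCR}
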