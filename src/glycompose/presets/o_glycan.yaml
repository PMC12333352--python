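# Compositional limits for mucin-type O-linked glycans.
# Applied on top of the default rule set; limits only tighten the space.
element_limits:
  hex: [0, 9]
  pent: [0, 0]
  nacetyl: [1, 10]    # core GalNAc minimum
  deoxy: [0, 4]
  neuac: [0, 6]
  sulfate: [0, 4]
  phosphate: [0, 1]
  oacetyl: [0, 2]
  omethyl: [0, 0]
  amino: [0, 0]
  carboxylicacid: [0, 0]
  anhydrobridge: [0, 0]
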