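# Compositional limits for mammalian N-linked glycans.
# Applied on top of the default rule set; limits only tighten the space.
# Keys are composition components: hex, pent, or modification names.
# Values are inclusive [min, max] total counts per composition.
element_limits:
  hex: [3, 12]        # chitobiose + mannose core requires >= 3 hexoses
  pent: [0, 0]        # mammalian N-glycans do not contain pentoses
  nacetyl: [2, 8]     # two core GlcNAc minimum
  deoxy: [0, 3]       # core/antenna fucosylation
  neuac: [0, 4]       # terminal sialylation
  sulfate: [0, 4]
  phosphate: [0, 2]
  oacetyl: [0, 2]
  omethyl: [0, 0]
  amino: [0, 0]
  carboxylicacid: [0, 0]
  anhydrobridge: [0, 0]
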