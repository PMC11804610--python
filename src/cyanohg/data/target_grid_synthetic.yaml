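# SYNTHETIC stand-in for the published 88-structure HG target grid.
#
# The authoritative grid is a supplementary table not bundled with this
# package. This stand-in reconstructs it from what the main article text
# states: an 80-structure core grid (4 headgroups x 4 even chain lengths x
# the 5 usual functionalization classes) plus 8 additional structures of
# the kinds the text names explicitly -- odd-chain hexose HGs (C27 diol,
# C29 keto-ol), an unknown C6 sugar (modeled as a hexose isomer), pentose
# HG30 keto-triol, monofunctional HGs, and an HG with four functional
# groups. Chain assignments for the unnamed extras are fixed choices of
# this package, not published values.
headgroups: [hexose, pentose, methylhexose, deoxyhexose]
chains: [26, 28, 30, 32]
patterns: [diol, keto-ol, keto-diol, triol, diketo-ol]
exclusions: []
extras:
  - [hexose, 27, diol]
  - [hexose, 29, keto-ol]
  - [pentose, 30, keto-triol]
  - [hexose_isomer, 26, diol]
  - [hexose_isomer, 28, keto-ol]
  - [hexose, 26, ol]
  - [hexose, 28, ol]
  - [hexose, 32, keto-triol]
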