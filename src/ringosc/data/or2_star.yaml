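# 3-node ring with a weakened repressor binding site on node 3 (CI-like):
# raised half-repression constant and reduced cooperativity. The magnitude
# of the shift is a free knob; these values are the fixture defaults.
name: or2_star
n: 3
nodes:
  - {}
  - {}
  - {K: 25.0, nu: 1.5}
g: 5.0
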