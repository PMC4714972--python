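# 3-node ring, untagged proteins: no active degradation, removal by
# dilution only (b = 0).
name: 3n_untagged
n: 3
symmetric: true
nodes:
  - {b: 0.0}
g: 5.0
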