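# 3-node ring, degradation-tagged proteins (default protein half-life 90 min).
name: 3n_tagged
n: 3
symmetric: true
nodes:
  - {}
g: 5.0
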