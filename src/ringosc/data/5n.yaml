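# Symmetric 5-node ring oscillator.
name: 5n
n: 5
symmetric: true
nodes:
  - {}
g: 5.0
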