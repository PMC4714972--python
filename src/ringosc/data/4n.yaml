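# Symmetric 4-node ring: even loop, behaves as a bistable switch.
name: 4n
n: 4
symmetric: true
nodes:
  - {}
g: 5.0
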