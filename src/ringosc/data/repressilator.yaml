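# Symmetric 3-node repression ring, ssrA-tagged proteins, default kinetics.
name: repressilator
n: 3
symmetric: true
nodes:
  - {}
g: 5.0
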