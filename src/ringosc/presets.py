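"""Bundled ring-network fixtures.

All fixtures default to the standard simulation parameter set (mRNA
half-life 8 min, tagged-protein half-life 90 min, beta = 0.4, c = 0.5,
K = 5 nM, nu = 2, g = 5 nM):

- ``repressilator``: symmetric 3-node ring, ssrA-tagged proteins.
- ``or2_star``: 3-node ring with weakened CI operator binding on one node
  (raised K, lowered cooperativity); the exact mutant shift is not known,
  so the fixture values (K x5, nu 1.5) are adjustable knobs.
- ``3n_tagged`` / ``3n_untagged``: 3-node rings differing only in the
  protein degradation rate (ln2/90 vs 0 -- removal by dilution only).
- ``4n``: symmetric 4-node ring (bistable, not oscillatory).
- ``5n``: symmetric 5-node ring.
"""

from __future__ import annotations

from importlib import resources

from .network import RingNetwork

BUILTIN_NAMES = ("repressilator", "or2_star", "3n_tagged", "3n_untagged", "4n", "5n")


def builtin_network(name: str) -> RingNetwork:
    """Load one of the bundled network fixtures by name."""
    from .io import parse_network_spec
    import yaml

    if name not in BUILTIN_NAMES:
        raise KeyError(f"unknown builtin network {name!r}; choose from {BUILTIN_NAMES}")
    text = resources.files("ringosc.data").joinpath(f"{name}.yaml").read_text()
    return parse_network_spec(yaml.safe_load(text))
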