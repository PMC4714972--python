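"""Readers and writers for the package's file formats.

Formats (all plain text; time unit minutes, concentrations nM):

- network spec (YAML or JSON): ``{name, n, symmetric, nodes: [...], g}``
  where each node record may set ``a, b, c, beta, K, nu``; absent fields
  default to the standard simulation parameters, and ``symmetric: true``
  expands a single node record to all n nodes.
- trajectory CSV ``time_min,r1..rn,p1..pn`` with a JSON metadata sidecar.
- fluorescence trace CSV ``time_min,Pf_nM`` with a sidecar
  ``{dil, dt_min, mat_per_min, label}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import (DEFAULT_A, DEFAULT_B, DEFAULT_BETA, DEFAULT_C,
                      DEFAULT_G, DEFAULT_K, DEFAULT_NU, RingNetwork)
from .simulate import Trajectory
from .transfer import FluorescenceTrace

__all__ = [
    "read_network_spec", "parse_network_spec", "write_network_spec",
    "write_trajectory", "read_trajectory",
    "write_trace", "read_trace",
]

_NODE_DEFAULTS = {"a": DEFAULT_A, "b": DEFAULT_B, "c": DEFAULT_C,
                  "beta": DEFAULT_BETA, "K": DEFAULT_K, "nu": DEFAULT_NU}


def parse_network_spec(doc: dict) -> RingNetwork:
    """Build a RingNetwork from a parsed spec document."""
    if not isinstance(doc, dict):
        raise ValueError("network spec must be a mapping")
    try:
        n = int(doc["n"])
    except KeyError:
        raise ValueError("network spec is missing required field 'n'") from None
    nodes = doc.get("nodes", [{}])
    if not isinstance(nodes, list) or not all(isinstance(nd, dict) for nd in nodes):
        raise ValueError("field 'nodes' must be a list of mappings")
    if doc.get("symmetric", False) or len(nodes) == 1:
        nodes = [dict(nodes[0])] * n
    if len(nodes) != n:
        raise ValueError(f"field 'nodes' has {len(nodes)} records, expected {n}")
    vectors = {}
    for key, default in _NODE_DEFAULTS.items():
        vals = []
        for i, nd in enumerate(nodes):
            unknown = set(nd) - set(_NODE_DEFAULTS)
            if unknown:
                raise ValueError(f"unknown field(s) {sorted(unknown)} in node {i + 1}")
            v = float(nd.get(key, default))
            vals.append(v)
        vectors[key] = np.array(vals)
    g = float(doc.get("g", DEFAULT_G))
    return RingNetwork(n=n, g=g, name=str(doc.get("name", "ring")), **vectors)


def read_network_spec(path) -> RingNetwork:
    """Read a YAML or JSON network spec file."""
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return parse_network_spec(doc)


def write_network_spec(net: RingNetwork, path) -> None:
    path = Path(path)
    nodes = [{k: float(getattr(net, k)[i]) for k in _NODE_DEFAULTS}
             for i in range(net.n)]
    doc = {"name": net.name, "n": net.n, "nodes": nodes, "g": float(net.g)}
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=1))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_trajectory(traj: Trajectory, csv_path) -> None:
    csv_path = Path(csv_path)
    n = traj.n
    cols = {"time_min": traj.times}
    cols.update({f"r{i + 1}": traj.r[:, i] for i in range(n)})
    cols.update({f"p{i + 1}": traj.p[:, i] for i in range(n)})
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.12g")
    _sidecar(csv_path).write_text(json.dumps(traj.net_ref, indent=1, default=float))


def read_trajectory(csv_path) -> Trajectory:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if "time_min" not in df.columns:
        raise ValueError("trajectory CSV is missing the 'time_min' column")
    r_cols = sorted((c for c in df.columns if c.startswith("r") and c[1:].isdigit()),
                    key=lambda c: int(c[1:]))
    p_cols = sorted((c for c in df.columns if c.startswith("p") and c[1:].isdigit()),
                    key=lambda c: int(c[1:]))
    if not r_cols or len(r_cols) != len(p_cols):
        raise ValueError("trajectory CSV must have matching r1..rn and p1..pn columns")
    meta = {}
    side = _sidecar(csv_path)
    if side.exists():
        meta = json.loads(side.read_text())
    return Trajectory(times=df["time_min"].to_numpy(),
                      r=df[r_cols].to_numpy(), p=df[p_cols].to_numpy(),
                      net_ref=meta)


def write_trace(trace: FluorescenceTrace, csv_path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"time_min": trace.times, "Pf_nM": trace.Pf}).to_csv(
        csv_path, index=False, float_format="%.12g")
    _sidecar(csv_path).write_text(json.dumps(
        {"dil": trace.dil, "dt_min": trace.dt,
         "mat_per_min": trace.mat, "label": trace.label}, indent=1))


def read_trace(csv_path) -> FluorescenceTrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    for col in ("time_min", "Pf_nM"):
        if col not in df.columns:
            raise ValueError(f"trace CSV is missing the {col!r} column")
    side = _sidecar(csv_path)
    if not side.exists():
        raise ValueError(f"trace sidecar {side.name} not found")
    meta = json.loads(side.read_text())
    return FluorescenceTrace(times=df["time_min"].to_numpy(),
                             Pf=df["Pf_nM"].to_numpy(),
                             dil=meta["dil"], dt=meta["dt_min"],
                             mat=meta["mat_per_min"], label=meta.get("label", ""))
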