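"""Report writing: hashed, reproducible CSV/JSON/GraphML exports.

Every artefact carries the run's config hash and seed (CSV: a leading
``#`` comment line, readable back with ``pd.read_csv(..., comment='#')``;
JSON: top-level fields; GraphML: graph attributes) so outputs can be traced
to the configuration that produced them.  Re-running with an identical
configuration yields byte-identical files: nothing time- or path-dependent
is written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .zero_order import MdsLayout, WeightedNetwork

__all__ = ["config_hash", "write_csv", "write_json", "write_graphml", "network_to_graph"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in sorted(obj) if not isinstance(obj, (list, tuple))] if isinstance(obj, (set, frozenset)) else [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping/dataclass."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: Path, chash: str, seed: int, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash} seed={seed}\n")
        df.to_csv(fh, index=index)


def write_json(obj, path: Path, chash: str, seed: int) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"config_hash": chash, "seed": seed, **_jsonable(obj)}
    path.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")


def network_to_graph(net: WeightedNetwork, layout: MdsLayout | None = None) -> nx.Graph:
    G = nx.Graph()
    for i, lab in enumerate(net.labels):
        attrs = {}
        if layout is not None:
            attrs["x"] = float(layout.coords[i, 0])
            attrs["y"] = float(layout.coords[i, 1])
        G.add_node(lab, **attrs)
    n = net.n_nodes
    for i in range(n):
        for j in range(i + 1, n):
            w = net.weights[i, j]
            if not np.isfinite(w):
                continue
            attrs = {"weight": float(w), "displayed": bool(net.mask[i, j])}
            if net.pvalues is not None:
                attrs["p"] = float(net.pvalues[i, j])
            G.add_edge(net.labels[i], net.labels[j], **attrs)
    return G


def write_graphml(
    net: WeightedNetwork, path: Path, chash: str, seed: int, layout: MdsLayout | None = None
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    G = network_to_graph(net, layout)
    G.graph["config_hash"] = chash
    G.graph["seed"] = seed
    nx.write_graphml(G, path)
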