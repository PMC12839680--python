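"""Strength centrality, hub calling, and cross-layer hub classification.

Hubs are nodes whose in- (or out-) strength lies strictly above a percentile
cutoff of the layer's strength distribution (90th by default, linear
interpolation).  Hubs are then classed by how many of the multiplex layers
they appear in: local (one layer), intermediate (two or three), multiplex
(all four).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .multiplex import MultiplexNetwork

logger = logging.getLogger(__name__)

__all__ = ["strengths", "call_hubs", "classify_hubs_across_layers", "hub_table"]


def strengths(layer: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node (in_strength, out_strength): column and row weight sums."""
    w = np.asarray(layer, dtype=float)
    return w.sum(axis=0), w.sum(axis=1)


def call_hubs(strength: np.ndarray, percentile: float = 90.0) -> np.ndarray:
    """Indices of nodes strictly above the percentile cutoff.

    The cutoff uses numpy's linear-interpolation percentile; ties at the
    cutoff are excluded (the definition is "higher than" the percentile).
    An all-equal strength vector yields no hubs.
    """
    s = np.asarray(strength, dtype=float)
    if s.size < 10:
        raise ValueError("need at least 10 nodes for a meaningful percentile cutoff")
    cutoff = np.percentile(s, percentile)
    hubs = np.flatnonzero(s > cutoff)
    if hubs.size == 0:
        logger.warning("no strengths above the %.0fth percentile cutoff", percentile)
    return hubs


def classify_hubs_across_layers(
    hub_sets: list[np.ndarray], n_nodes: int
) -> dict[int, str]:
    """Multiplex class per hub node from its occurrence across layers.

    With M = 4 layers: appearing in 1 layer -> "local" (<= 25% of layers),
    in 2-3 -> "intermediate", in all 4 -> "multiplex" (> 75%).  Nodes that
    are hubs in no layer are absent from the result.
    """
    m = len(hub_sets)
    if m != 4:
        raise ValueError("hub classification is defined for the 4-layer multiplex")
    occurrence = np.zeros(n_nodes, dtype=int)
    for hubs in hub_sets:
        occurrence[np.asarray(hubs, dtype=int)] += 1
    out = {}
    for node in np.flatnonzero(occurrence):
        k = occurrence[node]
        out[int(node)] = "local" if k == 1 else ("multiplex" if k == m else "intermediate")
    return out


def hub_table(net: MultiplexNetwork, percentile: float = 90.0) -> pd.DataFrame:
    """Long-format table: node, layer, direction, strength, is_hub, class."""
    records = []
    hub_sets = {"in": [], "out": []}
    for name, w in zip(net.layer_names, net.layers):
        s_in, s_out = strengths(w)
        for direction, s in (("in", s_in), ("out", s_out)):
            hubs = set(call_hubs(s, percentile).tolist())
            hub_sets[direction].append(np.array(sorted(hubs), dtype=int))
            for node in range(net.n_nodes):
                records.append({
                    "node": net.node_labels[node], "layer": name,
                    "direction": direction, "strength": s[node],
                    "is_hub": node in hubs,
                })
    df = pd.DataFrame(records)
    classes = {
        d: classify_hubs_across_layers(hub_sets[d], net.n_nodes) for d in ("in", "out")
    }
    index_of = {lbl: i for i, lbl in enumerate(net.node_labels)}
    df["multiplex_class"] = [
        classes[rec["direction"]].get(index_of[rec["node"]], "") for rec in records
    ]
    return df
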