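"""Multiplex network container, per-layer metrics, and the network null model.

A multiplex here is a vector of weighted directed adjacency matrices over
one shared node set (one layer per interaction rule in the standard
pipeline), with no interlayer links.  The null model rewires a layer's
directed topology with degree-preserving edge swaps and then reassigns each
node's incoming weights as a random permutation of its original incoming
weights, so the in-strength sequence (and hence total weight) is preserved
exactly while weight-topology correlations are destroyed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "MultiplexNetwork",
    "density",
    "total_weight",
    "randomize_preserving_instrength",
]


@dataclass
class MultiplexNetwork:
    """Ordered layers of weighted directed adjacency over one node set."""

    layers: list[np.ndarray]
    layer_names: list[str] = field(default_factory=list)
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a multiplex needs at least one layer")
        self.layers = [np.asarray(w, dtype=float) for w in self.layers]
        n = self.layers[0].shape[0]
        for w in self.layers:
            if w.shape != (n, n):
                raise ValueError("all layers must be square and share one node set")
            if (w < 0).any():
                raise ValueError("layer weights must be non-negative")
            np.fill_diagonal(w, 0.0)
        if not self.layer_names:
            self.layer_names = [f"L{k}" for k in range(len(self.layers))]
        if len(self.layer_names) != len(self.layers):
            raise ValueError("layer_names length does not match layers")
        if not self.node_labels:
            self.node_labels = [f"ROI{i}" for i in range(n)]
        if len(self.node_labels) != n:
            raise ValueError("node_labels length does not match layer size")

    @property
    def n_nodes(self) -> int:
        return self.layers[0].shape[0]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer(self, name: str) -> np.ndarray:
        return self.layers[self.layer_names.index(name)]

    def map_layers(self, fn) -> "MultiplexNetwork":
        """A new multiplex with ``fn`` applied to every layer matrix."""
        return MultiplexNetwork(
            layers=[fn(w) for w in self.layers],
            layer_names=list(self.layer_names),
            node_labels=list(self.node_labels),
        )


def density(layer: np.ndarray) -> float:
    """Fraction of realized off-diagonal directed links (any w > 0)."""
    w = np.asarray(layer)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("layer must be a square matrix")
    n = w.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float((w[off] > 0).sum() / (n * (n - 1)))


def total_weight(layer: np.ndarray) -> float:
    """Sum of all link weights in a layer."""
    return float(np.asarray(layer).sum())


def randomize_preserving_instrength(
    layer: np.ndarray,
    n_iter: int = 10,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Randomize a weighted directed layer preserving the in-strength sequence.

    Topology is rewired by directed degree-preserving edge swaps
    (``n_iter`` x number-of-links swap attempts); each node's incoming
    weights are then reassigned as a random permutation of its original
    incoming weights.  In-degree, out-degree, per-node in-strength and total
    weight are preserved exactly; out-strengths and the weight-topology
    pairing are randomized.
    """
    rng = np.random.default_rng(seed)
    w = np.asarray(layer, dtype=float).copy()
    n = w.shape[0]
    edges = np.argwhere(w > 0)
    n_edges = len(edges)
    if n_edges < 2:
        logger.warning("layer has %d link(s); returning it unchanged", n_edges)
        return w

    present = w > 0
    edges = [tuple(e) for e in edges]
    attempts = n_iter * n_edges
    for _ in range(attempts):
        e1, e2 = rng.integers(n_edges), rng.integers(n_edges)
        if e1 == e2:
            continue
        (a, b), (c, d) = edges[e1], edges[e2]
        # propose (a->d, c->b); keep simple digraph, no self-loops
        if a == d or c == b or present[a, d] or present[c, b]:
            continue
        present[a, b] = present[c, d] = False
        present[a, d] = present[c, b] = True
        edges[e1], edges[e2] = (a, d), (c, b)

    # reassign: node j's incoming weights are a permutation of its originals
    out = np.zeros_like(w)
    for j in range(n):
        sources = np.flatnonzero(present[:, j])
        weights = w[w[:, j] > 0, j]
        out[rng.permutation(sources), j] = weights
    return out
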