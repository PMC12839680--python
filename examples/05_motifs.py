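"""Triad motif intensities across layer combinations, with significance.

Builds a two-layer multiplex with three heavy directed cycles planted in
layer one, then scores every motif class (Cycle, Flux, Chain, Source,
Sink) for every layer combination against strength-preserving
randomizations.  The planted cycles surface as a significant 0th-order
Cycle intensity.
"""

import numpy as np

from templex import gen_multiplex
from templex.motifs import motif_significance
from templex.multiplex import MultiplexNetwork

rng = np.random.default_rng(3)
net = gen_multiplex(14, n_layers=2, density=0.12, seed=3,
                    layer_names=["ActS", "TfO"])
w = net.layers[0]
for i, j, k in ((0, 1, 2), (3, 4, 5), (6, 7, 8)):
    w[i, j] = w[j, k] = w[k, i] = 4.0
    w[j, i] = w[k, j] = w[i, k] = 0.0

print("motif    layers        order  intensity  count      z      p")
for s in motif_significance(net, n_rand=100, seed=4):
    print(f"{s.motif_type:7s} {'+'.join(s.layers):13s} {s.order}   "
          f"{s.intensity:9.3f}  {s.count:5d}  {s.z:+6.2f}  {s.p:.3f}")
print()
print("Intensity sums the geometric mean of link weights over instances;")
print("the planted heavy cycles push the single-layer Cycle z-score far")
print("above the randomized-network null.")
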