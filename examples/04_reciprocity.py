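"""Null-normalized reciprocity within and between multiplex layers.

Generates a 4-layer multiplex with moderate within-layer reciprocity and
prints the raw reciprocated-weight fraction r, the null mean under
strength-preserving rewiring, and the normalized index nRI in [-1, 1]
(positive = reciprocal tendency, negative = reciprocal avoidance).
"""

from templex import gen_multiplex
from templex.reciprocity import multiplex_reciprocity

net = gen_multiplex(
    n_nodes=40, n_layers=4, density=0.12, reciprocity_level=0.35, seed=11
)
print("layers          r      null_mean   nRI      p")
for res in multiplex_reciprocity(net, n_null=100, seed=12):
    pair = f"{res.layer_alpha}->{res.layer_beta}"
    print(f"{pair:12s} {res.r:7.3f}  {res.null_mean:8.3f}  {res.nri:+7.3f}  {res.p:.3f}")
print()
print("Within-layer rows exceed their rewired null (positive nRI) because")
print("the generator reciprocates 35% of linked dyads; between-layer pairs")
print("carry no planted cross-layer mirroring and sit near zero.")
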