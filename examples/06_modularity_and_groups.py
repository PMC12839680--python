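"""Planted-module recovery and a two-group rule-weight comparison.

Part 1 partitions a directed network with three planted modules and tests
Q against strength-preserving nulls.  Part 2 generates a two-group cohort
whose group 2 has a stronger TfO coupling and runs the rank-sum +
Bonferroni comparison of rule-layer total weights.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from templex import gen_cohort, gen_multiplex
from templex.modularity import louvain_directed, q_significance
from templex.stats import compare_measures
from templex.synthetic import demo_cohort
from templex.te import RULE_NAMES, build_rule_layers, subject_contributions

planted = np.repeat([0, 1, 2], 15)
net = gen_multiplex(45, 1, density=0.15, partition=planted,
                    module_ratio=10, seed=21)
part, q = louvain_directed(net.layers[0], n_restarts=20, seed=22)
sig, null_q = q_significance(net.layers[0], q, n_rand=100, seed=23)
print(f"planted 3-module network: Q = {q:.3f} "
      f"(null mean {null_q.mean():.3f}), significant = {sig}")
print(f"adjusted Rand index vs planted partition: "
      f"{adjusted_rand_score(planted, part):.3f}")

g1, g2, _ = gen_cohort(demo_cohort(effect_delta=0.3, seed=24))
totals = []
for group in (g1, g2):
    t = {f"total_weight:{r}": [] for r in RULE_NAMES}
    for states in group:
        layers = build_rule_layers(subject_contributions(states))
        for r in RULE_NAMES:
            t[f"total_weight:{r}"].append(layers[r].sum())
    totals.append({k: np.array(v) for k, v in t.items()})
table = compare_measures(totals[0], totals[1])
print("\nrule-layer total weights, group 1 vs group 2 "
      "(rank-sum, Bonferroni m=4):")
print(table[["measure", "mean1", "mean2", "p", "p_corrected",
             "significant"]].to_string(index=False))
print("\nGroup 2's higher transfer probabilities raise its layer weights;")
print("significant rows survive the Bonferroni-corrected comparison.")
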