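"""Reproducibility studies: planted-structure recovery, calibration, power.

Each function runs one self-contained computational experiment on synthetic
data with known ground truth and returns plain numbers.  They back the
acceptance checks and the worked examples, and are sized to run on a single
CPU in seconds to a couple of minutes each:

* rule recovery uses the standard demonstration cohort (10 ROIs, 150
  timepoints, 20 subjects per group, transfer probability 0.6, 100
  permutations);
* the motif oracle study compares the matrix fast paths against explicit
  triad enumeration on random multiplexes of up to 10 nodes and 2-4 layers;
* modularity studies use 45-node planted three-module networks
  (within:between link-probability ratio 10:1) and 30-node null draws;
* group-test calibration runs 500 replicate null cohorts, the power study
  200 cohorts with the transfer probability of the TfO edges raised by 0.3
  in group 2.
"""

from __future__ import annotations

from itertools import combinations_with_replacement

import numpy as np
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from .modularity import louvain_directed, q_significance
from .motifs import CLOSED_MOTIFS, MOTIF_TYPES, intensity
from .multiplex import randomize_preserving_instrength
from .reciprocity import normalize_reciprocity, reciprocity_raw
from .stats import bonferroni, ranksum_test
from .synthetic import (
    DEMO_MARGINALS,
    CohortSpec,
    RuleSpec,
    demo_cohort,
    gen_cohort,
    gen_multiplex,
)
from .te import (
    RULE_NAMES,
    build_rule_layers,
    combination_significance,
    count_transitions,
    local_te,
    subject_contributions,
)

__all__ = [
    "rule_recovery_study",
    "te_analytic_limits",
    "motif_oracle_study",
    "reciprocity_study",
    "modularity_recovery_study",
    "modularity_null_rate",
    "group_test_calibration",
    "group_test_power",
]


def _spawn(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def rule_recovery_study(seed: int = 0, n_perm: int = 100):
    """Combination significance on the standard planted demo cohort.

    Returns ``(significance_result, subjects)`` so downstream checks (rule
    clustering) can reuse the cohort.
    """
    s_cohort, s_test = _spawn(seed, 2)
    g1, g2, _ = gen_cohort(demo_cohort(seed=s_cohort))
    subjects = g1 + g2
    sig = combination_significance(subjects, n_perm=n_perm, seed=s_test)
    return sig, subjects


def te_analytic_limits(seed: int = 0, n_time: int = 10_000):
    """Copy-channel and independence limits of the plug-in estimator.

    Returns ``(copy_channel_te, independent_te)`` in nats: the first should
    approach ln 3 (a uniform 3-state source copied one step ahead), the
    second — the raw plug-in total under independence — should approach 0.
    """
    rng = np.random.default_rng(seed)
    a = rng.integers(-1, 2, n_time)
    b = np.roll(a, 1)
    copy_te = float(local_te(count_transitions(a, b)).total)
    x = rng.integers(-1, 2, n_time)
    y = rng.integers(-1, 2, n_time)
    indep_te = float(local_te(count_transitions(x, y)).total_raw)
    return copy_te, indep_te


def motif_oracle_study(seed: int = 0, n_instances: int = 50) -> float:
    """Max |fast - reference| intensity over random multiplex instances.

    Every motif type and every layer combination (all orders) is evaluated
    on each instance; counts must agree exactly.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        net = gen_multiplex(
            n_nodes=int(rng.integers(6, 11)),
            n_layers=int(rng.integers(2, 5)),
            density=float(rng.uniform(0.15, 0.4)),
            reciprocity_level=float(rng.uniform(0.0, 0.5)),
            seed=rng,
        )
        for mt in MOTIF_TYPES:
            n_links = 3 if mt in CLOSED_MOTIFS else 2
            for combo in combinations_with_replacement(net.layer_names, n_links):
                fast = intensity(net, mt, combo, method="fast")
                ref = intensity(net, mt, combo, method="reference")
                worst = max(worst, abs(fast.intensity - ref.intensity))
                if fast.count != ref.count:
                    raise AssertionError(
                        f"count mismatch for {mt} {combo}: "
                        f"{fast.count} != {ref.count}"
                    )
    return worst


def reciprocity_study(seed: int = 0, n_null: int = 50, n_nodes: int = 40):
    """nRI endpoints and its tracking of the generator's reciprocity level.

    Returns a dict with the nRI of a fully reciprocal layer, a fully
    anti-reciprocal layer, and the Spearman rank correlation between the
    generator's reciprocity level and nRI over a 10-point sweep.
    """
    s_gen, s_null = _spawn(seed, 2)
    levels = np.linspace(0.0, 1.0, 10)
    nris = []
    for lvl in levels:
        net = gen_multiplex(n_nodes, 1, density=0.15,
                            reciprocity_level=float(lvl), seed=s_gen)
        w = net.layers[0]
        rng = np.random.default_rng(s_null)
        null = np.array([
            reciprocity_raw(randomize_preserving_instrength(w, seed=rng))
            for _ in range(n_null)
        ])
        nris.append(normalize_reciprocity(reciprocity_raw(w), null)[0])
    return {
        "nri_fully_reciprocal": nris[-1],
        "nri_fully_antireciprocal": nris[0],
        "rank_correlation": float(spearmanr(levels, nris).statistic),
    }


def modularity_recovery_study(seed: int = 0, n_rand: int = 100):
    """Planted three-module recovery: returns (ARI, Q significant)."""
    s_gen, s_opt = _spawn(seed, 2)
    planted = np.repeat([0, 1, 2], 15)
    net = gen_multiplex(45, 1, density=0.15, partition=planted,
                        module_ratio=10.0, seed=s_gen)
    w = net.layers[0]
    rng = np.random.default_rng(s_opt)
    part, q = louvain_directed(w, n_restarts=20, seed=rng)
    sig, _ = q_significance(w, q, n_rand=n_rand, seed=rng, n_restarts=5)
    return float(adjusted_rand_score(planted, part)), bool(sig)


def modularity_null_rate(seed: int = 0, n_rep: int = 40, n_rand: int = 100) -> float:
    """Type-I error of the Q-significance rule under its own null hypothesis.

    The decision rule declares a partition significant when its optimized Q
    exceeds the 95th percentile of optimized Q on strength-preserving
    randomizations; its null hypothesis is that the observed network is a
    typical member of that randomization ensemble.  Each replicate simulates
    exactly that: the "observed" network and the ``n_rand`` comparison
    networks are all independent randomizations of one unstructured base
    network, optimized identically, so the rejection rate estimates the
    rule's type-I error under exact exchangeability.
    """
    seeds = _spawn(seed, n_rep)
    hits = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        base = gen_multiplex(30, 1, density=0.2, reciprocity_level=0.3,
                             seed=rng).layers[0]
        w = randomize_preserving_instrength(base, seed=rng)
        _, q = louvain_directed(w, n_restarts=5, seed=rng)
        null_q = np.empty(n_rand)
        for k in range(n_rand):
            w_null = randomize_preserving_instrength(base, seed=rng)
            _, null_q[k] = louvain_directed(w_null, n_restarts=5, seed=rng)
        hits += q > np.percentile(null_q, 95)
    return hits / n_rep


def _cohort_rule_totals(spec: CohortSpec):
    """Per-subject rule-layer total weights for both groups of a cohort."""
    g1, g2, _ = gen_cohort(spec)
    out = []
    for grp in (g1, g2):
        totals = {r: [] for r in RULE_NAMES}
        for states in grp:
            layers = build_rule_layers(subject_contributions(states))
            for r in RULE_NAMES:
                totals[r].append(float(layers[r].sum()))
        out.append(totals)
    return out


def group_test_calibration(seed: int = 0, n_cohorts: int = 500) -> float:
    """Family-wise error of the rank-sum + Bonferroni comparison.

    Each replicate cohort has identical rule strengths in both groups
    (effect_delta = 0); an error is any rule layer whose total-weight
    difference is called significant after Bonferroni over the four layers.
    """
    seeds = _spawn(seed, n_cohorts)
    errors = 0
    for s in seeds:
        t1, t2 = _cohort_rule_totals(demo_cohort(seed=s))
        ps = [ranksum_test(t1[r], t2[r])[1] for r in RULE_NAMES]
        errors += bool(bonferroni(ps)[1].any())
    return errors / n_cohorts


def group_test_power(seed: int = 0, n_cohorts: int = 200,
                     effect_delta: float = 0.3) -> float:
    """Detection rate of a planted TfO-strength increase in group 2.

    TfO is planted on four disjoint edges at transfer probability 0.6;
    group 2 shifts it by ``effect_delta``.  Detection means the TfO
    total-weight comparison is significant after Bonferroni over the four
    rule layers.
    """
    rules = [RuleSpec(s, t, "TfO", 0.6) for s, t in ((0, 1), (2, 3), (4, 5), (6, 7))]
    seeds = _spawn(seed, n_cohorts)
    hits = 0
    tfo = list(RULE_NAMES).index("TfO")
    for s in seeds:
        spec = CohortSpec(n_roi=10, n_time=150, n_subjects_per_group=20,
                          marginals=DEMO_MARGINALS, rules=rules,
                          effect_delta=effect_delta, seed=s)
        t1, t2 = _cohort_rule_totals(spec)
        ps = [ranksum_test(t1[r], t2[r])[1] for r in RULE_NAMES]
        hits += bool(bonferroni(ps)[1][tfo])
    return hits / n_cohorts
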