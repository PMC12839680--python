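"""Synthetic cohorts with planted interaction rules.

The generator emulates what the analysis pipeline expects from a
resting-state cohort after ROI extraction: per-subject three-state sequences
(activation 1 / null 0 / deactivation -1) whose baseline is i.i.d. with
configurable marginal state frequencies, optionally perturbed by planted
directed couplings of the four rule types.  A planted rule ``A -> B`` of
type ActS, for instance, means: whenever ``A_n = s`` (s in {1, -1}) and
``B_n = 0``, the target's next state is overridden to ``s`` with probability
``epsilon`` (the transfer probability).  Both sign-mirrored transitions of a
rule are always planted together, as the rules are defined.

Continuous "BOLD-like" signals can be emitted from state sequences
(state x amplitude + Gaussian noise) so the discretization stage can be
exercised end to end, and weighted directed multiplex fixtures with
controlled density, reciprocity and planted modules feed the network
analytics.  Two-group cohorts shift the transfer probability of group 2 by
``effect_delta`` to plant group differences on rule-layer weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .te import RULE_NAMES

__all__ = [
    "RuleSpec",
    "CohortSpec",
    "gen_state_series",
    "gen_bold_from_states",
    "gen_multiplex",
    "gen_cohort",
    "demo_rules",
    "demo_cohort",
    "DEMO_MARGINALS",
    "write_cohort",
]

#: rule -> (required source state sign multiplier for B_n, forced B_{n+1})
#: encoded as functions of the source state s in {1, -1}:
#:   ActS: B_n = 0  => B_{n+1} = s
#:   TfS:  B_n = -s => B_{n+1} = 0
#:   ActO: B_n = 0  => B_{n+1} = -s
#:   TfO:  B_n = s  => B_{n+1} = 0
_RULE_DYNAMICS = {
    "ActS": (lambda s: 0, lambda s: s),
    "TfS": (lambda s: -s, lambda s: 0),
    "ActO": (lambda s: 0, lambda s: -s),
    "TfO": (lambda s: s, lambda s: 0),
}


@dataclass(frozen=True)
class RuleSpec:
    """A planted directed coupling of one rule type.

    epsilon is the transfer probability: the chance that a firing rule
    overrides the target's baseline draw at the next step.
    """

    source: int
    target: int
    rule: str
    epsilon: float

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("rule source and target must differ")
        if self.rule not in RULE_NAMES:
            raise ValueError(f"unknown rule {self.rule!r}; expected one of {RULE_NAMES}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must lie in [0, 1]")


@dataclass
class CohortSpec:
    """Conditions for a two-group synthetic cohort."""

    n_roi: int = 10
    n_time: int = 150
    n_subjects_per_group: int = 20
    marginals: tuple[float, float] = (0.3, 0.3)  # (p_plus, p_minus)
    rules: list[RuleSpec] = field(default_factory=list)
    effect_delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p_plus, p_minus = self.marginals
        if not (0 <= p_plus <= 1 and 0 <= p_minus <= 1 and p_plus + p_minus <= 1):
            raise ValueError("marginals must be probabilities with p_plus + p_minus <= 1")
        if self.n_time < 3:
            raise ValueError("n_time must be >= 3")
        for r in self.rules:
            if not 0.0 <= r.epsilon + self.effect_delta <= 1.0:
                raise ValueError(
                    f"epsilon + effect_delta = {r.epsilon + self.effect_delta:.3g} "
                    "falls outside [0, 1]"
                )


def demo_rules(epsilon: float = 0.6, n_roi: int = 10) -> list[RuleSpec]:
    """The standard planted ring for an ``n_roi``-ROI demonstration cohort.

    Edges form a single directed ring (each ROI sources one edge and targets
    one), which avoids common-driver couplings between planted edges.
    Activation rules occupy most edges and the turn-off rules one each: per
    edge, a turn-off rule concentrates far more transfer entropy on its
    combinations than an activation rule does (its firing condition is the
    common +-1 states), so this allocation gives all four rules comparable
    pooled signal.  Pair it with the activation-rich marginals of
    :func:`demo_cohort`.
    """
    if n_roi < 5:
        raise ValueError("the demonstration ring needs at least 5 ROIs")
    rules = []
    for i in range(n_roi):
        if i == n_roi - 3:
            rule = "TfS"
        elif i == n_roi - 1:
            rule = "TfO"
        elif i == n_roi - 2:
            rule = "ActO"
        else:
            rule = "ActS" if i % 2 == 0 else "ActO"
        rules.append(RuleSpec(source=i, target=(i + 1) % n_roi,
                              rule=rule, epsilon=epsilon))
    return rules


#: marginal state frequencies (p_plus, p_minus) of the demonstration cohorts:
#: an activation-rich regime (10% quiescence).  With frequent +-1 source
#: states the "source is quiescent, so no rule can fire" side channel --
#: which carries genuine transfer entropy into non-rule combinations such as
#: (0, 0, 0) -- has negligible probability mass, and the turn-off rules,
#: whose firing conditions require +-1 states on both nodes, retain strong
#: per-edge signal.
DEMO_MARGINALS: tuple[float, float] = (0.45, 0.45)


def demo_cohort(
    epsilon: float = 0.6,
    n_roi: int = 10,
    n_time: int = 150,
    n_subjects_per_group: int = 20,
    effect_delta: float = 0.0,
    seed: int = 0,
) -> CohortSpec:
    """The standard demonstration cohort: planted rules, activation-rich marginals."""
    return CohortSpec(
        n_roi=n_roi, n_time=n_time, n_subjects_per_group=n_subjects_per_group,
        marginals=DEMO_MARGINALS, rules=demo_rules(epsilon, n_roi),
        effect_delta=effect_delta, seed=seed,
    )


def gen_state_series(
    n_roi: int,
    n_time: int,
    marginals: tuple[float, float] = (0.3, 0.3),
    rules: list[RuleSpec] | None = None,
    seed: int | np.random.Generator | None = None,
    persistence: float = 0.0,
) -> np.ndarray:
    """Generate a (n_roi, n_time) three-state matrix with planted rules.

    At each step n+1 every ROI first draws a baseline state i.i.d. from the
    marginals (p_plus, p_minus, and 1 - p_plus - p_minus for state 0); with
    ``persistence`` rho > 0 the baseline instead repeats the previous state
    with probability rho.  Then each planted rule whose precondition holds at
    step n overrides its target's draw with probability epsilon.  When
    several rules fire on the same target at the same step, one of them is
    chosen uniformly at random.
    """
    p_plus, p_minus = marginals
    if not (0 <= p_plus <= 1 and 0 <= p_minus <= 1 and p_plus + p_minus <= 1):
        raise ValueError("marginals must be probabilities with p_plus + p_minus <= 1")
    if not 0.0 <= persistence < 1.0:
        raise ValueError("persistence must lie in [0, 1)")
    rules = rules or []
    rng = np.random.default_rng(seed)

    # baseline i.i.d. draws for every (roi, time) slot, drawn up front;
    # overrides replace slots without affecting later draws
    states = rng.choice(
        np.array([1, -1, 0], dtype=np.int8),
        size=(n_roi, n_time),
        p=[p_plus, p_minus, 1.0 - p_plus - p_minus],
    )
    if persistence > 0.0:
        keep = rng.random(size=(n_roi, n_time)) < persistence
        for n in range(1, n_time):
            col = keep[:, n]
            states[col, n] = states[col, n - 1]

    if not rules:
        return states

    by_target: dict[int, list[RuleSpec]] = {}
    for r in rules:
        if r.source >= n_roi or r.target >= n_roi or r.source < 0 or r.target < 0:
            raise ValueError("rule references a ROI outside the matrix")
        by_target.setdefault(r.target, []).append(r)

    for n in range(n_time - 1):
        for target, target_rules in by_target.items():
            forced: list[int] = []
            for r in target_rules:
                s = int(states[r.source, n])
                if s == 0:
                    continue
                cond_b, next_b = _RULE_DYNAMICS[r.rule]
                if int(states[target, n]) != cond_b(s):
                    continue
                if rng.random() < r.epsilon:
                    forced.append(next_b(s))
            if forced:
                choice = forced[0] if len(forced) == 1 else forced[rng.integers(len(forced))]
                states[target, n + 1] = choice
    return states


def gen_bold_from_states(
    states: np.ndarray,
    amplitude: float = 1.0,
    noise_sd: float = 0.1,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Emit a continuous signal: ``state * amplitude + N(0, noise_sd)``."""
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    s = np.asarray(states, dtype=float)
    return s * amplitude + rng.normal(0.0, noise_sd, size=s.shape) if noise_sd > 0 else s * amplitude


def gen_multiplex(
    n_nodes: int,
    n_layers: int = 4,
    density: float = 0.15,
    weight_dist: str = "uniform",
    reciprocity_level: float = 0.0,
    partition: np.ndarray | list[int] | None = None,
    module_ratio: float = 10.0,
    seed: int | np.random.Generator | None = None,
    layer_names: list[str] | None = None,
):
    """Random weighted directed multiplex with controlled reciprocity/modules.

    Each unordered dyad of each layer independently carries a link with
    probability ``p_link = 2 * density / (1 + reciprocity_level)``; a linked
    dyad is reciprocated with probability ``reciprocity_level`` (both
    directions, equal weights) and otherwise carries a single link in a
    random direction.  This yields expected off-diagonal link density
    ``density`` and a reciprocated-dyad fraction equal to the requested
    level.  With a planted ``partition``, within-module dyads are
    ``module_ratio`` times more likely to be linked than between-module
    dyads, at the same overall density.

    Returns a :class:`templex.multiplex.MultiplexNetwork`.
    """
    from .multiplex import MultiplexNetwork

    if n_nodes < 3:
        raise ValueError("need at least 3 nodes (triads are undefined below that)")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    if not 0.0 <= reciprocity_level <= 1.0:
        raise ValueError("reciprocity_level must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    p_link = 2.0 * density / (1.0 + reciprocity_level)
    if p_link > 1.0:
        raise ValueError("density too high for the requested reciprocity level")

    if partition is not None:
        part = np.asarray(partition)
        if part.shape != (n_nodes,):
            raise ValueError("partition must assign a module to every node")
        same = part[:, None] == part[None, :]
    else:
        same = None

    def draw_weights(size: int) -> np.ndarray:
        if weight_dist == "uniform":
            return rng.uniform(0.5, 1.5, size=size)
        if weight_dist == "lognormal":
            return rng.lognormal(0.0, 0.5, size=size)
        raise ValueError(f"unknown weight_dist {weight_dist!r}")

    iu, ju = np.triu_indices(n_nodes, k=1)
    if same is not None:
        within = same[iu, ju]
        f_within = within.mean()
        # p_w = ratio * p_b, with f*p_w + (1-f)*p_b = p_link
        p_between = p_link / (f_within * module_ratio + (1.0 - f_within))
        p_within = min(1.0, module_ratio * p_between)
        dyad_p = np.where(within, p_within, p_between)
    else:
        dyad_p = np.full(iu.size, p_link)

    layers = []
    for _ in range(n_layers):
        w = np.zeros((n_nodes, n_nodes))
        linked = rng.random(iu.size) < dyad_p
        recip = rng.random(iu.size) < reciprocity_level
        weights = draw_weights(iu.size)
        fwd = rng.random(iu.size) < 0.5
        for d in np.flatnonzero(linked):
            i, j = int(iu[d]), int(ju[d])
            if recip[d]:
                w[i, j] = w[j, i] = weights[d]
            elif fwd[d]:
                w[i, j] = weights[d]
            else:
                w[j, i] = weights[d]
        layers.append(w)

    if layer_names is None:
        layer_names = (
            list(RULE_NAMES[:n_layers])
            if n_layers <= len(RULE_NAMES)
            else [f"L{k}" for k in range(n_layers)]
        )
    return MultiplexNetwork(layers=layers, layer_names=layer_names)


def gen_cohort(spec: CohortSpec):
    """Generate the two groups of state matrices plus a manifest.

    Group 1 uses the spec's rule epsilons; group 2 shifts every epsilon by
    ``effect_delta``.  Returns ``(group1, group2, manifest)`` where the
    groups are lists of state matrices and the manifest is a DataFrame with
    subject_id, group and an empty path column (filled in by
    :func:`write_cohort` when the cohort is materialized on disk).
    """
    if spec.n_subjects_per_group < 2:
        raise ValueError("need at least 2 subjects per group for group statistics")
    rng = np.random.default_rng(spec.seed)
    groups: list[list[np.ndarray]] = []
    for g, delta in ((1, 0.0), (2, spec.effect_delta)):
        rules = [
            RuleSpec(r.source, r.target, r.rule, r.epsilon + delta)
            for r in spec.rules
        ]
        groups.append([
            gen_state_series(spec.n_roi, spec.n_time, spec.marginals, rules, rng)
            for _ in range(spec.n_subjects_per_group)
        ])
    rows = [
        {"subject_id": f"g{g}s{i:03d}", "group": g, "path": ""}
        for g in (1, 2)
        for i in range(spec.n_subjects_per_group)
    ]
    return groups[0], groups[1], pd.DataFrame(rows)


def write_cohort(spec: CohortSpec, out_dir: str | Path):
    """Materialize a cohort on disk: per-subject TSVs, manifest CSV, JSON sidecar."""
    from .io import write_timeseries

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g1, g2, manifest = gen_cohort(spec)
    mats = g1 + g2
    paths = []
    for row, mat in zip(manifest.itertuples(), mats):
        p = out / f"{row.subject_id}.tsv"
        write_timeseries(p, mat, [f"ROI{i}" for i in range(spec.n_roi)])
        paths.append(str(p))
    manifest = manifest.assign(path=paths)
    manifest.to_csv(out / "manifest.csv", index=False)
    sidecar = asdict(spec)
    sidecar["rules"] = [asdict(r) for r in spec.rules]
    (out / "cohort.json").write_text(json.dumps(sidecar, indent=2))
    return manifest
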