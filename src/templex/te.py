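"""Local transfer entropy over three-state sequences and rule-layer construction.

For an ordered ROI pair A -> B with history lengths k = l = 1, transfer
entropy decomposes over the 27 state-transition combinations
c = (A_n, B_n, B_{n+1}) in {-1, 0, 1}^3:

    T_{A->B} = sum_c P(A_n, B_n, B_{n+1}) * ln[ P(B_{n+1} | A_n, B_n)
                                               / P(B_{n+1} | B_n) ]

The per-combination log-ratio lambda_c is the *local* transfer entropy;
negative local values (misinformative transfer) are set to zero before the
probability-weighted contributions t_c are aggregated.  Units are nats.

Eight of the 27 combinations define the four interaction rules, each rule
pairing the two sign-mirrored transitions of one mechanism:

    ActS  (activate, same state):     (1, 0, 1)   and (-1, 0, -1)
    TfS   (turn off, opposite state): (1, -1, 0)  and (-1, 1, 0)
    ActO  (activate, opposite state): (1, 0, -1)  and (-1, 0, 1)
    TfO   (turn off, same state):     (1, 1, 0)   and (-1, -1, 0)

Rule-layer edge weights are the summed contributions t_c of the rule's two
combinations for that ordered pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

__all__ = [
    "COMBINATIONS",
    "RULE_NAMES",
    "RULE_COMBINATIONS",
    "TEParameters",
    "LocalTEResult",
    "SignificanceResult",
    "count_transitions",
    "pair_combination_counts",
    "local_te",
    "reshuffle_null",
    "combination_significance",
    "cluster_combinations",
    "build_rule_layers",
]

#: the 27 combinations (A_n, B_n, B_{n+1}) in canonical index order
COMBINATIONS: tuple[tuple[int, int, int], ...] = tuple(
    (a, b, bp) for a in (-1, 0, 1) for b in (-1, 0, 1) for bp in (-1, 0, 1)
)

RULE_NAMES: tuple[str, ...] = ("ActS", "TfS", "ActO", "TfO")

#: rule -> its two sign-mirrored combinations
RULE_COMBINATIONS: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = {
    "ActS": ((1, 0, 1), (-1, 0, -1)),
    "TfS": ((1, -1, 0), (-1, 1, 0)),
    "ActO": ((1, 0, -1), (-1, 0, 1)),
    "TfO": ((1, 1, 0), (-1, -1, 0)),
}


def combination_index(combo: tuple[int, int, int]) -> int:
    """Canonical index of a combination (A_n, B_n, B_{n+1}) in 0..26."""
    a, b, bp = combo
    return 9 * (a + 1) + 3 * (b + 1) + (bp + 1)


#: rule -> canonical indices of its two combinations
RULE_INDICES: dict[str, tuple[int, int]] = {
    r: tuple(combination_index(c) for c in cc) for r, cc in RULE_COMBINATIONS.items()
}


@dataclass
class TEParameters:
    """Estimator parameters: source/target history lengths (natural log units)."""

    k: int = 1
    l: int = 1

    def __post_init__(self) -> None:
        if self.k < 1 or self.l < 1:
            raise ValueError("history lengths k and l must be >= 1")
        if self.k != 1 or self.l != 1:
            raise NotImplementedError(
                "only k = l = 1 is supported (one-step state histories)"
            )


def count_transitions(
    states_a: np.ndarray, states_b: np.ndarray, params: TEParameters | None = None
) -> np.ndarray:
    """Tally the 27 (A_n, B_n, B_{n+1}) combinations for one ordered pair.

    Returns an integer array of length 27 in canonical order; the counts sum
    to ``T - 1`` for sequences of length ``T``.
    """
    if params is None:
        params = TEParameters()
    a = np.asarray(states_a, dtype=np.int64).ravel()
    b = np.asarray(states_b, dtype=np.int64).ravel()
    if a.shape != b.shape:
        raise ValueError("source and target sequences must have equal length")
    if a.size < params.k + 1:
        raise ValueError("sequences too short for the requested history length")
    idx = 9 * (a[:-1] + 1) + 3 * (b[:-1] + 1) + (b[1:] + 1)
    return np.bincount(idx, minlength=27)


def pair_combination_counts(states: np.ndarray) -> np.ndarray:
    """Combination counts for every ordered ROI pair of one subject.

    Parameters
    ----------
    states : (n_roi, n_time) matrix with values in {-1, 0, 1}

    Returns
    -------
    counts : (n_roi, n_roi, 27) integer array; ``counts[i, j]`` are the
        tallies for the ordered pair i -> j.  The diagonal holds the pair of
        a ROI with itself and is not meaningful for the rule analysis.
    """
    s = np.asarray(states, dtype=np.int64) + 1  # codes 0..2
    a_part = np.eye(3, dtype=np.float64)[s[:, :-1]]            # (R, T-1, 3)
    bb = 3 * s[:, :-1] + s[:, 1:]                              # (R, T-1)
    b_part = np.eye(9, dtype=np.float64)[bb]                   # (R, T-1, 9)
    # counts[i, j, a, m] = sum_t a_part[i, t, a] * b_part[j, t, m]
    counts = np.einsum("ita,jtm->ijam", a_part, b_part)
    return np.rint(counts.reshape(s.shape[0], s.shape[0], 27)).astype(np.int64)


@dataclass
class LocalTEResult:
    """Local TE terms for one or many combination tables.

    All arrays share the leading shape of the input counts with a trailing
    axis of 27 combinations.
    """

    counts: np.ndarray
    joint: np.ndarray          # P(A_n, B_n, B_{n+1})
    p_cond: np.ndarray         # P(B_{n+1} | A_n, B_n)
    p_marg_cond: np.ndarray    # P(B_{n+1} | B_n)
    lam: np.ndarray            # local TE log-ratio, 0 where unobserved
    contributions: np.ndarray  # t_c = joint * max(lambda, 0)
    total: np.ndarray          # sum_c t_c (after zeroing)
    total_raw: np.ndarray      # sum_c joint * lambda (before zeroing)


def local_te(counts: np.ndarray) -> LocalTEResult:
    """Plug-in local transfer entropy from combination counts.

    ``counts`` may be a single length-27 table or any array whose final axis
    has 27 entries (e.g. the (n_roi, n_roi, 27) output of
    :func:`pair_combination_counts`); all tables are evaluated at once.

    Unseen conditioning events contribute 0 by convention (no pseudo-counts),
    so the joint probabilities per table still sum to 1 and the raw total
    equals the plug-in transfer entropy before zeroing.
    """
    c = np.asarray(counts, dtype=np.float64)
    if c.shape[-1] != 27:
        raise ValueError("expected a trailing axis of 27 combinations")
    shape = c.shape[:-1]
    n = c.reshape(shape + (3, 3, 3))  # axes: A_n, B_n, B_{n+1}
    total_n = n.sum(axis=(-3, -2, -1), keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        joint = n / total_n
        n_ab = n.sum(axis=-1, keepdims=True)
        p_cond = np.where(n_ab > 0, n / np.where(n_ab > 0, n_ab, 1.0), 0.0)
        n_bbp = n.sum(axis=-3, keepdims=True)
        n_b = n_bbp.sum(axis=-1, keepdims=True)
        p_marg = np.where(n_b > 0, n_bbp / np.where(n_b > 0, n_b, 1.0), 0.0)
        p_marg = np.broadcast_to(p_marg, n.shape)
        observed = n > 0
        lam = np.zeros_like(joint)
        lam[observed] = np.log(p_cond[observed]) - np.log(p_marg[observed])
    contributions = joint * np.maximum(lam, 0.0)
    flat = lambda x: x.reshape(shape + (27,))
    return LocalTEResult(
        counts=flat(n),
        joint=flat(joint),
        p_cond=flat(p_cond),
        p_marg_cond=flat(np.array(p_marg)),
        lam=flat(lam),
        contributions=flat(contributions),
        total=contributions.sum(axis=(-3, -2, -1)),
        total_raw=(joint * lam).sum(axis=(-3, -2, -1)),
    )


def subject_contributions(states: np.ndarray) -> np.ndarray:
    """Per-pair combination contributions t_c for one subject.

    Returns a (n_roi, n_roi, 27) array; the diagonal is zeroed.
    """
    counts = pair_combination_counts(states)
    t = local_te(counts).contributions
    r = t.shape[0]
    t[np.arange(r), np.arange(r), :] = 0.0
    return t


def reshuffle_null(
    states: np.ndarray, n_perm: int, seed: int | np.random.Generator | None = None
):
    """Yield ``n_perm`` surrogate state matrices with time order destroyed.

    Each permutation independently and uniformly permutes every ROI's state
    sequence in time, exactly preserving per-ROI marginal state counts while
    removing all temporal and cross-ROI structure.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    s = np.asarray(states)
    for _ in range(n_perm):
        out = np.empty_like(s)
        for i in range(s.shape[0]):
            out[i] = s[i, rng.permutation(s.shape[1])]
        yield out


@dataclass
class SignificanceResult:
    """Cohort-pooled permutation test over the 27 combinations.

    ``observed`` is the mean contribution t_c over all ordered pairs and
    subjects; ``null`` holds one such summary per permutation replicate.
    The family-wise decision uses the single-step max-T procedure on
    studentized summaries; Bonferroni-corrected per-combination p-values are
    reported alongside (with a logged warning when n_perm is too small for
    the Bonferroni threshold to be attainable).
    """

    observed: np.ndarray            # (27,)
    null: np.ndarray                # (n_perm, 27)
    p_raw: np.ndarray               # (27,) +1-corrected permutation p
    p_bonferroni: np.ndarray        # (27,)
    p_maxt: np.ndarray              # (27,) studentized max-T adjusted p
    mse: np.ndarray                 # (27,) mean squared obs-null deviation
    significant: np.ndarray         # (27,) boolean decision (max-T)
    alpha: float
    n_perm: int
    combinations: tuple = COMBINATIONS

    @property
    def surviving(self) -> list[tuple[int, int, int]]:
        return [COMBINATIONS[i] for i in np.flatnonzero(self.significant)]


def combination_significance(
    subject_states: list[np.ndarray],
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
) -> SignificanceResult:
    """Test which state-transition combinations carry significant transfer.

    The observed summary per combination is the mean contribution t_c pooled
    over all ordered ROI pairs and all subjects.  The null reshuffles every
    ROI sequence of every subject independently in time (marginal counts
    preserved exactly) and recomputes the pooled summary, once per replicate.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20 for a usable permutation null")
    rng = np.random.default_rng(seed)
    m = 27

    def pooled_summary(mats: list[np.ndarray]) -> np.ndarray:
        acc = np.zeros(m)
        n_pairs = 0
        for s in mats:
            t = subject_contributions(s)
            r = t.shape[0]
            acc += t.sum(axis=(0, 1))
            n_pairs += r * (r - 1)
        return acc / n_pairs

    observed = pooled_summary(subject_states)

    null = np.empty((n_perm, m))
    for p in range(n_perm):
        permuted = [
            next(reshuffle_null(s, 1, rng)) for s in subject_states
        ]
        null[p] = pooled_summary(permuted)

    p_raw = (1 + (null >= observed[None, :]).sum(axis=0)) / (1 + n_perm)
    p_bonf = np.minimum(1.0, m * p_raw)
    if (1 + n_perm) < m / alpha:
        logger.warning(
            "n_perm=%d cannot reach the Bonferroni threshold alpha/m=%.4g; "
            "the max-T decision remains valid", n_perm, alpha / m,
        )

    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, np.inf)
    z_obs = (observed - mu) / sd_safe
    z_null = (null - mu[None, :]) / sd_safe[None, :]
    max_null = z_null.max(axis=1)  # (n_perm,)
    p_maxt = (1 + (max_null[:, None] >= z_obs[None, :]).sum(axis=0)) / (1 + n_perm)
    significant = p_maxt < alpha

    mse = ((null - observed[None, :]) ** 2).mean(axis=0)
    return SignificanceResult(
        observed=observed, null=null, p_raw=p_raw, p_bonferroni=p_bonf,
        p_maxt=p_maxt, mse=mse, significant=significant,
        alpha=alpha, n_perm=n_perm,
    )


def combination_profiles(
    subject_states: list[np.ndarray], combos: list[tuple[int, int, int]]
) -> np.ndarray:
    """Edge-wise contribution profiles for a set of combinations.

    Returns an array of shape (n_combos, n_subjects * n_pairs): for each
    combination, its t_c value on every ordered ROI pair of every subject.
    These profiles are what the rule clustering operates on.
    """
    idx = [combination_index(c) for c in combos]
    cols = []
    for s in subject_states:
        t = subject_contributions(s)
        r = t.shape[0]
        off = ~np.eye(r, dtype=bool)
        cols.append(t[off][:, idx])  # (n_pairs, n_combos)
    return np.concatenate(cols, axis=0).T


def cluster_combinations(profiles: np.ndarray) -> np.ndarray:
    """Group surviving combinations by average-linkage hierarchical clustering.

    Distance is correlation distance between edge-wise contribution profiles;
    the dendrogram is cut at the largest gap between consecutive merge
    heights.  Returns integer cluster labels (1-based, scipy convention).
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 surviving combinations to cluster")
    d = pdist(profiles, metric="correlation")
    d = np.clip(d, 0.0, None)  # numerical noise can push distances < 0
    z = linkage(d, method="average")
    heights = z[:, 2]
    if len(heights) == 1:
        # two profiles: one cluster if they coincide, else two
        k = 1 if heights[0] < 1e-12 else 2
        return fcluster(z, t=k, criterion="maxclust")
    gaps = np.diff(heights)
    cut_at = int(np.argmax(gaps))
    threshold = 0.5 * (heights[cut_at] + heights[cut_at + 1])
    return fcluster(z, t=threshold, criterion="distance")


def build_rule_layers(
    contributions: np.ndarray,
    rules: dict[str, tuple] | None = None,
) -> dict[str, np.ndarray]:
    """Assemble the four rule-layer adjacency matrices from pair contributions.

    Parameters
    ----------
    contributions : (n_roi, n_roi, 27) per-pair t_c array
        (e.g. from :func:`subject_contributions`; significance filtering, if
        any, is applied upstream by restricting which combinations are used).
    rules : optional mapping rule name -> pair of combinations, defaulting to
        the canonical four rules.

    Returns
    -------
    dict mapping rule name to a (n_roi, n_roi) weighted directed matrix with
    ``w[i, j] = t_c1 + t_c2`` for the pair i -> j and zero diagonal.
    """
    t = np.asarray(contributions, dtype=float)
    rules = rules or RULE_COMBINATIONS
    layers: dict[str, np.ndarray] = {}
    r = t.shape[0]
    off_diag = ~np.eye(r, dtype=bool)
    for name, combos in rules.items():
        w = sum(t[:, :, combination_index(c)] for c in combos)
        layers[name] = np.where(off_diag, w, 0.0)
    return layers
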