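import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from templex.synthetic import gen_state_series, RuleSpec
from templex.te import (
    COMBINATIONS,
    RULE_COMBINATIONS,
    TEParameters,
    build_rule_layers,
    cluster_combinations,
    combination_index,
    count_transitions,
    local_te,
    pair_combination_counts,
    reshuffle_null,
    subject_contributions,
)


def brute_force_counts(a, b):
    """Independent dictionary-based tally of (A_n, B_n, B_{n+1}) triples."""
    tally = {c: 0 for c in COMBINATIONS}
    for n in range(len(a) - 1):
        tally[(int(a[n]), int(b[n]), int(b[n + 1]))] += 1
    return np.array([tally[c] for c in COMBINATIONS])


class TestCounting:
    def test_single_triple_hand_count(self):
        counts = count_transitions([1, 1], [0, 1])
        expected = np.zeros(27, dtype=int)
        expected[combination_index((1, 0, 1))] = 1
        np.testing.assert_array_equal(counts, expected)

    def test_counts_sum_to_t_minus_one(self, rng):
        for t_len in (3, 17, 400):
            a = rng.integers(-1, 2, t_len)
            b = rng.integers(-1, 2, t_len)
            assert count_transitions(a, b).sum() == t_len - 1

    def test_matches_brute_force_tally(self, rng):
        a = rng.integers(-1, 2, 1000)
        b = rng.integers(-1, 2, 1000)
        np.testing.assert_array_equal(
            count_transitions(a, b), brute_force_counts(a, b)
        )

    def test_all_pairs_tensor_matches_per_pair(self, rng):
        states = rng.integers(-1, 2, (5, 80))
        counts = pair_combination_counts(states)
        for i in range(5):
            for j in range(5):
                np.testing.assert_array_equal(
                    counts[i, j], count_transitions(states[i], states[j])
                )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            count_transitions([1, 0, 1], [1, 0])

    def test_history_lengths_validated(self):
        with pytest.raises(ValueError):
            TEParameters(k=0)


class TestLocalTE:
    def test_copy_channel_reaches_log3(self, rng):
        a = rng.integers(-1, 2, 10_000)
        b = np.roll(a, 1)
        res = local_te(count_transitions(a, b))
        assert abs(res.total - np.log(3)) / np.log(3) < 0.02
        assert abs(res.total_raw - np.log(3)) / np.log(3) < 0.02

    def test_independent_sequences_raw_total_near_zero(self, rng):
        a = rng.integers(-1, 2, 10_000)
        b = rng.integers(-1, 2, 10_000)
        res = local_te(count_transitions(a, b))
        assert 0 <= res.total_raw < 0.01

    def test_joint_sums_to_one_and_contributions_nonnegative(self, rng):
        counts = pair_combination_counts(rng.integers(-1, 2, (4, 60)))
        res = local_te(counts)
        np.testing.assert_allclose(res.joint.sum(axis=-1), 1.0)
        assert (res.contributions >= 0).all()

    def test_rectification_only_increases_the_total(self, rng):
        counts = pair_combination_counts(rng.integers(-1, 2, (6, 100)))
        res = local_te(counts)
        assert (res.total >= res.total_raw - 1e-12).all()
        np.testing.assert_allclose(res.total, res.contributions.sum(axis=-1))

    def test_reduced_two_state_table_hand_evaluated(self):
        # 2-state copy channel embedded in the 3-state alphabet, built so the
        # empirical table is exactly balanced: triples (1,-1,1), (1,1,1),
        # (-1,1,-1), (-1,-1,-1), once each.  Hand evaluation of the sum:
        # P(B'|A,B) = 1, P(B'|B) = 1/2 for every observed triple, so
        # TE = 4 * (1/4) * ln 2 = ln 2 exactly.
        a = np.array([1, 1, -1, -1, 1])
        b = np.array([-1, 1, 1, -1, -1])  # b[n+1] = a[n]
        res = local_te(count_transitions(a, b))
        assert res.total == pytest.approx(np.log(2), rel=1e-12)
        assert res.total_raw == pytest.approx(np.log(2), rel=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    hnp.arrays(
        np.int8,
        st.tuples(st.integers(2, 5), st.integers(3, 40)),
        elements=st.integers(-1, 1),
    )
)
def test_estimator_invariants_on_arbitrary_state_matrices(states):
    """Count conservation, joint normalization, and rectification ordering
    hold for every state matrix, however degenerate."""
    counts = pair_combination_counts(states)
    assert (counts.sum(axis=-1) == states.shape[1] - 1).all()
    res = local_te(counts)
    np.testing.assert_allclose(res.joint.sum(axis=-1), 1.0)
    assert (res.contributions >= 0).all()
    assert (res.total >= res.total_raw - 1e-12).all()


class TestReshuffleNull:
    def test_marginals_preserved_exactly(self, rng):
        states = rng.integers(-1, 2, (6, 150))
        for perm in reshuffle_null(states, 5, seed=1):
            for i in range(6):
                np.testing.assert_array_equal(
                    np.sort(perm[i]), np.sort(states[i])
                )

    def test_seeded_reproducibility(self, rng):
        states = rng.integers(-1, 2, (4, 50))
        runs = [list(reshuffle_null(states, 3, seed=7)) for _ in range(2)]
        for a, b in zip(*runs):
            np.testing.assert_array_equal(a, b)


class TestSignificance:
    def test_rule_free_cohort_yields_no_survivors(self, rng):
        from templex.te import combination_significance

        subjects = [gen_state_series(8, 150, seed=s) for s in range(10)]
        sig = combination_significance(subjects, n_perm=60, seed=5)
        assert len(sig.surviving) == 0

    def test_planted_rules_survive(self, demo_significance):
        surviving = set(demo_significance.surviving)
        for rule, combos in RULE_COMBINATIONS.items():
            assert set(combos) <= surviving, f"{rule} combinations missing"

    def test_pvalues_are_valid_probabilities(self, demo_significance):
        for p in (demo_significance.p_raw, demo_significance.p_maxt,
                  demo_significance.p_bonferroni):
            assert ((p > 0) & (p <= 1)).all()

    def test_too_few_permutations_rejected(self):
        from templex.te import combination_significance

        with pytest.raises(ValueError):
            combination_significance([np.zeros((3, 10), dtype=int)], n_perm=5)


class TestClustering:
    def test_identical_profiles_merge_at_zero(self):
        profiles = np.vstack([np.arange(10.0), np.arange(10.0)])
        labels = cluster_combinations(profiles)
        assert len(set(labels)) == 1

    def test_two_distinct_profiles_split(self, rng):
        profiles = rng.normal(size=(2, 30))
        assert len(set(cluster_combinations(profiles))) == 2

    def test_matches_exhaustive_best_pairing_oracle(self, rng):
        # four well-separated base profiles, each duplicated with small noise
        bases = rng.normal(size=(4, 60))
        profiles = np.vstack([
            b + rng.normal(0, 0.05, 60) for b in bases for _ in range(2)
        ])
        labels = cluster_combinations(profiles)
        # oracle: exhaustive search over perfect matchings minimizing the
        # summed correlation distance within pairs
        d = np.corrcoef(profiles)
        dist = 1 - d

        def matchings(items):
            if not items:
                yield []
                return
            first, rest = items[0], items[1:]
            for k, other in enumerate(rest):
                for m in matchings(rest[:k] + rest[k + 1:]):
                    yield [(first, other)] + m

        best = min(
            matchings(list(range(8))),
            key=lambda m: sum(dist[i, j] for i, j in m),
        )
        assert len(set(labels)) == 4
        for i, j in best:
            assert labels[i] == labels[j]

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            cluster_combinations(np.ones((1, 5)))


class TestRuleLayers:
    def test_planted_edge_dominates_its_layer(self):
        states = gen_state_series(
            4, 5000, rules=[RuleSpec(0, 1, "ActS", 0.9)], seed=2
        )
        layers = build_rule_layers(subject_contributions(states))
        acts = layers["ActS"]
        assert acts[0, 1] > 10 * np.delete(acts.ravel(), 1).max()
        for other in ("TfS", "ActO", "TfO"):
            assert layers[other][0, 1] < acts[0, 1] / 10

    def test_no_events_zero_weight_and_nonnegativity(self, rng):
        # constant-zero sequences never realize the rule combinations
        states = np.zeros((3, 50), dtype=int)
        layers = build_rule_layers(subject_contributions(states))
        for w in layers.values():
            np.testing.assert_array_equal(w, 0.0)
        layers = build_rule_layers(
            subject_contributions(rng.integers(-1, 2, (5, 100)))
        )
        for w in layers.values():
            assert (w >= 0).all()
            assert np.diag(w).sum() == 0
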