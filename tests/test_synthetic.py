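import numpy as np
import pytest

import templex as tx
from templex.synthetic import (
    CohortSpec,
    RuleSpec,
    demo_cohort,
    demo_rules,
    gen_bold_from_states,
    gen_cohort,
    gen_multiplex,
    gen_state_series,
)


class TestRuleSpec:
    @pytest.mark.parametrize("kwargs", [
        dict(source=0, target=0, rule="ActS", epsilon=0.5),
        dict(source=0, target=1, rule="Bogus", epsilon=0.5),
        dict(source=0, target=1, rule="TfO", epsilon=1.5),
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RuleSpec(**kwargs)


class TestStateSeries:
    def test_rule_free_marginals_within_three_standard_errors(self):
        p = 0.3
        states = gen_state_series(3, 10_000, marginals=(p, p), seed=0)
        for value, expected in ((1, p), (-1, p), (0, 1 - 2 * p)):
            freq = (states == value).mean()
            assert abs(freq - expected) < 3 * np.sqrt(
                expected * (1 - expected) / states.size
            ), (value, freq)

    def test_deterministic_rule_always_fires_at_epsilon_one(self):
        states = gen_state_series(
            2, 4000, rules=[RuleSpec(0, 1, "ActS", 1.0)], seed=1
        )
        a, b = states
        fire = (a[:-1] != 0) & (b[:-1] == 0)
        assert fire.sum() > 100
        np.testing.assert_array_equal(b[1:][fire], a[:-1][fire])

    def test_epsilon_zero_leaves_baseline_untouched(self):
        p_minus = 0.3
        states = gen_state_series(
            2, 20_000, marginals=(0.3, p_minus),
            rules=[RuleSpec(0, 1, "ActO", 0.0)], seed=2,
        )
        a, b = states
        cond = (a[:-1] == 1) & (b[:-1] == 0)
        freq = (b[1:][cond] == -1).mean()
        assert abs(freq - p_minus) < 3 * np.sqrt(p_minus * 0.7 / cond.sum())

    def test_override_frequency_matches_epsilon(self):
        eps, p_plus = 0.5, 0.3
        states = gen_state_series(
            2, 40_000, marginals=(p_plus, 0.3),
            rules=[RuleSpec(0, 1, "ActS", eps)], seed=3,
        )
        a, b = states
        cond = (a[:-1] == 1) & (b[:-1] == 0)
        # P(B'=1 | fire condition) = eps + (1 - eps) * p_plus
        expected = eps + (1 - eps) * p_plus
        freq = (b[1:][cond] == 1).mean()
        assert abs(freq - expected) < 3 * np.sqrt(expected * (1 - expected) / cond.sum())

    def test_conflicting_rules_split_uniformly(self):
        # ActS and ActO on the same edge fire together whenever B_n = 0:
        # the winner is chosen uniformly, so B' is s or -s about equally often
        rules = [RuleSpec(0, 1, "ActS", 1.0), RuleSpec(0, 1, "ActO", 1.0)]
        states = gen_state_series(2, 20_000, rules=rules, seed=4)
        a, b = states
        cond = (a[:-1] == 1) & (b[:-1] == 0)
        same = (b[1:][cond] == 1).mean()
        assert abs(same - 0.5) < 3 * np.sqrt(0.25 / cond.sum())

    def test_seed_reproducibility_bit_identical(self):
        kwargs = dict(n_roi=6, n_time=200, rules=demo_rules(0.6)[:3], seed=9)
        np.testing.assert_array_equal(
            gen_state_series(**kwargs), gen_state_series(**kwargs)
        )

    def test_persistence_raises_autocorrelation(self):
        iid = gen_state_series(1, 20_000, seed=5)[0]
        sticky = gen_state_series(1, 20_000, seed=5, persistence=0.8)[0]
        assert np.mean(sticky[1:] == sticky[:-1]) > np.mean(iid[1:] == iid[:-1]) + 0.3

    def test_invalid_marginals_rejected(self):
        with pytest.raises(ValueError):
            gen_state_series(2, 100, marginals=(0.7, 0.6))

    def test_rule_outside_matrix_rejected(self):
        with pytest.raises(ValueError):
            gen_state_series(2, 100, rules=[RuleSpec(0, 5, "ActS", 0.5)])


class TestBoldEmission:
    def test_noiseless_emission_is_scaled_states(self):
        states = gen_state_series(3, 100, seed=0)
        signal = gen_bold_from_states(states, amplitude=2.5, noise_sd=0.0)
        np.testing.assert_array_equal(signal, states * 2.5)

    def test_low_noise_recovery_above_95_percent(self):
        states = gen_state_series(4, 5000, seed=1)
        signal = gen_bold_from_states(states, amplitude=1.0, noise_sd=0.1, seed=2)
        recovered = tx.discretize(tx.zscore(signal), threshold=0.5).states
        assert (recovered == states).mean() > 0.95

    def test_heavy_noise_recovery_near_chance(self):
        p = 0.3
        states = gen_state_series(4, 5000, marginals=(p, p), seed=3)
        signal = gen_bold_from_states(states, amplitude=1.0, noise_sd=20.0, seed=4)
        recovered = tx.discretize(tx.zscore(signal), threshold=0.5).states
        acc = (recovered == states).mean()
        # chance level: sum over states of P(true) * P(called); with theta=0.5
        # on ~N(0,1) z-scores the called fractions are ~(0.31, 0.38, 0.31)
        assert acc < 0.45

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            gen_bold_from_states(np.zeros((2, 5)), amplitude=0.0)
        with pytest.raises(ValueError):
            gen_bold_from_states(np.zeros((2, 5)), noise_sd=-1.0)


class TestMultiplexGenerator:
    def test_full_reciprocity_mirrors_every_link(self):
        net = gen_multiplex(20, n_layers=2, density=0.3, reciprocity_level=1.0, seed=0)
        for w in net.layers:
            np.testing.assert_array_equal(w, w.T)
            assert (w > 0).sum() > 0

    def test_zero_reciprocity_has_no_mutual_dyads(self):
        net = gen_multiplex(20, n_layers=2, density=0.3, reciprocity_level=0.0, seed=1)
        for w in net.layers:
            assert ((w > 0) & (w.T > 0)).sum() == 0

    def test_density_close_to_requested(self):
        for lvl in (0.0, 0.5, 1.0):
            net = gen_multiplex(
                60, n_layers=1, density=0.2, reciprocity_level=lvl, seed=2
            )
            d = tx.density(net.layers[0])
            assert abs(d - 0.2) < 0.05, (lvl, d)

    def test_planted_partition_concentrates_links_within_modules(self):
        part = np.repeat([0, 1, 2], 20)
        net = gen_multiplex(60, n_layers=1, density=0.15,
                            partition=part, module_ratio=10, seed=3)
        w = net.layers[0]
        same = part[:, None] == part[None, :]
        np.fill_diagonal(same, False)
        within = (w > 0)[same].mean()
        between = (w > 0)[~same & ~np.eye(60, dtype=bool)].mean()
        assert within > 5 * between

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            gen_multiplex(2, density=0.5)


class TestCohort:
    def test_effect_delta_shifts_group_two_only(self):
        spec = demo_cohort(n_subjects_per_group=2, effect_delta=0.2, seed=0)
        g1, g2, manifest = gen_cohort(spec)
        assert len(g1) == len(g2) == 2
        assert list(manifest.group) == [1, 1, 2, 2]

    def test_single_subject_group_rejected(self):
        with pytest.raises(ValueError):
            gen_cohort(CohortSpec(n_subjects_per_group=1))

    def test_epsilon_plus_delta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(rules=demo_rules(0.9), effect_delta=0.3)

    def test_cohort_seed_reproducibility(self):
        spec = demo_cohort(n_subjects_per_group=2, seed=5)
        a1, a2, _ = gen_cohort(spec)
        b1, b2, _ = gen_cohort(spec)
        for x, y in zip(a1 + a2, b1 + b2):
            np.testing.assert_array_equal(x, y)
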