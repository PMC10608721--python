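import numpy as np
import pytest

from fuzzysd import (
    EvolutionConfig,
    Rule,
    SubgroupDiscovery,
    build_partitions,
    classify,
    evolve,
    screen_rules,
)
from fuzzysd.engine import NOT_PARTICIPATING, nondominated_sort
from fuzzysd.quality import confusion_counts, fisher_exact_two_sided
from fuzzysd.synthetic import GeneratorConfig, generate
from conftest import SMALL_EVO, separable_table


def brute_force_fronts(F):
    """O(n^2 m) dominance oracle: peel non-dominated layers."""
    F = np.asarray(F, dtype=float)
    n = len(F)
    ranks = np.full(n, -1)
    alive = set(range(n))
    r = 0
    while alive:
        front = []
        for i in alive:
            dominated = any(
                np.all(F[j] >= F[i]) and np.any(F[j] > F[i])
                for j in alive if j != i
            )
            if not dominated:
                front.append(i)
        for i in front:
            ranks[i] = r
            alive.discard(i)
        r += 1
    return ranks


class TestNondominatedSort:
    def test_mutually_nondominated_points_share_front_one(self):
        ranks, _ = nondominated_sort([(0.9, 0.2), (0.2, 0.9), (0.5, 0.5)])
        assert list(ranks) == [0, 0, 0]

    def test_strict_dominance_splits_fronts(self):
        ranks, _ = nondominated_sort([(0.9, 0.9), (0.5, 0.5)])
        assert list(ranks) == [0, 1]

    def test_equal_vectors_share_a_front(self):
        ranks, _ = nondominated_sort([(0.5, 0.5), (0.5, 0.5), (0.1, 0.1)])
        assert ranks[0] == ranks[1] == 0 and ranks[2] == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle_on_random_points(self, seed):
        rng = np.random.default_rng(seed)
        F = rng.uniform(0, 1, size=(50, 2))
        ranks, _ = nondominated_sort(F)
        np.testing.assert_array_equal(ranks, brute_force_fronts(F))

    def test_larger_population_three_objectives(self):
        rng = np.random.default_rng(7)
        F = rng.uniform(0, 1, size=(200, 3))
        ranks, _ = nondominated_sort(F)
        np.testing.assert_array_equal(ranks, brute_force_fronts(F))

    def test_boundary_points_get_infinite_crowding(self):
        _, crowd = nondominated_sort([(0.9, 0.2), (0.2, 0.9), (0.5, 0.5)])
        assert np.isinf(crowd[0]) and np.isinf(crowd[1])


class TestInitialization:
    def test_biased_individuals_have_few_variables(self):
        table, _ = generate(GeneratorConfig(seed=0))
        eng = SubgroupDiscovery(table, "NPC1", EvolutionConfig(seed=0))
        pop = eng.initialize_population()
        cap = int(np.ceil(0.25 * table.n_features))
        n_biased = int(round(0.75 * len(pop)))
        for g in pop[:n_biased]:
            assert 1 <= np.sum(g != NOT_PARTICIPATING) <= cap

    def test_population_size_and_seeded_determinism(self):
        table, _ = generate(GeneratorConfig(seed=0))
        a = SubgroupDiscovery(table, "NPC1", EvolutionConfig(seed=4)).initialize_population()
        b = SubgroupDiscovery(table, "NPC1", EvolutionConfig(seed=4)).initialize_population()
        assert len(a) == EvolutionConfig().population_size
        np.testing.assert_array_equal(a, b)


class TestEvolve:
    def test_emitted_rules_have_nonempty_antecedent_and_target(self):
        t = separable_table(0)
        rules = evolve(t, "case", EvolutionConfig(**SMALL_EVO, seed=0))
        assert rules
        for r in rules:
            assert r.n_vars >= 1 and r.target == "case"

    def test_fixed_seed_gives_identical_rule_list(self):
        t = separable_table(1)
        cfg = EvolutionConfig(**SMALL_EVO, seed=5)
        r1 = evolve(t, "case", cfg)
        r2 = evolve(t, "case", EvolutionConfig(**SMALL_EVO, seed=5))
        assert [r.key() for r in r1] == [r.key() for r in r2]

    def test_unknown_target_class_rejected(self):
        t = separable_table(0)
        with pytest.raises(ValueError, match="target class"):
            evolve(t, "nosuch", EvolutionConfig(**SMALL_EVO, seed=0))

    def test_recovers_planted_subgroup_single_run(self):
        from fuzzysd import evaluate_recovery

        table, truth = generate(GeneratorConfig(seed=2))
        part = build_partitions(table)
        rules = evolve(table, "NPC1", EvolutionConfig(seed=2), part)
        rec = evaluate_recovery(rules, truth, table, part)[0]
        assert rec["jaccard"] >= 0.5
        assert rec["tp_rate"] >= 0.8 and rec["fp_rate"] <= 0.3


class TestScreening:
    def test_survivors_satisfy_alpha_by_direct_retest(self):
        table, _ = generate(GeneratorConfig(seed=3))
        part = build_partitions(table)
        rules = evolve(table, "NPC1", EvolutionConfig(**SMALL_EVO, seed=3), part)
        for r in rules:
            p = fisher_exact_two_sided(confusion_counts(r, table, part))
            assert p < 0.10

    def test_screening_is_idempotent_and_dedupes(self, toy_table):
        part = build_partitions(toy_table)
        good = Rule({"7.00-7.10": "high"}, "case")
        rules = [good, good, Rule({"7.20-7.30": "normal"}, "case")]
        once = screen_rules(rules, toy_table, 0.10, part)
        twice = screen_rules(once, toy_table, 0.10, part)
        assert [r.key() for r in once] == [r.key() for r in twice]
        assert len({r.key() for r in once}) == len(once)

    def test_insignificant_rule_dropped_empty_input_ok(self, toy_table):
        part = build_partitions(toy_table)
        weak = Rule({"7.20-7.30": "normal"}, "case")  # covers nearly everyone
        p = fisher_exact_two_sided(confusion_counts(weak, toy_table, part))
        assert p > 0.10
        assert screen_rules([weak], toy_table, 0.10, part) == []
        assert screen_rules([], toy_table, 0.10, part) == []


class TestClassify:
    def test_highest_compatibility_wins(self, toy_table):
        part = build_partitions(toy_table)
        sets = {
            "case": [Rule({"7.00-7.10": "high"}, "case")],
            "ctrl": [Rule({"7.00-7.10": "low"}, "ctrl")],
        }
        priors = {"case": 0.4, "ctrl": 0.6}
        out = classify(sets, part, toy_table.intensities, priors)
        assert out[:4] == ["case"] * 4
        assert out[4:] == ["ctrl"] * 6

    def test_no_rule_fires_falls_back_to_majority(self, toy_table):
        part = build_partitions(toy_table)
        sets = {"case": [Rule({"7.00-7.10": "high"}, "case")], "ctrl": []}
        priors = {"case": 0.4, "ctrl": 0.6}
        # a sample at the bottom of feature 0 fires nothing
        out = classify(sets, part, np.array([[0.05, 0.5, 1.0]]), priors)
        assert out == ["ctrl"]

    def test_no_rules_at_all_rejected(self, toy_table):
        part = build_partitions(toy_table)
        with pytest.raises(ValueError):
            classify({"case": [], "ctrl": []}, part, toy_table.intensities,
                     {"case": 0.4, "ctrl": 0.6})


class TestEvolutionConfig:
    @pytest.mark.parametrize("kwargs", [
        {"alpha": 0.0}, {"alpha": 1.0}, {"crossover_prob": 1.5},
        {"population_size": 1}, {"objectives": ("unusualness", "nope")},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EvolutionConfig(**kwargs)
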