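"""Genetic-algorithm operators and the full panel search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corepanel.errors import ConfigError, InputError
from corepanel.ga_select import (
    GAConfig,
    GAPopulation,
    brute_force_best_panel,
    chromosome_spread_tiebreak,
    crossover,
    fitness,
    init_population,
    merge_and_truncate,
    mutate,
    assemble_profiles,
    rank_fitness_linear,
    rank_fitness_nonlinear,
    roulette_pick,
    run_ga,
    selection_probabilities,
)
from corepanel.vcf_io import encode_genotypes

from conftest import StubRng, build_gm


def enc_from(calls, **kwargs):
    return encode_genotypes(build_gm(calls, **kwargs))


class TestInitPopulation:
    def test_determinism_and_invariants(self):
        pops = [
            init_population(50, 5, 10, np.random.default_rng(7)) for _ in range(2)
        ]
        for a, b in zip(pops[0].members, pops[1].members):
            assert np.array_equal(a, b)
        for panel in pops[0].members:
            assert len(panel) == 5
            assert len(np.unique(panel)) == 5
            assert panel.min() >= 0 and panel.max() < 50

    def test_full_locus_set_forced(self):
        pop = init_population(4, 4, 3, np.random.default_rng(0))
        for panel in pop.members:
            assert sorted(panel.tolist()) == [0, 1, 2, 3]

    def test_panel_too_large(self):
        with pytest.raises(ConfigError):
            init_population(3, 4, 5, np.random.default_rng(0))


class TestProfilesAndFitness:
    def test_profiles_are_ordered_tuples_not_sums(self):
        # (97, 98) and (98, 97) sum identically but must stay distinct
        enc = enc_from([[0, 2], [2, 0]])
        profiles = assemble_profiles(enc, np.array([0, 1]))
        assert profiles == [(97, 98), (98, 97)]
        assert fitness(enc, np.array([0, 1])) == 1.0

    def test_fitness_counts_unique_profiles(self):
        enc = enc_from([[0], [0], [2]])  # profiles (97),(97),(98)
        assert fitness(enc, np.array([0])) == pytest.approx(1 / 3)

    def test_fitness_extremes(self):
        distinct = enc_from([[0, 0], [1, 2], [2, 1]])
        assert fitness(distinct, np.array([0, 1])) == 1.0
        identical = enc_from([[0, 1], [0, 1], [0, 1]])
        assert fitness(identical, np.array([0, 1])) == 0.0

    def test_missing_wildcard_mode(self):
        # second sample's missing call matches the first sample's genotype
        enc = enc_from([[0, 2], [-1, 2], [2, 0]])
        assert fitness(enc, np.array([0, 1])) == 1.0
        assert fitness(enc, np.array([0, 1]), missing_wildcard=True) == pytest.approx(
            1 / 3
        )


class TestRanking:
    def test_linear_collapses_at_sp_one(self):
        assert rank_fitness_linear(5, 1.0) == pytest.approx([1.0] * 5)

    def test_linear_sp_two(self):
        assert rank_fitness_linear(3, 2.0) == pytest.approx([0.0, 1.0, 2.0])

    def test_nonlinear_base_two(self):
        assert rank_fitness_nonlinear(3, 2.0) == pytest.approx(
            [3 / 7, 6 / 7, 12 / 7]
        )

    def test_nonlinear_uniform_at_base_one(self):
        assert rank_fitness_nonlinear(4, 1.0) == pytest.approx([1.0] * 4)

    @pytest.mark.parametrize("sp", [1.0, 1.3, 1.7, 2.0])
    @pytest.mark.parametrize("n", [2, 5, 17, 50])
    def test_linear_sums_to_nind(self, n, sp):
        assert rank_fitness_linear(n, sp).sum() == pytest.approx(n, abs=1e-9)

    @pytest.mark.parametrize("base", [0.5, 1.0, 2.0, 4.0])
    @pytest.mark.parametrize("n", [2, 5, 17, 50])
    def test_nonlinear_sums_to_nind(self, n, base):
        assert rank_fitness_nonlinear(n, base).sum() == pytest.approx(n, abs=1e-9)

    def test_out_of_range_params(self):
        with pytest.raises(ConfigError):
            rank_fitness_linear(5, 2.5)
        with pytest.raises(ConfigError):
            rank_fitness_nonlinear(5, 0.0)


class TestSelection:
    def test_probabilities_normalised(self):
        probs = selection_probabilities([1.0, 1.0, 2.0])
        assert probs == pytest.approx([0.25, 0.25, 0.5])
        assert abs(probs.sum() - 1.0) < 1e-12

    def test_all_zero_gives_uniform(self):
        assert selection_probabilities([0.0, 0.0]) == pytest.approx([0.5, 0.5])

    def test_negative_fitness_rejected(self):
        with pytest.raises(InputError):
            selection_probabilities([-0.1, 1.0])

    def test_roulette_interval_membership(self):
        probs = np.array([0.5, 0.5])
        assert roulette_pick(probs, StubRng(randoms=[0.25])) == 0
        assert roulette_pick(probs, StubRng(randoms=[0.75])) == 1
        assert roulette_pick(np.array([1.0]), StubRng(randoms=[0.99])) == 0

    def test_roulette_empirical_frequencies(self):
        probs = np.array([0.2, 0.3, 0.5])
        rng = np.random.default_rng(5)
        draws = np.array([roulette_pick(probs, rng) for _ in range(10_000)])
        for k, p in enumerate(probs):
            se = np.sqrt(p * (1 - p) / 10_000)
            assert abs((draws == k).mean() - p) < 3 * se


class TestCrossover:
    def test_tail_swap_at_injected_point(self):
        a, b = np.array([1, 2, 3]), np.array([4, 5, 6])
        rng = StubRng(randoms=[0.0], integers=[2])
        c1, c2 = crossover(a, b, 1.0, rng, 10)
        assert c1.tolist() == [1, 2, 6]
        assert c2.tolist() == [4, 5, 3]

    def test_duplicate_repair_uses_smallest_absent(self):
        a, b = np.array([1, 2, 3]), np.array([3, 4, 5])
        rng = StubRng(randoms=[0.0], integers=[2])
        c1, c2 = crossover(a, b, 1.0, rng, 7)
        assert c1.tolist() == [1, 2, 5]
        # {3,4,3}: duplicate at the tail, smallest absent locus is 0
        assert c2.tolist() == [3, 4, 0]

    def test_zero_probability_keeps_parents(self):
        a, b = np.array([0, 1]), np.array([2, 3])
        c1, c2 = crossover(a, b, 0.0, np.random.default_rng(0), 5)
        assert c1.tolist() == [0, 1] and c2.tolist() == [2, 3]

    def test_single_locus_panels_degenerate(self):
        a, b = np.array([0]), np.array([3])
        c1, c2 = crossover(a, b, 1.0, np.random.default_rng(0), 5)
        assert c1.tolist() == [0] and c2.tolist() == [3]


class TestMutate:
    def test_mutation_bit_count(self):
        panel = np.arange(10)
        rng = StubRng(randoms=[0.0], seed=1)
        out = mutate(panel, 1.0, 0.3, rng, 40)
        assert (out != panel).sum() <= 3
        assert len(np.unique(out)) == 10

    def test_rounding_half_away_from_zero(self):
        # C=3, fraction 0.3 -> round(0.9) = 1 position
        panel = np.array([0, 1, 2])
        moved = []
        for seed in range(20):
            out = mutate(panel, 1.0, 0.3, StubRng(randoms=[0.0], seed=seed), 50)
            moved.append(int((out != panel).sum()))
        assert max(moved) == 1

    def test_zero_probability_unchanged(self):
        panel = np.array([3, 1, 4])
        out = mutate(panel, 0.0, 0.3, np.random.default_rng(0), 10)
        assert out.tolist() == [3, 1, 4]

    def test_panel_equals_universe_still_valid(self):
        panel = np.arange(5)
        out = mutate(panel, 1.0, 1.0, np.random.default_rng(2), 5)
        assert sorted(out.tolist()) == [0, 1, 2, 3, 4]

    @given(st.integers(0, 10_000), st.integers(2, 12), st.integers(12, 30))
    @settings(max_examples=60, derandomize=True)
    def test_operators_preserve_panel_invariants(self, seed, c, m):
        rng = np.random.default_rng(seed)
        a = rng.choice(m, size=c, replace=False)
        b = rng.choice(m, size=c, replace=False)
        c1, c2 = crossover(a, b, 0.9, rng, m)
        for child in (mutate(c1, 0.9, 0.3, rng, m), mutate(c2, 0.9, 0.3, rng, m)):
            assert len(child) == c
            assert len(np.unique(child)) == c
            assert child.min() >= 0 and child.max() < m


class TestMergeAndTruncate:
    def test_elitism_and_constant_size(self):
        parents = GAPopulation(
            [np.array([0, 1]), np.array([2, 3])], np.array([0.9, 0.4])
        )
        offspring = GAPopulation(
            [np.array([4, 5]), np.array([1, 0])], np.array([0.7, 0.9])
        )
        merged = merge_and_truncate(parents, offspring, 2)
        assert merged.size == 2
        assert merged.fitnesses[0] == 0.9
        assert merged.members[0].tolist() == [0, 1]  # duplicate set removed

    def test_refill_after_total_duplication(self):
        enc = enc_from(np.random.default_rng(0).choice([0, 1, 2], size=(6, 8)))
        members = [np.array([0, 1]), np.array([1, 0])]
        pop = GAPopulation(members, np.array([0.5, 0.5]))
        merged = merge_and_truncate(
            pop, GAPopulation(list(members), np.array([0.5, 0.5])), 3,
            enc=enc, rng=np.random.default_rng(1),
        )
        assert merged.size == 3
        keys = {tuple(sorted(m.tolist())) for m in merged.members}
        assert len(keys) == 3


class TestRunGa:
    def test_single_discriminating_locus(self):
        # locus 0 alone separates all three samples
        enc = enc_from([[0, 0], [1, 0], [2, 0]])
        cfg = GAConfig(panel_size=1, population_size=2, max_iterations=10, rng_seed=0)
        res = run_ga(enc, cfg)
        assert res.fitnesses[0] == 1.0
        assert res.chosen_panel.tolist() == [0]

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(9)
        enc = enc_from(rng.choice([0, 1, 2], size=(10, 20)))
        cfg = GAConfig(panel_size=4, population_size=8, max_iterations=15, rng_seed=123)
        r1, r2 = run_ga(enc, cfg), run_ga(enc, cfg)
        assert r1.best_fitness == r2.best_fitness
        assert r1.mean_fitness == r2.mean_fitness
        assert np.array_equal(r1.chosen_panel, r2.chosen_panel)
        for a, b in zip(r1.panels, r2.panels):
            assert np.array_equal(a, b)

    def test_best_trace_non_decreasing_and_sizes(self):
        rng = np.random.default_rng(2)
        enc = enc_from(rng.choice([0, 1, 2], size=(12, 18)))
        cfg = GAConfig(
            panel_size=3, population_size=10, max_iterations=25, rng_seed=4,
            ranking="linear", sp=1.6,
        )
        res = run_ga(enc, cfg)
        trace = np.array(res.best_fitness)
        assert (np.diff(trace) >= 0).all()
        assert len(res.panels) == 10
        for panel in res.panels:
            assert len(np.unique(panel)) == 3


class TestBruteForce:
    def test_only_panel_when_m_equals_c(self):
        enc = enc_from([[0, 1], [2, 1]])
        panel, fit = brute_force_best_panel(enc, 2)
        assert panel.tolist() == [0, 1]
        assert fit == 1.0

    def test_agrees_with_fitness_everywhere(self):
        rng = np.random.default_rng(6)
        enc = enc_from(rng.choice([0, 1, 2], size=(6, 7)))
        panel, fit = brute_force_best_panel(enc, 2)
        from itertools import combinations

        fits = {c: fitness(enc, np.array(c)) for c in combinations(range(7), 2)}
        assert fit == max(fits.values())
        assert fit == fits[tuple(panel.tolist())]

    def test_guard_refuses_large_enumerations(self):
        enc = enc_from(np.zeros((2, 60), dtype=np.int8))
        with pytest.raises(InputError):
            brute_force_best_panel(enc, 10, guard=1000)


class TestTiebreak:
    def test_even_spread_wins(self):
        gm = build_gm(
            np.zeros((2, 8), dtype=np.int8),
            chroms=["1"] * 4 + ["2"] * 4,
            positions=[1, 2, 3, 4, 1, 2, 3, 4],
        )
        lopsided = np.array([0, 1, 2, 3])  # (4, 0)
        spread = np.array([0, 1, 4, 5])  # (2, 2)
        assert chromosome_spread_tiebreak([lopsided, spread], gm.loci) is spread

    def test_exact_tie_goes_lexicographic(self):
        gm = build_gm(np.zeros((2, 6), dtype=np.int8))
        a, b = np.array([0, 3]), np.array([0, 2])
        assert chromosome_spread_tiebreak([a, b], gm.loci) is b

    def test_single_candidate(self):
        gm = build_gm(np.zeros((2, 3), dtype=np.int8))
        only = np.array([1, 2])
        assert chromosome_spread_tiebreak([only], gm.loci) is only

    def test_empty_candidates_rejected(self):
        with pytest.raises(InputError):
            chromosome_spread_tiebreak([], [])
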