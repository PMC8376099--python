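"""GA operators, adaptation schedule and the fitting driver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from degroot_ga.core import (
    Network,
    OpinionTrajectory,
    WeightMatrix,
    objective_continuous,
    simulate_diffusion,
)
from degroot_ga.ga import (
    Chromosome,
    FixedMask,
    GAConfig,
    GAState,
    adapt_hyperparameters,
    blend,
    blend_genes,
    crossover,
    evaluate,
    fit,
    gene_swap,
    init_population,
    mutate,
    mutate_gene_values,
    reintroduce,
    select_elite,
    survival,
)

from conftest import random_weight_matrix


def _is_valid(w: np.ndarray, fixed: FixedMask) -> bool:
    return (
        np.abs(w.sum(axis=1) - 1.0).max() < 1e-9
        and (w >= -1e-12).all()
        and (w[fixed.fixed] == fixed.values[fixed.fixed]).all()
    )


class TestFixedMask:
    def test_adjacency_zeros_are_fixed(self, complete3):
        net = Network(np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]]))
        fx = FixedMask.from_network(net)
        assert fx.fixed[0, 2] and fx.fixed[2, 0]
        assert not fx.fixed[0, 1]

    def test_rejects_overfull_fixed_rows(self):
        f = np.array([[True, False], [False, False]])
        v = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(ValueError):
            FixedMask(f, v)

    def test_diagonal_chromosome_is_identity_on_complete_network(self, fixed3):
        np.testing.assert_array_equal(fixed3.diagonal_chromosome(), np.eye(3))


class TestInitPopulation:
    def test_population_composition_and_validity(self, complete3, fixed3, rng):
        cfg = GAConfig()
        pop = init_population(complete3, fixed3, cfg, rng)
        assert len(pop) == 21
        diag = [c for c in pop
                if np.array_equal(c.weights, fixed3.diagonal_chromosome())]
        assert len(diag) == 1
        for c in pop:
            assert _is_valid(c.weights, fixed3)

    def test_respects_extra_fixed_values(self, complete3, rng):
        extra = np.zeros((3, 3), dtype=bool)
        extra[0, 1] = True
        vals = np.zeros((3, 3))
        vals[0, 1] = 0.25
        fx = FixedMask.from_network(complete3, extra, vals)
        pop = init_population(complete3, fx, GAConfig(), rng)
        for c in pop:
            assert c.weights[0, 1] == 0.25
            assert _is_valid(c.weights, fx)


class TestEvaluate:
    def test_true_weights_give_zero_on_noiseless_data(self, noiseless3, fixed3):
        net, w, traj = noiseless3
        chrom = evaluate(Chromosome(w.weights, fixed3), traj)
        assert chrom.total_objective == pytest.approx(0.0, abs=1e-12)

    def test_identity_vs_consensus_toy(self):
        net = Network.complete(2)
        fx = FixedMask.from_network(net)
        obs = simulate_diffusion(
            WeightMatrix([[0.5, 0.5], [0.5, 0.5]]), np.array([0.0, 1.0]), 1)
        chrom = evaluate(Chromosome(np.eye(2), fx), obs)
        assert chrom.total_objective == pytest.approx(0.5)
        np.testing.assert_allclose(chrom.gene_objectives, [0.25, 0.25])

    def test_gene_objectives_sum_to_total(self, noiseless3, fixed3, rng):
        net, _, traj = noiseless3
        chrom = evaluate(
            Chromosome(random_weight_matrix(3, rng).weights, fixed3), traj)
        assert chrom.gene_objectives.sum() == pytest.approx(
            chrom.total_objective, abs=1e-12)

    def test_missing_initial_opinion_rejected(self, fixed3, complete3):
        mask = np.ones((3, 3), dtype=bool)
        mask[1, 0] = False
        obs = OpinionTrajectory(np.full((3, 3), 0.5), mask)
        with pytest.raises(ValueError):
            evaluate(Chromosome(np.eye(3), fixed3), obs)


class TestGeneSwap:
    def test_no_others_is_noop(self, noiseless3, fixed3):
        net, w, traj = noiseless3
        c = evaluate(Chromosome(w.weights, fixed3), traj)
        best, others, accepted = gene_swap(c, [], traj)
        assert not accepted and best is c and others == []

    def test_beneficial_swap_retained_and_genes_exchanged(self):
        net = Network.complete(2)
        fx = FixedMask.from_network(net)
        w_true = WeightMatrix([[0.7, 0.3], [0.2, 0.8]])
        obs = simulate_diffusion(w_true, np.array([0.1, 0.9]), 5)
        # best holds the true gene 0, donor the true gene 1
        a = evaluate(Chromosome(np.array([[0.7, 0.3], [0.5, 0.5]]), fx), obs)
        b = evaluate(Chromosome(np.array([[0.4, 0.6], [0.2, 0.8]]), fx), obs)
        best, others, accepted = gene_swap(a, [b], obs)
        assert accepted
        assert best.total_objective == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(best.weights, w_true.weights)
        # the donor received the best's old gene (a swap, not a copy)
        np.testing.assert_allclose(others[0].weights[1], [0.5, 0.5])
        # re-evaluation matches an independent computation
        pred = simulate_diffusion(
            WeightMatrix(others[0].weights), obs.values[:, 0], 5)
        assert others[0].total_objective == pytest.approx(
            objective_continuous(pred, obs))

    def test_detrimental_swaps_reverted_en_bloc(self):
        # donated genes are fitter in their own context but hurt the best
        # chromosome; everything must revert
        net = Network.complete(2)
        fx = FixedMask.from_network(net)
        w_true = WeightMatrix([[0.6, 0.4], [0.3, 0.7]])
        obs = simulate_diffusion(w_true, np.array([0.05, 0.95]), 5)
        best0 = evaluate(
            Chromosome(np.array([[0.62, 0.38], [0.31, 0.69]]), fx), obs)
        # donor's gene 0 scores better in the donor's context (its gene 1
        # compensates) but transplanting it into best makes best worse
        donor = evaluate(
            Chromosome(np.array([[0.5, 0.5], [0.36, 0.64]]), fx), obs)
        if donor.gene_objectives[0] < best0.gene_objectives[0]:
            best, others, accepted = gene_swap(best0, [donor], obs)
            if not accepted:
                np.testing.assert_array_equal(best.weights, best0.weights)
                np.testing.assert_array_equal(others[0].weights, donor.weights)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_never_increases_best_objective(self, seed):
        rng = np.random.default_rng(seed)
        net = Network.complete(3)
        fx = FixedMask.from_network(net)
        obs = simulate_diffusion(random_weight_matrix(3, rng),
                                 rng.uniform(0, 1, 3), 4)
        chroms = [
            evaluate(Chromosome(random_weight_matrix(3, rng).weights, fx), obs)
            for _ in range(4)
        ]
        elite, rest = select_elite(chroms)
        best, _, _ = gene_swap(elite, rest, obs)
        assert best.total_objective <= elite.total_objective + 1e-15


class TestSelectElite:
    def test_unique_minimum_and_tie_break(self, fixed3):
        mk = lambda t: Chromosome(np.eye(3), fixed3, np.zeros(3), t)
        pop = [mk(0.5), mk(0.2), mk(0.2), mk(0.9)]
        elite, rest = select_elite(pop)
        assert elite is pop[1]
        assert len(rest) == 3 and pop[2] in rest


class TestBlend:
    def test_beta_one_is_identity_and_half_is_average(self, fixed3):
        b = np.array([0.2, 0.3, 0.5])
        c = np.array([0.6, 0.1, 0.3])
        ob, oc = blend_genes(b, c, 1.0, fixed3, 0)
        np.testing.assert_allclose(ob, b)
        np.testing.assert_allclose(oc, c)
        ob, oc = blend_genes(b, c, 0.5, fixed3, 0)
        np.testing.assert_allclose(ob, (b + c) / 2)
        np.testing.assert_allclose(ob, oc)

    def test_hand_arithmetic(self):
        fx = FixedMask.from_network(Network.complete(2))
        ob, oc = blend_genes([0.2, 0.8], [0.6, 0.4], 0.3, fx, 0)
        np.testing.assert_allclose(ob, [0.48, 0.52])
        np.testing.assert_allclose(oc, [0.32, 0.68])

    def test_fixed_entries_untouched_and_rows_stochastic(self, rng):
        net = Network(np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]]))
        fx = FixedMask.from_network(net)
        a = Chromosome(random_weight_matrix(3, rng, net).weights, fx)
        b = Chromosome(random_weight_matrix(3, rng, net).weights, fx)
        oa, ob = blend((a, b), 1.0, rng)
        for o in (oa, ob):
            assert _is_valid(o.weights, fx)


class TestCrossover:
    def test_single_free_entry_unchanged(self, rng):
        net = Network(np.array([[1, 1], [1, 1]]))
        extra = np.zeros((2, 2), dtype=bool)
        extra[0, 1] = True
        vals = np.zeros((2, 2))
        vals[0, 1] = 0.4
        fx = FixedMask.from_network(net, extra, vals)
        c = Chromosome(np.array([[0.6, 0.4], [0.5, 0.5]]), fx)
        out = crossover(c, 1.0, rng)
        np.testing.assert_array_equal(out.weights[0], [0.6, 0.4])

    def test_permutation_preserves_multiset_and_sum(self, fixed3, rng):
        c = Chromosome(np.array([[0.1, 0.6, 0.3]] * 3), fixed3)
        out = crossover(c, 1.0, rng)
        for i in range(3):
            assert sorted(out.weights[i]) == [0.1, 0.3, 0.6]
            assert out.weights[i].sum() == pytest.approx(1.0, abs=1e-12)

    def test_permutations_uniform(self, fixed3, rng):
        # Monte Carlo over 10,000 crossovers of a 3-entry row
        from collections import Counter

        counts = Counter()
        base = Chromosome(
            np.array([[0.1, 0.6, 0.3], [1 / 3] * 3, [1 / 3] * 3]), fixed3)
        for _ in range(10_000):
            out = crossover(base, 1.0, rng)
            counts[tuple(out.weights[0])] += 1
        assert len(counts) == 6
        for k, v in counts.items():
            assert v / 10_000 == pytest.approx(1 / 6, abs=0.02)


class TestMutate:
    """The three boundary rules plus the generic rescale."""

    def test_negative_perturbation_clips_to_zero(self, rng):
        fx = FixedMask.from_network(Network.complete(2))
        out = mutate_gene_values([0.5, 0.5], fx, 0, selected=0, eps=-0.7)
        np.testing.assert_allclose(out, [0.0, 1.0])

    def test_full_weight_redistributes_evenly(self):
        fx = FixedMask.from_network(Network.complete(3))
        out = mutate_gene_values([1.0, 0.0, 0.0], fx, 0, selected=0, eps=-0.4)
        np.testing.assert_allclose(out, [0.6, 0.2, 0.2])

    def test_overflow_takes_all_free_mass(self):
        fx = FixedMask.from_network(Network.complete(2))
        out = mutate_gene_values([0.4, 0.6], fx, 0, selected=0, eps=0.8)
        np.testing.assert_allclose(out, [1.0, 0.0])

    def test_generic_rescale_keeps_row_stochastic(self):
        fx = FixedMask.from_network(Network.complete(3))
        out = mutate_gene_values([0.3, 0.3, 0.4], fx, 0, selected=0, eps=0.1)
        np.testing.assert_allclose(out[0], 0.4)
        np.testing.assert_allclose(out[1:] / np.array([0.3, 0.4]),
                                   (1 - 0.4) / (1 - 0.3))
        assert out.sum() == pytest.approx(1.0, abs=1e-12)

    def test_overflow_respects_fixed_mass(self):
        net = Network.complete(3)
        extra = np.zeros((3, 3), dtype=bool)
        extra[0, 2] = True
        vals = np.zeros((3, 3))
        vals[0, 2] = 0.3
        fx = FixedMask.from_network(net, extra, vals)
        out = mutate_gene_values([0.4, 0.3, 0.3], fx, 0, selected=0, eps=0.9)
        np.testing.assert_allclose(out, [0.7, 0.0, 0.3])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_random_mutations_stay_valid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        net = Network.complete(n)
        fx = FixedMask.from_network(net)
        c = Chromosome(random_weight_matrix(n, rng).weights, fx)
        out = mutate(c, 1.0, float(rng.uniform(0.1, 2.0)), fx, rng)
        assert _is_valid(out.weights, fx)


class TestSurvival:
    def test_ties_keep_parents(self, noiseless3, fixed3, rng):
        _, _, traj = noiseless3
        parents = [
            evaluate(Chromosome(random_weight_matrix(3, rng).weights, fixed3),
                     traj)
            for _ in range(3)
        ]
        out = survival(parents, [Chromosome(p.weights.copy(), fixed3)
                                 for p in parents], traj)
        for o, p in zip(out, parents):
            np.testing.assert_array_equal(o.weights, p.weights)

    def test_strictly_better_offspring_replace_parents(self, noiseless3,
                                                       fixed3, rng):
        net, w_true, traj = noiseless3
        parents = [
            evaluate(Chromosome(random_weight_matrix(3, rng).weights, fixed3),
                     traj)
            for _ in range(2)
        ]
        offspring = [Chromosome(w_true.weights.copy(), fixed3)] * 2
        out = survival(parents, offspring, traj)
        for o in out:
            assert o.total_objective == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_retained_never_worse_than_either_pair_member(self, seed):
        rng = np.random.default_rng(seed)
        net = Network.complete(3)
        fx = FixedMask.from_network(net)
        traj = simulate_diffusion(random_weight_matrix(3, rng),
                                  rng.uniform(0, 1, 3), 4)
        parents = [
            evaluate(Chromosome(random_weight_matrix(3, rng).weights, fx),
                     traj)
            for _ in range(3)
        ]
        offspring = [
            evaluate(Chromosome(random_weight_matrix(3, rng).weights, fx),
                     traj)
            for _ in range(3)
        ]
        out = survival(parents, offspring, traj)
        for o, p, c in zip(out, parents, offspring):
            assert o.total_objective <= min(p.total_objective,
                                            c.total_objective) + 1e-15
            # re-evaluation agrees with an independent computation
            pred = simulate_diffusion(WeightMatrix(o.weights),
                                      traj.values[:, 0], traj.n_times - 1)
            assert o.total_objective == pytest.approx(
                objective_continuous(pred, traj))


class TestAdaptation:
    def test_schedule_after_stagnation(self):
        cfg = GAConfig()
        state = GAState.from_config(cfg)
        for _ in range(1000):
            state = adapt_hyperparameters(state, cfg)
        assert state.current_pb == pytest.approx(0.02)
        assert state.current_pc == pytest.approx(0.1)
        assert state.current_pm == pytest.approx(0.1)
        assert state.current_sigma == pytest.approx(1.0)  # iters = 2000
        for _ in range(1000):
            state = adapt_hyperparameters(state, cfg)
        assert state.current_sigma == pytest.approx(0.5)

    def test_bounds_are_respected_indefinitely(self):
        cfg = GAConfig()
        state = GAState.from_config(cfg)
        for _ in range(30_000):
            state = adapt_hyperparameters(state, cfg)
        assert state.current_pb <= 0.2
        assert state.current_pm >= 0.01
        assert state.current_sigma >= 0.001

    def test_improvement_resets_counters(self):
        cfg = GAConfig()
        state = GAState.from_config(cfg)
        for _ in range(999):
            state = adapt_hyperparameters(state, cfg)
        state = adapt_hyperparameters(state, cfg, improved=True)
        assert all(v == 0 for v in state.counters.values())
        assert state.current_pb == cfg.probb


class TestReintroduce:
    def _pop(self, fixed3, rng, traj):
        return [
            evaluate(Chromosome(random_weight_matrix(3, rng).weights, fixed3),
                     traj)
            for _ in range(4)
        ]

    def test_elite_mode_duplicates_elite(self, noiseless3, fixed3, rng):
        _, _, traj = noiseless3
        pop = self._pop(fixed3, rng, traj)
        elite, _ = select_elite(pop)
        out = reintroduce(pop, elite, fixed3, GAConfig(reintroduce="elite"))
        assert len(out) == len(pop)
        matches = sum(np.array_equal(c.weights, elite.weights) for c in out)
        assert matches >= 2

    def test_diagonal_mode_inserts_identity(self, noiseless3, fixed3, rng):
        _, _, traj = noiseless3
        pop = self._pop(fixed3, rng, traj)
        elite, _ = select_elite(pop)
        out = reintroduce(pop, elite, fixed3, GAConfig(reintroduce="diagonal"))
        worst = int(np.argmax([c.total_objective for c in pop]))
        np.testing.assert_array_equal(out[worst].weights, np.eye(3))


class TestFit:
    def test_noiseless_recovery_on_complete_network(self, noiseless3):
        net, w_true, traj = noiseless3
        res = fit(traj, net, config=GAConfig(max_iter=50_000), seed=11)
        assert res.objective < 1e-4

    def test_identical_seeds_are_bit_identical(self, noiseless3):
        net, _, traj = noiseless3
        cfg = GAConfig(max_iter=3000)
        a = fit(traj, net, config=cfg, seed=5)
        b = fit(traj, net, config=cfg, seed=5)
        assert a.objective == b.objective
        np.testing.assert_array_equal(a.weights.weights, b.weights.weights)
        assert a.history == b.history

    def test_history_is_non_increasing_and_matches_final(self, noiseless3):
        net, _, traj = noiseless3
        res = fit(traj, net, config=GAConfig(max_iter=1000), seed=3)
        vals = [v for _, v in res.history]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert res.objective == pytest.approx(vals[-1])

    def test_result_satisfies_weight_invariants(self, rng):
        net = Network(np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]]))
        fx = FixedMask.from_network(net)
        w_true = random_weight_matrix(3, rng, net)
        traj = simulate_diffusion(w_true, rng.uniform(0, 1, 3), 5)
        res = fit(traj, net, config=GAConfig(max_iter=2000), seed=1)
        assert _is_valid(res.weights.weights, fx)

    def test_stationary_population_with_zero_probabilities(self, noiseless3):
        # with p_b = p_c = p_m = 0 only gene swaps act; the run must still
        # be monotone and valid
        net, _, traj = noiseless3
        cfg = GAConfig(probb=0.0, probc=0.0, probm=0.0, maxb=0.0,
                       minc=0.0, minm=0.0, max_iter=500)
        res = fit(traj, net, config=cfg, seed=2)
        vals = [v for _, v in res.history]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_min_dev_stops_early(self):
        net = Network.complete(2)
        w = WeightMatrix([[0.5, 0.5], [0.5, 0.5]])
        traj = simulate_diffusion(w, np.array([0.0, 1.0]), 3)
        res = fit(traj, net, config=GAConfig(max_iter=100_000, min_dev=1e-3),
                  seed=0)
        assert res.objective <= 1e-3
        assert res.iterations < 100_000

    def test_rejects_single_time_step(self, complete3):
        obs = OpinionTrajectory(np.full((3, 1), 0.5))
        with pytest.raises(ValueError):
            fit(obs, complete3, config=GAConfig(max_iter=10), seed=0)
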