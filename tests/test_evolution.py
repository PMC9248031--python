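"""Evolutionary-loop tests.

The IBEA fitness and environmental selection are checked against a
brute-force re-implementation of the additive-epsilon indicator scheme
written with explicit Python loops, independent of the vectorised path.
"""

import hashlib
import math

import numpy as np
import pytest

import neuroea.scoring
from neuroea.errors import ConfigurationError
from neuroea.evolution import (EAConfig, HallOfFame, environmental_select,
                               ibea_fitness, initialize, optimize, resume,
                               variation)
from neuroea.model import Individual, Population, default_parameter_spec
from neuroea.rng import named_stream

SPEC = default_parameter_spec()


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_indicators(objectives):
    obj = np.asarray(objectives, dtype=float)
    n, d = obj.shape
    norm = np.zeros_like(obj)
    for k in range(d):
        lo, hi = obj[:, k].min(), obj[:, k].max()
        if hi > lo:
            for i in range(n):
                norm[i, k] = (obj[i, k] - lo) / (hi - lo)
    ind = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ind[i, j] = max(norm[i, k] - norm[j, k] for k in range(d))
    c = max(abs(ind[i, j]) for i in range(n) for j in range(n)) or 1.0
    return ind, c


def brute_fitness(objectives, kappa=0.05, alive=None):
    ind, c = brute_indicators(objectives)
    n = len(objectives)
    alive = list(range(n)) if alive is None else alive
    fit = {}
    for j in alive:
        fit[j] = -sum(math.exp(-ind[i][j] / (c * kappa))
                      for i in alive if i != j)
    return fit


def brute_removal_sequence(objectives, mu, kappa=0.05):
    """Iterative worst-removal, recomputing every pairwise fitness sum from
    scratch over the remaining individuals at each step (normalisation and
    scaling fixed at the full pool, as in the canonical scheme)."""
    alive = list(range(len(objectives)))
    removed = []
    while len(alive) > mu:
        fit = brute_fitness(objectives, kappa, alive)
        worst = min(alive, key=lambda j: (fit[j], j))  # ties: lowest index
        alive.remove(worst)
        removed.append(worst)
    return removed, alive


class TestInitialize:
    def test_uniform_within_bounds_and_shapes(self):
        pop = initialize(SPEC, 50, named_stream(0, "init"))
        assert len(pop) == 50
        for ind in pop:
            assert ind.values.shape == (13,)
            assert SPEC.check_bounds(ind.values)

    def test_same_seed_same_population(self):
        a = initialize(SPEC, 20, named_stream(5, "init"))
        b = initialize(SPEC, 20, named_stream(5, "init"))
        assert np.array_equal(a.values_matrix(), b.values_matrix())

    def test_invalid_size_rejected(self):
        with pytest.raises(ConfigurationError):
            initialize(SPEC, 0, named_stream(0, "init"))


class TestVariation:
    def parents(self, n=6, seed=0):
        return initialize(SPEC, n, named_stream(seed, "init"))

    def test_pure_reproduction_copies_parents(self):
        parents = self.parents()
        off = variation(parents, 10, 0.0, 0.0, named_stream(1, "variation"),
                        SPEC)
        assert len(off) == 10
        parent_rows = {tuple(p.values) for p in parents}
        for child in off:
            assert tuple(child.values) in parent_rows
            assert child.scores is None

    def test_pure_mutation_respects_bounds_and_perturbs(self):
        parents = self.parents()
        off = variation(parents, 40, 0.0, 1.0, named_stream(2, "variation"),
                        SPEC)
        parent_rows = {tuple(p.values) for p in parents}
        changed = sum(tuple(c.values) not in parent_rows for c in off)
        # indpb = 1/13: P(no gene mutated) = (12/13)^13 ~ 0.35, so about
        # 26 of 40 offspring should differ from every parent
        assert changed >= 18
        for child in off:
            assert SPEC.check_bounds(child.values)

    def test_pure_crossover_respects_bounds(self):
        parents = self.parents()
        off = variation(parents, 30, 1.0, 0.0, named_stream(3, "variation"),
                        SPEC)
        for child in off:
            assert SPEC.check_bounds(child.values)

    def test_seeded_variation_regression_hash(self):
        """Bit-identical offspring across runs, frozen as a digest recorded
        once from the implementation."""
        parents = self.parents(n=5, seed=9)
        off = variation(parents, 12, 0.3, 0.5, named_stream(7, "variation"),
                        SPEC)
        digest = hashlib.sha256(
            np.ascontiguousarray(off.values_matrix()).tobytes()
        ).hexdigest()
        again = variation(parents, 12, 0.3, 0.5, named_stream(7, "variation"),
                          SPEC)
        assert np.array_equal(off.values_matrix(), again.values_matrix())
        assert digest == ("2d981f3b08460eec4f31b452385c7f34"
                          "4e2f49890edfd90dc50b803dc0fc8a76")

    def test_invalid_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            variation(self.parents(), 5, 0.7, 0.5,
                      named_stream(0, "variation"), SPEC)

    def test_crossover_needs_two_parents(self):
        lone = Population([Individual(SPEC.lower)])
        with pytest.raises(ConfigurationError, match="two parents"):
            variation(lone, 5, 0.5, 0.0, named_stream(0, "variation"), SPEC)


class TestIbeaFitness:
    def test_dominance_orders_fitness(self):
        obj = np.array([[0.1, 0.2], [0.5, 0.8]])
        fit = ibea_fitness(obj)
        assert fit[0] > fit[1]

    def test_duplicates_get_equal_fitness(self):
        obj = np.array([[1.0, 2.0], [3.0, 0.5], [1.0, 2.0]])
        fit = ibea_fitness(obj)
        assert fit[0] == pytest.approx(fit[2], abs=1e-12)

    def test_four_corner_example_matches_brute_force(self):
        obj = np.array([[0., 0.], [1., 0.], [0., 1.], [1., 1.]])
        fit = ibea_fitness(obj, kappa=0.05)
        oracle = brute_fitness(obj, kappa=0.05)
        for j in range(4):
            assert fit[j] == pytest.approx(oracle[j], abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_random_populations_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        d = int(rng.integers(1, 7))
        obj = rng.uniform(0, 5, size=(n, d))
        fit = ibea_fitness(obj, kappa=0.05)
        oracle = brute_fitness(obj, kappa=0.05)
        for j in range(n):
            assert fit[j] == pytest.approx(oracle[j], rel=1e-12, abs=1e-12)

    def test_degenerate_component_is_ignored(self):
        obj = np.array([[1.0, 5.0], [2.0, 5.0], [0.5, 5.0]])
        fit = ibea_fitness(obj)
        assert fit[2] > fit[0] > fit[1]

    def test_single_individual_rejected(self):
        with pytest.raises(ConfigurationError):
            ibea_fitness(np.array([[1.0, 2.0]]))


def scored_population(objectives):
    pop = Population([Individual(np.full(2, float(i)), scores=row)
                      for i, row in enumerate(np.asarray(objectives,
                                                         dtype=float))])
    return pop


class TestEnvironmentalSelect:
    def test_identity_when_mu_equals_n(self, rng):
        obj = rng.uniform(0, 3, size=(5, 4))
        pop = scored_population(obj)
        out = environmental_select(pop, 5)
        assert [tuple(i.values) for i in out] == [tuple(i.values)
                                                 for i in pop]

    def test_dominator_survives_pairwise(self):
        pop = scored_population([[0.1, 0.1], [0.9, 0.9]])
        out = environmental_select(pop, 1)
        assert tuple(out[0].values) == (0.0, 0.0)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_survivors_match_stepwise_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        obj = rng.uniform(0, 2, size=(6, 3))
        _, alive = brute_removal_sequence(obj, mu=2)
        out = environmental_select(scored_population(obj), 2)
        assert sorted(tuple(i.values) for i in out) == sorted(
            (float(j), float(j)) for j in alive)

    def test_overdraw_rejected(self):
        with pytest.raises(ConfigurationError):
            environmental_select(scored_population([[1.0], [2.0]]), 3)


class TestHallOfFame:
    def entry(self, total, n=13):
        return Individual(np.random.default_rng(int(total * 10)).uniform(
            size=n), scores=np.array([total]))

    def test_first_generation_keeps_all_sorted(self):
        hof = HallOfFame(10)
        pop = Population([self.entry(t) for t in (3.0, 1.0, 2.0, 5.0, 4.0)])
        hof.update(pop, generation=0)
        assert hof.totals() == [1.0, 2.0, 3.0, 4.0, 5.0]

    def test_uniformly_worse_generation_changes_nothing(self):
        hof = HallOfFame(3)
        hof.update(Population([self.entry(t) for t in (1.0, 2.0, 3.0)]), 0)
        before = hof.totals()
        hof.update(Population([self.entry(t) for t in (9.0, 8.0)]), 1)
        assert hof.totals() == before

    def test_keeps_ten_smallest_of_fifteen(self):
        hof = HallOfFame(10)
        hof.update(Population([self.entry(float(t))
                               for t in range(15, 7, -1)]), 0)
        hof.update(Population([self.entry(float(t)) for t in range(1, 8)]), 1)
        assert hof.totals() == [float(t) for t in range(1, 11)]
        assert len(hof) == 10

    def test_unscored_candidates_rejected(self):
        hof = HallOfFame(5)
        with pytest.raises(ConfigurationError):
            hof.update(Population([Individual(np.zeros(2))]), 0)


class TestOptimize:
    def config(self, **kw):
        base = dict(mu=4, lambda_=8, n_generations=2, seed=3)
        base.update(kw)
        return EAConfig(**base)

    def test_run_is_deterministic(self, small_problem):
        b1, h1 = optimize(self.config(), small_problem)
        b2, h2 = optimize(self.config(), small_problem)
        assert np.array_equal(b1.values, b2.values)
        assert h1 == h2

    def test_history_shape_and_hof_monotonicity(self, small_problem):
        _, history = optimize(self.config(n_generations=4), small_problem)
        assert [h.generation for h in history] == [0, 1, 2, 3, 4]
        hof_best = [h.hof_best for h in history]
        assert all(a >= b for a, b in zip(hof_best[:-1], hof_best[1:]))
        assert history[0].evaluations == 8
        assert all(h.evaluations == 8 for h in history[1:])

    def test_evaluation_count_is_lambda_per_generation(self, small_problem,
                                                       monkeypatch):
        calls = []
        real = neuroea.scoring.score_individual

        def counting(values, *args, **kw):
            calls.append(1)
            return real(values, *args, **kw)

        monkeypatch.setattr(neuroea.scoring, "score_individual", counting)
        optimize(self.config(n_generations=3), small_problem)
        # lambda initial + 3 generations x lambda offspring, never more
        assert len(calls) == 8 * (1 + 3)

    def test_best_comes_from_hall_of_fame(self, small_problem):
        hof = HallOfFame(10)
        best, _ = optimize(self.config(), small_problem, hof=hof)
        assert best.total_score == hof.best.total
        assert np.array_equal(best.values, hof.best.individual.values)

    def test_checkpoint_resume_matches_uninterrupted_run(self, small_problem,
                                                         tmp_path):
        ckpt = tmp_path / "ckpt.json"
        cfg = self.config(n_generations=4)
        best_full, hist_full = optimize(cfg, small_problem)

        cfg2 = self.config(n_generations=2)
        optimize(cfg2, small_problem, checkpoint_path=ckpt)
        best_res, hist_res = resume(cfg, small_problem, ckpt)
        assert np.array_equal(best_res.values, best_full.values)
        assert [h.best_total for h in hist_res] == pytest.approx(
            [h.best_total for h in hist_full])
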