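"""Genetic-algorithm operators, fitness, search, and final evaluation."""

import numpy as np
import pandas as pd
import pytest

import immunosig as im
from immunosig.ga import EvalParams, GAParams

PANEL = [f"m{i}" for i in range(12)]


class TestMutate:
    def test_size_bounds_never_violated(self, rng):
        big = tuple(PANEL[:10])
        small = (PANEL[0],)
        for _ in range(200):
            assert len(im.mutate(big, PANEL, rng)) in (9, 10)
            assert len(im.mutate(small, PANEL, rng)) in (1, 2)

    def test_exactly_one_edit(self, rng):
        s = tuple(PANEL[:3])
        for _ in range(200):
            out = im.mutate(s, PANEL, rng)
            a, b = set(s), set(out)
            assert (len(a - b), len(b - a)) in {(0, 1), (1, 0), (1, 1)}

    def test_edit_type_frequencies_uniform_over_feasible(self, rng):
        s = tuple(PANEL[:3])
        counts = {"add": 0, "remove": 0, "substitute": 0}
        n = 30_000
        for _ in range(n):
            out = im.mutate(s, PANEL, rng)
            if len(out) == 4:
                counts["add"] += 1
            elif len(out) == 2:
                counts["remove"] += 1
            else:
                counts["substitute"] += 1
        # each feasible edit expected with probability 1/3 (3 SE band)
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 3) < 3 * se

    def test_saturated_panel_returns_subset_unchanged(self, rng):
        assert im.mutate(("a",), ["a"], rng) == ("a",)

    def test_empty_panel_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            im.mutate(("a",), [], rng)


class TestCrossover:
    def test_identical_parents_give_same_child(self, rng):
        a = tuple(PANEL[:4])
        assert set(im.crossover(a, a, rng)) == set(a)

    def test_child_within_union_and_keeps_intersection(self, rng):
        a, b = tuple(PANEL[:6]), tuple(PANEL[3:9])
        for _ in range(100):
            child = set(im.crossover(a, b, rng))
            assert child <= set(a) | set(b)
            assert set(a) & set(b) <= child

    def test_disjoint_max_parents_truncate_to_bound(self, rng):
        a = tuple(f"a{i}" for i in range(10))
        b = tuple(f"b{i}" for i in range(10))
        for _ in range(100):
            assert 1 <= len(im.crossover(a, b, rng)) <= 10

    def test_singleton_inclusion_probabilities_match_enumeration(self, rng):
        # a={m1}, b={m2}: child {m1,m2} w.p. 1/4, {m1} 1/4, {m2} 1/4,
        # empty -> fallback to one uniform parent feature (1/8 each);
        # so P(m1 in child) = P(m2 in child) = 5/8
        n = 30_000
        hits1 = hits2 = 0
        for _ in range(n):
            child = im.crossover(("m1",), ("m2",), rng)
            hits1 += "m1" in child
            hits2 += "m2" in child
        se = np.sqrt(0.625 * 0.375 / n)
        assert abs(hits1 / n - 0.625) < 4 * se
        assert abs(hits2 / n - 0.625) < 4 * se


def _separable_frame(rng, n=60, n_pos=20):
    """One perfectly separating marker m0 among noise."""
    X = pd.DataFrame(rng.normal(size=(n, 6)), columns=[f"m{i}" for i in range(6)])
    y = np.array([1] * n_pos + [0] * (n - n_pos))
    X.loc[y == 1, "m0"] += 10.0
    return X, y


class TestFitness:
    def test_perfect_marker_fitness_is_one_minus_penalty(self, rng):
        X, y = _separable_frame(rng)
        f = im.fitness(("m0",), X, y, GAParams(seed=1))
        assert f == pytest.approx(1.0 - 0.02, abs=1e-12)

    def test_pure_noise_marker_near_chance(self, rng):
        n = 400
        X = pd.DataFrame({"m0": rng.normal(size=n), "m1": rng.normal(size=n)})
        y = np.array([0, 1] * (n // 2))
        f = im.fitness(("m0",), X, y, GAParams(seed=2))
        assert f == pytest.approx(0.5 - 0.02, abs=0.07)

    def test_cv_variance_across_rng_states_is_small(self, default_cohort):
        y = (default_cohort.true_profile == 2).to_numpy()
        vals = [
            im.fitness(("scd163", "iga"), default_cohort.markers, y,
                       GAParams(), np.random.default_rng(s))
            for s in range(50)
        ]
        assert np.std(vals) < 0.05

    def test_penalty_monotone_in_size(self, rng):
        X, y = _separable_frame(rng)
        # m0 separates alone; adding noise cannot raise accuracy above 1
        f1 = im.fitness(("m0",), X, y, GAParams(seed=3))
        f3 = im.fitness(("m0", "m1", "m2"), X, y, GAParams(seed=3))
        assert f1 > f3

    def test_empty_subset_rejected(self, rng):
        X, y = _separable_frame(rng)
        with pytest.raises(ValueError):
            im.fitness((), X, y)


class TestSearch:
    @pytest.mark.parametrize("params", [
        GAParams(population_size=20, n_generations=10, n_restarts=2, seed=0),
        GAParams(population_size=30, n_generations=8, n_restarts=1,
                 mutation_rate=0.5, crossover_rate=0.5, elitism_count=4, seed=1),
        GAParams(population_size=16, n_generations=12, n_restarts=2,
                 tournament_size=3, seed=2),
    ])
    def test_core_properties_across_hyperparameter_grid(self, rng, params):
        """Elitism monotonicity, size bound, reproducibility hold for any
        reasonable hyperparameter choice."""
        X, y = _separable_frame(rng)
        res = im.ga_search(X, y, params)
        for hist in res.histories:
            assert (np.diff(hist) >= -1e-12).all()
        assert all(1 <= len(s) <= 10 for s in res.final_population)
        res2 = im.ga_search(X, y, params)
        assert res.final_population == res2.final_population
        assert res.final_fitness == res2.final_fitness

    def test_dominant_marker_always_found(self, rng):
        params = GAParams(population_size=20, n_generations=20, n_restarts=2)
        for seed in range(3):
            X, y = _separable_frame(np.random.default_rng(seed))
            res = im.ga_search(X, y, GAParams(**{**params.__dict__, "seed": seed}))
            assert "m0" in res.best_subset

    def test_invalid_params_rejected(self, rng):
        X, y = _separable_frame(rng)
        with pytest.raises(ValueError):
            im.ga_search(X, y, GAParams(population_size=1, elitism_count=2))


class TestEvaluateFinal:
    def test_perfect_subset_scores_perfectly(self, rng):
        X, y = _separable_frame(rng)
        ev = im.evaluate_final([("m0",)], X, y, EvalParams(seed=0))[0]
        assert ev.error_rate == 0.0
        assert ev.sensitivity == 1.0 and ev.specificity == 1.0
        assert ev.error_rate + ev.mean_accuracy == pytest.approx(1.0)
        assert len(ev.per_run_accuracies) == 30

    def test_majority_floor_flag(self, rng):
        n, n_pos = 150, 22
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        y = np.array([1] * n_pos + [0] * (n - n_pos))
        ev = im.evaluate_final([("a",)], X, y, EvalParams(seed=1))[0]
        assert ev.majority_accuracy == pytest.approx(128 / 150)
        assert not ev.beats_majority  # noise subset cannot beat the floor

    def test_ranking_tie_breaks_smaller_then_lexicographic(self, rng):
        X, y = _separable_frame(rng)
        # m0 alone and m0 plus pure noise reach identical (perfect) accuracy
        ranked = im.evaluate_final(
            [("m0", "m1"), ("m0",), ("m0", "m2")], X, y, EvalParams(seed=2)
        )
        assert ranked[0].subset == ("m0",)
        assert tuple(sorted(ranked[1].subset)) == ("m0", "m1")

    def test_duplicate_candidates_deduplicated(self, rng):
        X, y = _separable_frame(rng)
        ranked = im.evaluate_final([("m0", "m1"), ("m1", "m0")], X, y, EvalParams())
        assert len(ranked) == 1


class TestSelectorEstimator:
    def test_fit_transform_and_sklearn_contract(self, rng):
        X, y = _separable_frame(rng)
        sel = im.GASignatureSelector(
            population_size=16, n_generations=8, n_restarts=1, seed=0
        )
        out = sel.fit_transform(X, y)
        assert out.shape == (len(X), sel.support_.sum())
        assert "m0" in sel.best_subset_
        assert sel.get_params()["population_size"] == 16
        frame = sel.ranking_frame()
        assert {"rank", "markers", "mean_accuracy", "error_rate"} <= set(frame.columns)

    def test_clone_compatible(self):
        from sklearn.base import clone

        sel = im.GASignatureSelector(seed=7, population_size=10)
        cloned = clone(sel)
        assert cloned.get_params() == sel.get_params()
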