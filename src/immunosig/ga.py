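"""Genetic-algorithm biomarker signature selection.

Solutions are subsets of at most ``max_subset_size`` (default 10) marker
names. The population evolves by tournament selection with elitism,
cross-over (intersection kept, symmetric-difference features tossed in
independently with probability 1/2) and single-edit mutation (feature
addition, removal or substitution, uniform over the feasible edits). The
fitness of a subset is its repeated stratified 2-fold cross-validated LDA
accuracy penalized linearly by subset size:

    fitness(S) = mean CV accuracy(S) - penalty_lambda * |S|

The search is run ``n_restarts`` times (default 4) from independent seed
streams; every member of every final generation is then re-evaluated with
30 independent stratified 2-fold LDA cross-validations and ranked by mean
correct classification rate (ties: smaller subset first, then lexicographic
marker names).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .lda import PooledLDA

__all__ = [
    "GAParams",
    "EvalParams",
    "SignatureEvaluation",
    "GAResult",
    "mutate",
    "crossover",
    "fitness",
    "ga_search",
    "evaluate_final",
    "GASignatureSelector",
]

FeatureSubset = tuple[str, ...]


@dataclass(frozen=True)
class GAParams:
    population_size: int = 100
    n_generations: int = 50
    mutation_rate: float = 0.3
    crossover_rate: float = 0.7
    max_subset_size: int = 10
    penalty_lambda: float = 0.02
    fitness_cv_folds: int = 2
    fitness_cv_repeats: int = 5
    n_restarts: int = 4
    elitism_count: int = 2
    tournament_size: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.mutation_rate <= 1 or not 0 <= self.crossover_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.max_subset_size < 1:
            raise ValueError("max_subset_size must be >= 1")
        if self.penalty_lambda < 0:
            raise ValueError("penalty_lambda must be >= 0")
        if self.population_size < self.elitism_count:
            raise ValueError("population_size must be >= elitism_count")
        if self.population_size < 1 or self.n_generations < 0:
            raise ValueError("population_size >= 1 and n_generations >= 0 required")


@dataclass(frozen=True)
class EvalParams:
    n_eval_runs: int = 30
    eval_cv_folds: int = 2
    seed: int = 0


@dataclass(frozen=True)
class SignatureEvaluation:
    """Final 30 x 2-fold held-out performance of one subset.

    Sensitivity/specificity are pooled over every held-out prediction
    (positive class = the target profile); ``majority_accuracy`` is the
    always-predict-majority floor a useful subset must beat.
    """

    subset: FeatureSubset
    mean_accuracy: float
    error_rate: float
    sensitivity: float
    specificity: float
    per_run_accuracies: tuple[float, ...]
    majority_accuracy: float

    @property
    def size(self) -> int:
        return len(self.subset)

    @property
    def beats_majority(self) -> bool:
        return self.mean_accuracy > self.majority_accuracy


def _validate_subset(subset: Sequence[str], panel: Sequence[str], max_size: int) -> FeatureSubset:
    subset = tuple(subset)
    if not 1 <= len(subset) <= max_size:
        raise ValueError(f"subset size must be in [1, {max_size}]")
    if len(set(subset)) != len(subset):
        raise ValueError("duplicate features in subset")
    unknown = set(subset) - set(panel)
    if unknown:
        raise ValueError(f"features not in panel: {sorted(unknown)}")
    return subset


def mutate(
    subset: Sequence[str],
    panel: Sequence[str],
    rng: np.random.Generator,
    max_size: int = 10,
) -> FeatureSubset:
    """Apply exactly one edit, uniform over the feasible ones of
    {addition, removal, substitution}.

    Addition is infeasible at ``max_size`` (or with no unused marker),
    removal at size 1; if nothing is feasible the subset is returned
    unchanged.
    """
    panel = list(panel)
    if not panel:
        raise ValueError("empty marker panel")
    subset = _validate_subset(subset, panel, max_size)
    unused = [m for m in panel if m not in subset]
    feasible = []
    if len(subset) < max_size and unused:
        feasible.append("add")
    if len(subset) > 1:
        feasible.append("remove")
    if unused:
        feasible.append("substitute")
    if not feasible:
        return subset
    edit = feasible[rng.integers(len(feasible))]
    if edit == "add":
        return subset + (unused[rng.integers(len(unused))],)
    if edit == "remove":
        drop = rng.integers(len(subset))
        return tuple(f for i, f in enumerate(subset) if i != drop)
    pos = rng.integers(len(subset))
    new = unused[rng.integers(len(unused))]
    return tuple(new if i == pos else f for i, f in enumerate(subset))


def crossover(
    a: Sequence[str],
    b: Sequence[str],
    rng: np.random.Generator,
    max_size: int = 10,
) -> FeatureSubset:
    """Recombine two subsets: shared features are always kept, each feature
    unique to one parent is included independently with probability 1/2; an
    empty child falls back to one random parent feature, and an oversized
    child is truncated by random removal to ``max_size``."""
    a, b = tuple(a), tuple(b)
    shared = [f for f in a if f in b]
    symdiff = [f for f in a if f not in b] + [f for f in b if f not in a]
    child = list(shared) + [f for f in symdiff if rng.random() < 0.5]
    if not child:
        pool = list(dict.fromkeys(a + b))
        child = [pool[rng.integers(len(pool))]]
    if len(child) > max_size:
        keep = rng.choice(len(child), size=max_size, replace=False)
        child = [child[i] for i in sorted(keep)]
    return tuple(child)


# --------------------------------------------------------------------------
# Fitness
# --------------------------------------------------------------------------


def _make_splits(y: np.ndarray, folds: int, repeats: int, seeds: Sequence[int]):
    """Stratified fold index pairs for ``repeats`` independent splits."""
    out = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seeds[r]))
        out.extend((tr, te) for tr, te in skf.split(np.zeros(len(y)), y))
    return out


def _cv_accuracy(cols: np.ndarray, X: np.ndarray, y: np.ndarray, splits) -> float:
    accs = []
    Xs = X[:, cols]
    for tr, te in splits:
        model = PooledLDA().fit(Xs[tr], y[tr])
        accs.append(float(np.mean(model.predict(Xs[te]) == y[te])))
    return float(np.mean(accs))


def fitness(
    subset: Sequence[str],
    X: pd.DataFrame,
    y,
    params: GAParams | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Penalized CV accuracy of one subset: mean held-out LDA accuracy over
    ``fitness_cv_repeats`` x ``fitness_cv_folds`` stratified folds minus
    ``penalty_lambda * len(subset)``. Deterministic given the rng state
    (fold assignment is the only randomness)."""
    if params is None:
        params = GAParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    X = pd.DataFrame(X)
    panel = list(X.columns)
    subset = _validate_subset(subset, panel, params.max_subset_size)
    y = np.asarray(y)
    counts = np.bincount(np.unique(y, return_inverse=True)[1])
    if len(counts) != 2:
        raise ValueError("labels must define exactly two classes")
    if counts.min() < params.fitness_cv_folds:
        raise ValueError("minority class smaller than the number of folds")
    seeds = rng.integers(2**31, size=params.fitness_cv_repeats)
    splits = _make_splits(y, params.fitness_cv_folds, params.fitness_cv_repeats, seeds)
    cols = np.array([panel.index(f) for f in subset])
    acc = _cv_accuracy(cols, X.to_numpy(dtype=float), y, splits)
    return acc - params.penalty_lambda * len(subset)


@dataclass
class GAResult:
    """Union of final generations over all restarts, plus per-run traces."""

    final_population: list[FeatureSubset]
    final_fitness: list[float]
    histories: list[list[float]] = field(default_factory=list)  # best per generation

    @property
    def best_subset(self) -> FeatureSubset:
        return self.final_population[int(np.argmax(self.final_fitness))]


def _sort_key(subset: FeatureSubset, fit: float):
    return (-fit, len(subset), tuple(sorted(subset)))


def ga_search(X: pd.DataFrame, y, params: GAParams | None = None) -> GAResult:
    """Run the full multi-restart genetic search.

    Each restart draws its own rng stream and its own fixed set of
    stratified CV splits, making within-run fitness a pure (cacheable)
    function of the subset and the whole search bit-reproducible from
    ``params.seed``.
    """
    if params is None:
        params = GAParams()
    params.validate()
    X = pd.DataFrame(X)
    panel = list(X.columns)
    if len(panel) < 2:
        raise ValueError("marker panel must have at least 2 features")
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y)
    counts = np.bincount(np.unique(y, return_inverse=True)[1])
    if len(counts) != 2 or counts.min() < params.fitness_cv_folds:
        raise ValueError("need two classes, minority >= number of folds")
    max_size = min(params.max_subset_size, len(panel))
    col_of = {f: i for i, f in enumerate(panel)}

    final_pop: list[FeatureSubset] = []
    final_fit: list[float] = []
    histories: list[list[float]] = []
    seen: set[frozenset] = set()

    for run in range(params.n_restarts):
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, run]))
        seeds = rng.integers(2**31, size=params.fitness_cv_repeats)
        splits = _make_splits(y, params.fitness_cv_folds, params.fitness_cv_repeats, seeds)
        cache: dict[frozenset, float] = {}

        def fit_of(sub: FeatureSubset) -> float:
            key = frozenset(sub)
            if key not in cache:
                cols = np.fromiter((col_of[f] for f in sub), dtype=int)
                cache[key] = (
                    _cv_accuracy(cols, Xv, y, splits)
                    - params.penalty_lambda * len(sub)
                )
            return cache[key]

        def random_subset() -> FeatureSubset:
            size = int(rng.integers(1, max_size + 1))
            idx = rng.choice(len(panel), size=size, replace=False)
            return tuple(panel[i] for i in idx)

        pop = [random_subset() for _ in range(params.population_size)]
        history: list[float] = []
        for _gen in range(params.n_generations):
            fits = [fit_of(s) for s in pop]
            order = sorted(range(len(pop)), key=lambda i: _sort_key(pop[i], fits[i]))
            history.append(fits[order[0]])
            elites = [pop[i] for i in order[: params.elitism_count]]
            nxt = list(elites)

            def tournament() -> FeatureSubset:
                idx = rng.integers(len(pop), size=params.tournament_size)
                best = min(idx, key=lambda i: _sort_key(pop[i], fits[i]))
                return pop[best]

            # duplicate avoidance: a child identical (as a set) to a member
            # already in the next generation is re-mutated a few times, which
            # slows elite takeover and preserves candidate diversity
            used = {frozenset(s) for s in nxt}
            while len(nxt) < params.population_size:
                pa, pb = tournament(), tournament()
                child = (
                    crossover(pa, pb, rng, max_size)
                    if rng.random() < params.crossover_rate
                    else tuple(pa)
                )
                if rng.random() < params.mutation_rate:
                    child = mutate(child, panel, rng, max_size)
                for _ in range(10):
                    if frozenset(child) not in used:
                        break
                    child = mutate(child, panel, rng, max_size)
                used.add(frozenset(child))
                nxt.append(child)
            pop = nxt
        fits = [fit_of(s) for s in pop]
        history.append(max(fits) if fits else float("-inf"))
        histories.append(history)
        for s, f in zip(pop, fits):
            key = frozenset(s)
            if key not in seen:
                seen.add(key)
                final_pop.append(s)
                final_fit.append(f)

    return GAResult(final_population=final_pop, final_fitness=final_fit,
                    histories=histories)


# --------------------------------------------------------------------------
# Final evaluation
# --------------------------------------------------------------------------


def evaluate_final(
    subsets: Sequence[Sequence[str]],
    X: pd.DataFrame,
    y,
    eval_params: EvalParams | None = None,
) -> list[SignatureEvaluation]:
    """Re-evaluate candidate subsets with ``n_eval_runs`` (default 30)
    independent stratified ``eval_cv_folds``-fold LDA cross-validations;
    rank by mean held-out accuracy (ties: smaller subset, then lexicographic
    marker names). ``y`` truthiness defines the positive class."""
    if eval_params is None:
        eval_params = EvalParams()
    if not len(subsets):
        raise ValueError("need at least one candidate subset")
    X = pd.DataFrame(X)
    panel = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    y = np.asarray(y).astype(bool)
    majority = float(max(y.mean(), 1 - y.mean()))
    run_seeds = np.random.SeedSequence(eval_params.seed).generate_state(
        eval_params.n_eval_runs
    ) % (2**31)
    split_sets = [
        _make_splits(y, eval_params.eval_cv_folds, 1, [s]) for s in run_seeds
    ]

    results: list[SignatureEvaluation] = []
    done: set[frozenset] = set()
    for subset in subsets:
        subset = tuple(subset)
        key = frozenset(subset)
        if key in done:
            continue
        done.add(key)
        cols = np.array([panel.index(f) for f in subset])
        per_run = []
        tp = fp = tn = fn = 0
        for splits in split_sets:
            correct = 0
            for tr, te in splits:
                model = PooledLDA().fit(Xv[np.ix_(tr, cols)], y[tr])
                pred = model.predict(Xv[np.ix_(te, cols)]).astype(bool)
                truth = y[te]
                correct += int(np.sum(pred == truth))
                tp += int(np.sum(pred & truth))
                fn += int(np.sum(~pred & truth))
                fp += int(np.sum(pred & ~truth))
                tn += int(np.sum(~pred & ~truth))
            per_run.append(correct / len(y))
        mean_acc = float(np.mean(per_run))
        results.append(
            SignatureEvaluation(
                subset=subset,
                mean_accuracy=mean_acc,
                error_rate=1.0 - mean_acc,
                sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
                specificity=tn / (tn + fp) if tn + fp else float("nan"),
                per_run_accuracies=tuple(per_run),
                majority_accuracy=majority,
            )
        )
    results.sort(key=lambda r: (-r.mean_accuracy, r.size, tuple(sorted(r.subset))))
    return results


# --------------------------------------------------------------------------
# Estimator facade
# --------------------------------------------------------------------------


class GASignatureSelector(BaseEstimator):
    """sklearn-style feature selector wrapping the GA search + final ranking.

    ``fit(X, y)`` runs the multi-restart genetic search with penalized
    CV-LDA fitness, then the 30 x 2-fold final evaluation, and exposes:

    - ``ranking_``: list of :class:`SignatureEvaluation`, best first
    - ``best_subset_`` / ``best_evaluation_``
    - ``support_``: boolean mask over input features
    - ``histories_``: best fitness per generation for each restart

    ``transform(X)`` keeps only the selected markers.
    """

    def __init__(self, population_size: int = 100, n_generations: int = 50,
                 mutation_rate: float = 0.3, crossover_rate: float = 0.7,
                 max_subset_size: int = 10, penalty_lambda: float = 0.02,
                 fitness_cv_folds: int = 2, fitness_cv_repeats: int = 5,
                 n_restarts: int = 4, elitism_count: int = 2,
                 tournament_size: int = 2, n_eval_runs: int = 30,
                 eval_cv_folds: int = 2, seed: int = 0):
        self.population_size = population_size
        self.n_generations = n_generations
        self.mutation_rate = mutation_rate
        self.crossover_rate = crossover_rate
        self.max_subset_size = max_subset_size
        self.penalty_lambda = penalty_lambda
        self.fitness_cv_folds = fitness_cv_folds
        self.fitness_cv_repeats = fitness_cv_repeats
        self.n_restarts = n_restarts
        self.elitism_count = elitism_count
        self.tournament_size = tournament_size
        self.n_eval_runs = n_eval_runs
        self.eval_cv_folds = eval_cv_folds
        self.seed = seed

    def _ga_params(self) -> GAParams:
        return GAParams(
            population_size=self.population_size,
            n_generations=self.n_generations,
            mutation_rate=self.mutation_rate,
            crossover_rate=self.crossover_rate,
            max_subset_size=self.max_subset_size,
            penalty_lambda=self.penalty_lambda,
            fitness_cv_folds=self.fitness_cv_folds,
            fitness_cv_repeats=self.fitness_cv_repeats,
            n_restarts=self.n_restarts,
            elitism_count=self.elitism_count,
            tournament_size=self.tournament_size,
            seed=self.seed,
        )

    def fit(self, X, y):
        X = pd.DataFrame(X)
        if not isinstance(X.columns[0], str):
            X.columns = [f"m{i}" for i in range(X.shape[1])]
        search = ga_search(X, y, self._ga_params())
        ranking = evaluate_final(
            search.final_population, X, y,
            EvalParams(self.n_eval_runs, self.eval_cv_folds, self.seed),
        )
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        self.search_result_ = search
        self.histories_ = search.histories
        self.ranking_ = ranking
        self.best_evaluation_ = ranking[0]
        self.best_subset_ = ranking[0].subset
        self.support_ = np.isin(self.feature_names_in_, list(self.best_subset_))
        return self

    def get_support(self):
        check_is_fitted(self, "support_")
        return self.support_

    def transform(self, X):
        check_is_fitted(self, "support_")
        X = pd.DataFrame(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return X.to_numpy()[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def ranking_frame(self) -> pd.DataFrame:
        """Ranked solutions as a tidy table."""
        check_is_fitted(self, "ranking_")
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranking_) + 1),
                "markers": ["+".join(r.subset) for r in self.ranking_],
                "size": [r.size for r in self.ranking_],
                "mean_accuracy": [r.mean_accuracy for r in self.ranking_],
                "error_rate": [r.error_rate for r in self.ranking_],
                "sensitivity": [r.sensitivity for r in self.ranking_],
                "specificity": [r.specificity for r in self.ranking_],
            }
        )
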