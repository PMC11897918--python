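"""Genetic-algorithm wavelength selection and the PCA reduction baseline.

A candidate solution (chromosome) is a binary inclusion mask over the
wavelength grid.  Fitness is the validation R^2 of a small extreme learning
machine trained on the masked wavelengths, evaluated on a fixed internal
80/20 split; the evolutionary operators are roulette-wheel selection,
single-point crossover and independent bitwise mutation (probability 0.05),
with one elite carried over per generation.

Two selection procedures are provided on top of the single GA run:

* **Iterative selection** — round 1 searches all wavelengths; each later
  round restricts candidates to the previous round's selected set, with a
  parsimony penalty on the selected fraction so the count actually shrinks.
  Selected sets are nested across rounds by construction.
* **Voting selection** — independent GA runs accumulate until 50 of them
  reach best fitness above 0.7; the wavelengths selected most frequently
  across those qualifying runs win, with ties at rank k broken toward the
  lower wavelength index.  The number kept defaults to the count found by
  iterative selection.

Fitness is deterministic per chromosome (the ELM seed is derived from the
run seed and the mask bits), so identical masks always score identically —
which makes single runs memoizable and exactly comparable with an
exhaustive search over all masks on small grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.feature_selection import SelectorMixin

from ._rng import substream
from .models import ELMRegressor, UndefinedMetricError, r_squared

__all__ = [
    "FitnessSpec",
    "GAConfig",
    "SelectionResult",
    "VotingTally",
    "InsufficientSignalError",
    "FitnessEvaluator",
    "fitness",
    "roulette_select",
    "single_point_crossover",
    "mutate",
    "run_ga",
    "iterative_select",
    "voting_select",
    "top_k_by_votes",
    "pca_reduce",
    "GAWavelengthSelector",
    "IterativeGASelector",
    "VotingGASelector",
    "PCAReducer",
]

_EPS = 1e-6  # roulette shift for nonpositive fitness


@dataclass(frozen=True)
class FitnessSpec:
    """The wrapper criterion: a small ELM scored on internal validation data.

    With ``n_splits`` = 1 the score is the validation R^2 on a single
    ``val_fraction`` hold-out; with ``n_splits`` > 1 it is the mean R^2 over
    that many cross-validation folds, which smooths the fitness landscape so
    independent runs agree on genuinely informative wavelengths.
    """

    n_hidden: int = 20
    val_fraction: float = 0.2
    activation: str = "logistic"
    n_splits: int = 4

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    The mutation probability of 0.05, roulette selection and single-point
    crossover are the study's stated operators; population size, generation
    count, crossover probability and elitism are package defaults.
    """

    population_size: int = 40
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.05
    elitism: int = 1
    init_prob: float = 0.5
    parsimony: float = 0.0
    fitness: FitnessSpec = field(default_factory=FitnessSpec)
    seed: int = 0

    def __post_init__(self):
        for p in (self.crossover_prob, self.mutation_prob, self.init_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size < 1 or self.generations < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.elitism <= self.population_size:
            raise ValueError("elitism must lie in [0, population_size]")


@dataclass
class SelectionResult:
    """Outcome of one GA run, in the coordinates of the full grid."""

    selected_indices: np.ndarray
    best_fitness: float  # raw validation R^2 of the winning mask
    best_objective: float  # fitness minus parsimony penalty
    fitness_trace: np.ndarray  # per-generation best objective
    run_id: tuple
    mask: np.ndarray
    n_evaluations: int
    run_seed: int


@dataclass
class VotingTally:
    """Per-wavelength selection counts across qualifying GA runs."""

    counts: np.ndarray
    n_qualifying: int
    n_runs_total: int

    def __post_init__(self):
        if (self.counts < 0).any() or (self.counts > self.n_qualifying).any():
            raise ValueError("counts must lie in [0, n_qualifying]")


class InsufficientSignalError(RuntimeError):
    """Voting could not accumulate enough qualifying runs; carries the tally."""

    def __init__(self, message: str, tally: VotingTally):
        super().__init__(message)
        self.tally = tally


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """An all-zero mask selects nothing; set one random bit."""
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


class FitnessEvaluator:
    """Validation-R^2 fitness with per-mask determinism and memoization.

    The train/validation split is fixed once per run; the ELM's random hidden
    layer is seeded from the run seed plus the mask bytes, so a mask's score
    never depends on evaluation order.
    """

    def __init__(self, X, y, spec: FitnessSpec = FitnessSpec(), seed: int = 0):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y disagree in sample count")
        n = self.X.shape[0]
        if n < 4:
            raise ValueError("fitness split needs at least 4 samples")
        self.spec = spec
        self.seed = int(seed)
        perm = substream(self.seed, "fitness-split").permutation(n)
        if spec.n_splits == 1:
            n_val = min(max(2, round(n * spec.val_fraction)), n - 2)
            self._folds = [(perm[n_val:], perm[:n_val])]
        else:
            if n < 2 * spec.n_splits:
                raise ValueError("too few samples for the requested CV folds")
            parts = np.array_split(perm, spec.n_splits)
            self._folds = [
                (np.concatenate(parts[:i] + parts[i + 1:]), parts[i])
                for i in range(spec.n_splits)
            ]
        self._cache: dict[bytes, float] = {}

    @property
    def n_evaluations(self) -> int:
        return len(self._cache)

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.X.shape[1]:
            raise ValueError("mask length does not match feature count")
        if not mask.any():
            warnings.warn("all-zero chromosome repaired to one random bit")
            mask = _repair(mask, substream(self.seed, "zero-repair"))
        key = np.packbits(mask).tobytes()
        if key not in self._cache:
            cols = np.flatnonzero(mask)
            scores = []
            for fold, (train_idx, val_idx) in enumerate(self._folds):
                rng = substream(self.seed, "fitness-elm", fold, key)
                model = ELMRegressor(
                    n_hidden=self.spec.n_hidden,
                    activation=self.spec.activation,
                    random_state=rng,
                ).fit(self.X[np.ix_(train_idx, cols)], self.y[train_idx])
                pred = model.predict(self.X[np.ix_(val_idx, cols)])
                try:
                    scores.append(r_squared(self.y[val_idx], pred))
                except UndefinedMetricError:
                    scores.append(-np.inf)
            self._cache[key] = float(np.mean(scores))
        return self._cache[key]


def fitness(mask, X, y, spec: FitnessSpec = FitnessSpec(), seed: int = 0) -> float:
    """Validation R^2 of the masked-wavelength ELM (one-shot convenience form)."""
    return FitnessEvaluator(X, y, spec, seed)(np.asarray(mask, dtype=bool))


def roulette_select(population: np.ndarray, fitnesses: np.ndarray,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two independent draws with probability proportional to fitness.

    Fitness is used raw when all values are positive; when zero or negative
    values are present the whole vector is shifted by ``min + 1e-6`` so that
    ordering is preserved and probabilities stay valid.
    """
    fitnesses = np.asarray(fitnesses, dtype=float)
    if not np.isfinite(fitnesses).all():
        raise ValueError("roulette selection requires finite fitness values")
    f = fitnesses.copy()
    if f.min() <= 0:
        f = f - f.min() + _EPS
    prob = f / f.sum()
    i, j = rng.choice(population.shape[0], size=2, p=prob)
    return population[i].copy(), population[j].copy()


def single_point_crossover(a: np.ndarray, b: np.ndarray,
                           rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Swap suffixes after a uniform cut point in [1, L-1]."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("parents differ in length")
    L = a.size
    if L < 2:
        return a.copy(), b.copy()
    cut = int(rng.integers(1, L))
    child1 = np.concatenate([a[:cut], b[cut:]])
    child2 = np.concatenate([b[:cut], a[cut:]])
    return child1, child2


def mutate(mask: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``p``; repair all-zero."""
    if not 0 <= p <= 1:
        raise ValueError("mutation probability must lie in [0, 1]")
    mask = np.asarray(mask, dtype=bool)
    flips = rng.random(mask.size) < p
    return _repair(mask ^ flips, rng)


def _derive_run_seed(seed: int, run_id: tuple) -> int:
    return int(substream(seed, "run", *run_id).integers(0, 2**31 - 1))


def make_evaluator(X, y, config: GAConfig) -> FitnessEvaluator:
    """The config's fitness function: one fixed fold assignment per dataset.

    The evaluator depends on the master seed but not on the run id, so every
    run under one config optimizes the same deterministic objective — run-to-
    run variation comes only from the GA's own randomness (initial
    population, crossover, mutation), which is what voting aggregates over.
    """
    fit_seed = int(substream(config.seed, "fitness").integers(0, 2**31 - 1))
    return FitnessEvaluator(X, y, config.fitness, seed=fit_seed)


def run_ga(X, y, config: GAConfig = GAConfig(), run_id: tuple = (0,),
           evaluator: FitnessEvaluator | None = None) -> SelectionResult:
    """One generational GA run with elitism; seeded-deterministic.

    ``run_id`` names the run within the config's master seed so repeated and
    voting runs draw independent operator substreams while sharing one
    fitness objective.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    L = X.shape[1]
    run_seed = _derive_run_seed(config.seed, tuple(run_id))
    if evaluator is None:
        evaluator = make_evaluator(X, y, config)

    def objective(mask: np.ndarray) -> float:
        score = evaluator(mask) - config.parsimony * mask.mean()
        if not np.isfinite(score):
            raise FloatingPointError(
                f"non-finite fitness in run {run_id} for mask with "
                f"{int(mask.sum())} bits"
            )
        return score

    rng_init = substream(run_seed, "population-init")
    rng_rou = substream(run_seed, "roulette")
    rng_xo = substream(run_seed, "crossover")
    rng_mut = substream(run_seed, "mutation")

    pop = [
        _repair((rng_init.random(L) < config.init_prob), rng_init)
        for _ in range(config.population_size)
    ]
    scores = np.array([objective(m) for m in pop])
    trace = [scores.max()]
    best = int(np.argmax(scores))
    best_mask, best_score = pop[best].copy(), float(scores[best])

    for _ in range(config.generations):
        order = np.argsort(-scores, kind="stable")
        pop_arr = np.array(pop)
        children = [pop[i].copy() for i in order[: config.elitism]]
        while len(children) < config.population_size:
            pa, pb = roulette_select(pop_arr, scores, rng_rou)
            if rng_xo.random() < config.crossover_prob:
                pa, pb = single_point_crossover(pa, pb, rng_xo)
            for child in (pa, pb):
                if len(children) < config.population_size:
                    children.append(mutate(child, config.mutation_prob, rng_mut))
        pop = children
        scores = np.array([objective(m) for m in pop])
        trace.append(scores.max())
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            best_mask, best_score = pop[gen_best].copy(), float(scores[gen_best])
    return SelectionResult(
        selected_indices=np.flatnonzero(best_mask),
        best_fitness=evaluator(best_mask),
        best_objective=best_score,
        fitness_trace=np.array(trace),
        run_id=tuple(run_id),
        mask=best_mask.copy(),
        n_evaluations=evaluator.n_evaluations,
        run_seed=run_seed,
    )


def iterative_select(X, y, config: GAConfig = GAConfig(), n_rounds: int = 3,
                     parsimony: float = 0.05) -> list[SelectionResult]:
    """Nested GA rounds: each round searches within the previous selection.

    A parsimony penalty of ``parsimony`` times the selected fraction is added
    to every round's objective so the wavelength count shrinks.  Results are
    reported in full-grid coordinates; ``S_{r+1} ⊆ S_r`` by construction.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    X = np.asarray(X, dtype=float)
    candidates = np.arange(X.shape[1])
    cfg = replace(config, parsimony=parsimony)
    results: list[SelectionResult] = []
    for r in range(n_rounds):
        res = run_ga(X[:, candidates], y, cfg, run_id=("iterative", r))
        global_idx = candidates[res.selected_indices]
        global_mask = np.zeros(X.shape[1], dtype=bool)
        global_mask[global_idx] = True
        res.selected_indices = global_idx
        res.mask = global_mask
        results.append(res)
        candidates = global_idx
        if candidates.size < 2:
            warnings.warn(
                f"iterative selection stopped after round {r + 1}: fewer than "
                "2 wavelengths remain"
            )
            break
    return results


def voting_select(X, y, config: GAConfig = GAConfig(), n_qualifying: int = 50,
                  r2_threshold: float = 0.7, k: int | None = None,
                  max_runs: int | None = None,
                  ) -> tuple[np.ndarray, VotingTally]:
    """Aggregate independent GA runs and keep the most-voted wavelengths.

    Runs accumulate until ``n_qualifying`` of them reach best validation R^2
    above ``r2_threshold`` (runs below the bar are discarded); the tally then
    ranks wavelengths by how many qualifying runs selected them, ties at rank
    ``k`` broken toward the lower wavelength index.  ``k`` defaults to the
    count found by iterative selection on the same data.

    Raises :class:`InsufficientSignalError` (carrying the partial tally) if
    ``max_runs`` (default ``4 * n_qualifying``) runs are exhausted first.
    """
    if k is not None and k < 1:
        raise ValueError("k must be >= 1")
    X = np.asarray(X, dtype=float)
    L = X.shape[1]
    if max_runs is None:
        max_runs = 4 * n_qualifying
    counts = np.zeros(L, dtype=int)
    qualifying = 0
    total = 0
    evaluator = make_evaluator(X, y, config)  # one objective, shared cache
    while qualifying < n_qualifying and total < max_runs:
        res = run_ga(X, y, config, run_id=("vote", total), evaluator=evaluator)
        total += 1
        if res.best_fitness > r2_threshold:
            counts[res.mask] += 1
            qualifying += 1
    tally = VotingTally(counts=counts, n_qualifying=qualifying, n_runs_total=total)
    if qualifying < n_qualifying:
        raise InsufficientSignalError(
            f"only {qualifying}/{n_qualifying} runs exceeded R^2 "
            f"{r2_threshold} within {max_runs} runs",
            tally,
        )
    if k is None:
        k = len(iterative_select(X, y, config)[-1].selected_indices)
    return top_k_by_votes(counts, k), tally


def top_k_by_votes(counts: np.ndarray, k: int) -> np.ndarray:
    """The ``k`` most-voted wavelength indices, ties broken toward lower index.

    Depends only on the tally, so the result is invariant to the order in
    which the qualifying runs were accumulated.
    """
    counts = np.asarray(counts)
    order = np.lexsort((np.arange(counts.size), -counts))
    return np.sort(order[: int(k)])


def pca_reduce(X, n_components: int = 5):
    """Column-centered PCA with a fixed sign convention.

    Returns ``(scores, loadings, explained_variance)`` with components
    ordered by decreasing explained variance and each component's
    largest-magnitude loading made positive.  If the data's rank falls short
    of ``n_components`` the result is truncated with a warning.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    n, p = X.shape
    limit = min(n - 1, p)
    k = n_components
    if k > limit:
        warnings.warn(f"n_components reduced from {k} to {limit} (data size)")
        k = limit
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    rank = int(np.sum(pca.explained_variance_ > max(
        pca.explained_variance_[0], 1.0) * 1e-12))
    if rank < k:
        warnings.warn(f"data rank {rank} below requested {k} components; truncating")
        scores = scores[:, :rank]
        k = rank
    loadings = pca.components_[:k].copy()
    explained = pca.explained_variance_[:k].copy()
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i_max] < 0:
            loadings[j] *= -1
            scores[:, j] *= -1
    return scores, loadings, explained


# --------------------------------------------------------------------------
# scikit-learn estimator surface
# --------------------------------------------------------------------------


class _GABase(SelectorMixin, BaseEstimator):
    """Shared parameter plumbing for the GA selector estimators."""

    def __init__(self, population_size=40, generations=50, crossover_prob=0.8,
                 mutation_prob=0.05, elitism=1, init_prob=0.5,
                 fitness_n_hidden=20, fitness_val_fraction=0.2, random_state=0):
        self.population_size = population_size
        self.generations = generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.elitism = elitism
        self.init_prob = init_prob
        self.fitness_n_hidden = fitness_n_hidden
        self.fitness_val_fraction = fitness_val_fraction
        self.random_state = random_state

    def _config(self, parsimony: float = 0.0) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            elitism=self.elitism,
            init_prob=self.init_prob,
            parsimony=parsimony,
            fitness=FitnessSpec(
                n_hidden=self.fitness_n_hidden,
                val_fraction=self.fitness_val_fraction,
            ),
            seed=0 if self.random_state is None else int(self.random_state),
        )

    def _get_support_mask(self):
        return self.support_


class GAWavelengthSelector(_GABase):
    """Single-run GA wavelength selector (sklearn transformer)."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.result_ = run_ga(X, y, self._config())
        self.support_ = self.result_.mask
        self.n_features_in_ = X.shape[1]
        return self


class IterativeGASelector(_GABase):
    """Iterative (nested-rounds) GA selector with a parsimony penalty."""

    def __init__(self, n_rounds=3, parsimony=0.05, **kwargs):
        super().__init__(**kwargs)
        self.n_rounds = n_rounds
        self.parsimony = parsimony

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.results_ = iterative_select(
            X, y, self._config(), n_rounds=self.n_rounds, parsimony=self.parsimony
        )
        self.support_ = self.results_[-1].mask
        self.n_features_in_ = X.shape[1]
        return self


class VotingGASelector(_GABase):
    """Voting GA selector: most-frequent wavelengths across qualifying runs.

    The constituent runs start sparse (``init_prob`` 0.1) and carry a
    parsimony pressure (``parsimony`` 0.2, i.e. 0.2/L per selected band), so
    each run commits to a small wavelength subset and the cross-run vote
    frequencies discriminate informative bands; qualification (best R^2 above
    the threshold) always uses the raw, unpenalized validation score.
    """

    def __init__(self, n_qualifying=50, r2_threshold=0.7, k=None, max_runs=None,
                 parsimony=0.2, init_prob=0.1, **kwargs):
        super().__init__(init_prob=init_prob, **kwargs)
        self.n_qualifying = n_qualifying
        self.r2_threshold = r2_threshold
        self.k = k
        self.max_runs = max_runs
        self.parsimony = parsimony

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        selected, tally = voting_select(
            X, y, self._config(self.parsimony), n_qualifying=self.n_qualifying,
            r2_threshold=self.r2_threshold, k=self.k, max_runs=self.max_runs,
        )
        self.selected_indices_ = selected
        self.tally_ = tally
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[selected] = True
        self.n_features_in_ = X.shape[1]
        return self


class PCAReducer(TransformerMixin, BaseEstimator):
    """First-``n_components`` PCA scores as the reduced spectral variables."""

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        _, self.components_, self.explained_variance_ = pca_reduce(
            X, self.n_components
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T
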