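"""Wrapper feature selection over the deep-feature block.

Two metaheuristics search the space of feature bitmasks, scoring each
candidate by stratified cross-validated accuracy of a small classifier
restricted to the masked columns:

* **Genetic search** — tournament selection (size 2), single-point
  crossover (p = 0.6), per-bit flip mutation (p = 0.033), elitism of one,
  population 20 evolved for 20 generations, linear-SVM fitness.
* **Geometric PSO** — a velocity-free, discrete swarm: each particle's next
  position copies every bit from its current position, personal best, or
  global best with probabilities (0.33, 0.34, 0.33), followed by per-bit
  mutation (default 1/n_features); logistic-regression fitness.

The final subset is the union of the two searches' masks, so a feature kept
by either algorithm survives. An empty mask scores fitness 0 (a penalty,
not an error); fitness ties break toward the smaller subset.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .config import GeneticConfig, PsoConfig
from .types import FeatureSubset, ParameterError


def _make_classifier(name: str, seed: int):
    if name == "svm":
        return SVC(kernel="linear", C=0.1, random_state=seed)
    if name == "logistic":
        return LogisticRegression(max_iter=500, random_state=seed)
    raise ParameterError(f"unknown fitness classifier '{name}'")


class FitnessEvaluator:
    """Memoized wrapper fitness: mean stratified k-fold CV accuracy."""

    def __init__(self, X: np.ndarray, y: np.ndarray, classifier: str = "svm",
                 cv_folds: int = 5, seed: int = 0, groups: np.ndarray | None = None):
        if cv_folds < 2:
            raise ParameterError("cv_folds must be >= 2")
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.groups = None if groups is None else np.asarray(groups)
        if self.groups is None:
            _, counts = np.unique(self.y, return_counts=True)
            if counts.min() < cv_folds:
                raise ParameterError(
                    f"smallest class has {counts.min()} samples; cannot stratify {cv_folds} folds"
                )
        self.classifier = classifier
        self.cv_folds = cv_folds
        self.seed = seed
        self.n_evaluations = 0
        self._cache: dict[bytes, float] = {}

    @property
    def config_hash(self) -> str:
        return f"{self.classifier}/cv{self.cv_folds}/seed{self.seed}"

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.X.shape[1]:
            raise ParameterError("mask length must match feature count")
        if not mask.any():
            return 0.0
        key = np.packbits(mask).tobytes()
        if key in self._cache:
            return self._cache[key]
        clf = _make_classifier(self.classifier, self.seed)
        if self.groups is None:
            cv = StratifiedKFold(n_splits=self.cv_folds, shuffle=True, random_state=self.seed)
            scores = cross_val_score(clf, self.X[:, mask], self.y, cv=cv, scoring="accuracy")
        else:
            cv = StratifiedGroupKFold(n_splits=self.cv_folds, shuffle=True, random_state=self.seed)
            scores = cross_val_score(clf, self.X[:, mask], self.y, cv=cv,
                                     groups=self.groups, scoring="accuracy")
        fitness = float(scores.mean())
        self._cache[key] = fitness
        self.n_evaluations += 1
        return fitness


def evaluate_subset_fitness(
    mask: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    classifier: str = "svm",
    cv_folds: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> float:
    """One-shot wrapper fitness for a single mask (empty mask -> 0)."""
    return FitnessEvaluator(X, y, classifier, cv_folds, seed, groups)(mask)


def _better(fit_a: float, size_a: int, fit_b: float, size_b: int) -> bool:
    """True when (fit_a, size_a) beats (fit_b, size_b): higher fitness, then smaller."""
    if fit_a != fit_b:
        return fit_a > fit_b
    return size_a < size_b


def _random_mask(rng: np.random.Generator, n: int) -> np.ndarray:
    mask = rng.random(n) < 0.5
    if not mask.any():
        mask[rng.integers(n)] = True
    return mask


def genetic_search(
    X: np.ndarray,
    y: np.ndarray,
    config: GeneticConfig | None = None,
    classifier: str = "svm",
    cv_folds: int = 5,
    groups: np.ndarray | None = None,
    run_log: list | None = None,
) -> FeatureSubset:
    """Evolve feature bitmasks; returns the best-ever subset.

    ``groups`` (e.g. participant ids) makes the wrapper CV group-aware so
    fitness estimates generalization across participants, matching the
    grouped final evaluation.
    """
    config = config or GeneticConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if n < 1:
        raise ParameterError("need at least one feature")
    rng = np.random.default_rng(config.seed)
    fitness = FitnessEvaluator(X, y, classifier, cv_folds, config.seed, groups)

    pop = [_random_mask(rng, n) for _ in range(config.population)]
    fits = [fitness(m) for m in pop]
    best_mask, best_fit = None, -1.0
    for m, f in zip(pop, fits):
        if best_mask is None or _better(f, int(m.sum()), best_fit, int(best_mask.sum())):
            best_mask, best_fit = m.copy(), f

    for gen in range(config.generations):
        order = np.argsort(fits)[::-1]
        new_pop = [pop[order[i]].copy() for i in range(config.elitism)]
        while len(new_pop) < config.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, config.population, config.tournament_size)
                winner = max(contenders, key=lambda i: (fits[i], -int(pop[i].sum())))
                parents.append(pop[winner].copy())
            if n > 1 and rng.random() < config.crossover_prob:
                point = int(rng.integers(1, n))
                c1 = np.concatenate([parents[0][:point], parents[1][point:]])
                c2 = np.concatenate([parents[1][:point], parents[0][point:]])
            else:
                c1, c2 = parents
            for child in (c1, c2):
                flip = rng.random(n) < config.mutation_prob
                child ^= flip
                new_pop.append(child)
                if len(new_pop) >= config.population:
                    break
        pop = new_pop
        fits = [fitness(m) for m in pop]
        for m, f in zip(pop, fits):
            if _better(f, int(m.sum()), best_fit, int(best_mask.sum())):
                best_mask, best_fit = m.copy(), f
        if run_log is not None:
            run_log.append(
                {"stage": "genetic", "generation": gen + 1,
                 "best_fitness": best_fit, "mean_fitness": float(np.mean(fits)),
                 "evaluations": fitness.n_evaluations}
            )

    return FeatureSubset(best_mask, best_fit, "genetic", fitness.config_hash)


def pso_search(
    X: np.ndarray,
    y: np.ndarray,
    config: PsoConfig | None = None,
    cv_folds: int = 5,
    groups: np.ndarray | None = None,
    run_log: list | None = None,
) -> FeatureSubset:
    """Geometric, velocity-free binary PSO; returns the global-best subset."""
    config = config or PsoConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if n < 1:
        raise ParameterError("need at least one feature")
    rng = np.random.default_rng(config.seed)
    fitness = FitnessEvaluator(X, y, config.fitness_classifier, cv_folds, config.seed, groups)
    p_mut = config.mutation_prob if config.mutation_prob is not None else 1.0 / n

    positions = [_random_mask(rng, n) for _ in range(config.population)]
    fits = [fitness(m) for m in positions]
    pbest = [m.copy() for m in positions]
    pbest_fit = list(fits)
    g_idx = max(range(len(fits)), key=lambda i: (fits[i], -int(positions[i].sum())))
    gbest, gbest_fit = positions[g_idx].copy(), fits[g_idx]

    for it in range(config.iterations):
        for i in range(config.population):
            r = rng.random(n)
            new = np.where(
                r < config.inertia_weight,
                positions[i],
                np.where(r < config.inertia_weight + config.individual_weight, pbest[i], gbest),
            )
            if p_mut > 0:
                new = new ^ (rng.random(n) < p_mut)
            positions[i] = new
            f = fitness(new)
            fits[i] = f
            if _better(f, int(new.sum()), pbest_fit[i], int(pbest[i].sum())):
                pbest[i], pbest_fit[i] = new.copy(), f
            if _better(f, int(new.sum()), gbest_fit, int(gbest.sum())):
                gbest, gbest_fit = new.copy(), f
        if run_log is not None:
            run_log.append(
                {"stage": "pso", "iteration": it + 1,
                 "best_fitness": gbest_fit, "mean_fitness": float(np.mean(fits)),
                 "evaluations": fitness.n_evaluations}
            )

    if not gbest.any():  # only possible when every evaluated mask was empty
        gbest[int(rng.integers(n))] = True
    return FeatureSubset(gbest, gbest_fit, "pso", fitness.config_hash)


def subset_union(a: FeatureSubset, b: FeatureSubset) -> FeatureSubset:
    """Bitwise OR of two subsets over the same feature index space."""
    if a.mask.size != b.mask.size:
        raise ParameterError(
            f"mask dimension mismatch: {a.mask.size} vs {b.mask.size}"
        )
    return FeatureSubset(a.mask | b.mask, float("nan"), "union",
                         a.eval_config or b.eval_config)


def exhaustive_search(
    X: np.ndarray,
    y: np.ndarray,
    classifier: str = "svm",
    cv_folds: int = 5,
    seed: int = 0,
) -> FeatureSubset:
    """Enumerate every non-empty subset (tractable for <= ~15 features)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if n > 20:
        raise ParameterError("exhaustive search is limited to 20 features")
    fitness = FitnessEvaluator(X, y, classifier, cv_folds, seed)
    best_mask, best_fit = None, -1.0
    for code in range(1, 2**n):
        mask = np.array([(code >> i) & 1 for i in range(n)], dtype=bool)
        f = fitness(mask)
        if best_mask is None or _better(f, int(mask.sum()), best_fit, int(best_mask.sum())):
            best_mask, best_fit = mask, f
    return FeatureSubset(best_mask, best_fit, "exhaustive", fitness.config_hash)
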