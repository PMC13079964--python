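"""Wrapper feature selection: fitness contract, both metaheuristics, union."""

import numpy as np
import pytest

from actisleep import selection as sel
from actisleep.config import GeneticConfig, PsoConfig
from actisleep.types import ConfigError, FeatureSubset, ParameterError


def planted(n=200, n_features=10, n_informative=3, shift=1.2, seed=0):
    """Balanced 2-class design: informative columns are mean-shifted by class."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    X = rng.normal(size=(n, n_features))
    X[:, :n_informative] += shift * y[:, None]
    return X, y


def test_label_leak_column_reaches_perfect_fitness():
    rng = np.random.default_rng(0)
    y = np.arange(60) % 2
    X = np.column_stack([y.astype(float), rng.normal(size=60)])
    mask = np.array([True, False])
    assert sel.evaluate_subset_fitness(mask, X, y, cv_folds=5, seed=0) == 1.0


def test_empty_mask_is_penalized_not_raised():
    X, y = planted()
    assert sel.evaluate_subset_fitness(np.zeros(10, dtype=bool), X, y) == 0.0


def test_fitness_is_memoized_and_deterministic():
    X, y = planted()
    ev = sel.FitnessEvaluator(X, y, cv_folds=5, seed=1)
    m = np.zeros(10, dtype=bool)
    m[:3] = True
    f1 = ev(m)
    f2 = ev(m)
    assert f1 == f2
    assert ev.n_evaluations == 1
    assert f1 == sel.FitnessEvaluator(X, y, cv_folds=5, seed=1)(m)


def test_genetic_search_deterministic_and_monotone_log():
    X, y = planted(seed=3)
    log: list = []
    cfg = GeneticConfig(population=10, generations=6, seed=5)
    s1 = sel.genetic_search(X, y, cfg, run_log=log)
    s2 = sel.genetic_search(X, y, GeneticConfig(population=10, generations=6, seed=5))
    assert np.array_equal(s1.mask, s2.mask)
    best = [entry["best_fitness"] for entry in log]
    assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))
    assert s1.provenance == "genetic" and s1.mask.any()


def test_genetic_degenerate_population_one_no_generations():
    X, y = planted(seed=4)
    cfg = GeneticConfig(population=1, generations=0, seed=2)
    out = sel.genetic_search(X, y, cfg)
    assert isinstance(out, FeatureSubset) and out.mask.any()
    assert 0.0 <= out.fitness <= 1.0


def test_pso_deterministic_and_frozen_swarm():
    X, y = planted(seed=6)
    cfg = PsoConfig(population=8, iterations=5, seed=9)
    s1 = sel.pso_search(X, y, cfg)
    s2 = sel.pso_search(X, y, PsoConfig(population=8, iterations=5, seed=9))
    assert np.array_equal(s1.mask, s2.mask)

    frozen = PsoConfig(inertia_weight=1.0, individual_weight=0.0, social_weight=0.0,
                       mutation_prob=0.0, population=8, iterations=5, seed=9)
    # with pure inertia and no mutation the swarm never moves:
    # the result equals the best initial particle
    init = sel.pso_search(X, y, PsoConfig(inertia_weight=1.0, individual_weight=0.0,
                                          social_weight=0.0, mutation_prob=0.0,
                                          population=8, iterations=0, seed=9))
    out = sel.pso_search(X, y, frozen)
    assert np.array_equal(out.mask, init.mask)


def test_pso_rejects_bad_weights():
    with pytest.raises(ConfigError):
        sel.pso_search(*planted(), PsoConfig(inertia_weight=0.5, individual_weight=0.3,
                                             social_weight=0.3))


def test_both_searches_recover_planted_features_small():
    hits_ga = hits_pso = 0
    for seed in range(5):
        X, y = planted(n=200, n_features=10, seed=100 + seed)
        ga = sel.genetic_search(X, y, GeneticConfig(seed=seed))
        ps = sel.pso_search(X, y, PsoConfig(seed=seed))
        hits_ga += ga.mask[:3].all()
        hits_pso += ps.mask[:3].all()
    assert hits_ga >= 4 and hits_pso >= 4


def test_union_is_bitwise_or_with_expected_algebra():
    a = FeatureSubset(np.array([0, 1, 0, 1], dtype=bool), 0.8, "genetic")
    b = FeatureSubset(np.array([0, 1, 1, 0], dtype=bool), 0.7, "pso")
    u = sel.subset_union(a, b)
    assert list(u.mask) == [False, True, True, True]
    assert u.provenance == "union"
    assert u.size >= max(a.size, b.size)
    assert np.array_equal(sel.subset_union(a, a).mask, a.mask)
    empty = FeatureSubset(np.zeros(4, dtype=bool), 0.0, "pso")
    assert np.array_equal(sel.subset_union(a, empty).mask, a.mask)


def test_union_rejects_dimension_mismatch():
    a = FeatureSubset(np.ones(4, dtype=bool), 0.5, "genetic")
    b = FeatureSubset(np.ones(5, dtype=bool), 0.5, "pso")
    with pytest.raises(ParameterError):
        sel.subset_union(a, b)


def test_exhaustive_search_upper_bounds_metaheuristics():
    X, y = planted(n=150, n_features=6, seed=42)
    exh = sel.exhaustive_search(X, y, cv_folds=5, seed=0)
    ga = sel.genetic_search(X, y, GeneticConfig(seed=0), cv_folds=5)
    assert exh.fitness >= ga.fitness - 1e-12
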