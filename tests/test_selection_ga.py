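import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

from critres.selection_ga import (
    CLASS_WEIGHT_PRESETS,
    FitnessRecord,
    GAConfig,
    GeneticSubsetSelector,
    _resolve_class_weight,
    evaluate_fitness,
    init_population,
    mutate,
    ssocf_crossover,
    tournament_select,
)
from critres.synthetic import make_feature_table


class FakeRng:
    """Deterministic stand-in feeding preset draws to the GA primitives."""

    def __init__(self, integer_draws=(), random_draws=()):
        self._ints = list(integer_draws)
        self._rands = list(random_draws)

    def integers(self, low, high=None, size=None):
        v = self._ints.pop(0)
        return np.asarray(v) if size is not None else v

    def random(self):
        return self._rands.pop(0)


# --- initialization ----------------------------------------------------------

def test_init_population_sizes_within_range():
    rng = np.random.default_rng(0)
    cfg = GAConfig()
    pop = init_population(100, cfg, rng)
    assert len(pop) == 50
    assert all(1 <= len(ch) <= 10 for ch in pop)
    assert all(max(ch) < 100 for ch in pop)


def test_init_population_reproducible_and_clamped():
    cfg = GAConfig()
    p1 = init_population(100, cfg, np.random.default_rng(42))
    p2 = init_population(100, cfg, np.random.default_rng(42))
    assert p1 == p2
    tiny = init_population(5, cfg, np.random.default_rng(0))
    assert all(len(ch) == 1 for ch in tiny)


def test_init_population_size_distribution_uniform():
    cfg = GAConfig(population_size=10_000)
    pop = init_population(100, cfg, np.random.default_rng(1))
    sizes = np.bincount([len(ch) for ch in pop], minlength=11)[1:]
    expected = len(pop) / 10
    # chi-square against uniform on [1,10]
    chi2 = ((sizes - expected) ** 2 / expected).sum()
    assert chi2 < 27.9  # 99.9% quantile, 9 dof


# --- tournament --------------------------------------------------------------

def test_tournament_prefers_higher_mcc_with_exact_probability():
    pop = [frozenset({0}), frozenset({1})]
    fitness = {pop[0]: FitnessRecord(pop[0], 0.9), pop[1]: FitnessRecord(pop[1], 0.1)}
    wins = 0
    # enumerate all 4 equally likely draw pairs
    for draw in ([0, 0], [0, 1], [1, 0], [1, 1]):
        chosen = tournament_select(pop, fitness, FakeRng(integer_draws=[draw]))
        wins += chosen == pop[0]
    assert wins == 3  # P(best) = 3/4


def test_tournament_tie_breaks_to_smaller_subset_then_first_drawn():
    small, big = frozenset({0, 1, 2}), frozenset(range(7))
    fitness = {small: FitnessRecord(small, 0.5), big: FitnessRecord(big, 0.5)}
    assert tournament_select([big, small], fitness, FakeRng([[0, 1]])) == small
    same = frozenset({1, 2}), frozenset({3, 4})
    fit2 = {same[0]: FitnessRecord(same[0], 0.5), same[1]: FitnessRecord(same[1], 0.5)}
    assert tournament_select(list(same), fit2, FakeRng([[0, 1]])) == same[0]


def test_tournament_single_chromosome_population():
    only = frozenset({3})
    fitness = {only: FitnessRecord(only, 0.2)}
    assert tournament_select([only], fitness, FakeRng([[0, 0]])) == only


# --- SSOCF crossover ---------------------------------------------------------

def test_identical_parents_yield_copies():
    p = frozenset({1, 2, 3})
    c1, c2 = ssocf_crossover(p, p, np.random.default_rng(0))
    assert c1 == p and c2 == p


def test_two_feature_parents_enumerated_outcomes():
    p1, p2 = frozenset({1, 2}), frozenset({1, 3})
    seen = set()
    for seed in range(20):
        c1, c2 = ssocf_crossover(p1, p2, np.random.default_rng(seed))
        assert {c1, c2} <= {p1, p2}
        assert len(c1) == len(p1) and len(c2) == len(p2)
        seen.add((c1, c2))
    assert seen == {(p1, p2), (p2, p1)}


def test_ssocf_preserves_sizes_and_common_features():
    rng = np.random.default_rng(5)
    for _ in range(1000):
        m = 30
        p1 = frozenset(rng.choice(m, size=rng.integers(1, 10), replace=False).tolist())
        p2 = frozenset(rng.choice(m, size=rng.integers(1, 10), replace=False).tolist())
        c1, c2 = ssocf_crossover(p1, p2, rng)
        assert len(c1) == len(p1) and len(c2) == len(p2)
        assert (p1 & p2) <= c1 and (p1 & p2) <= c2
        assert c1 | c2 == p1 | p2


# --- mutation ----------------------------------------------------------------

def test_mutation_toggles_and_guards_emptiness():
    rng_add = FakeRng(integer_draws=[5], random_draws=[0.0])
    assert mutate(frozenset({1}), 10, rng_add) == frozenset({1, 5})
    rng_rm = FakeRng(integer_draws=[1], random_draws=[0.0])
    assert mutate(frozenset({1, 2}), 10, rng_rm) == frozenset({2})
    # singleton: removal re-draws until it becomes an addition
    rng_guard = FakeRng(integer_draws=[0, 0, 7], random_draws=[0.0])
    assert mutate(frozenset({0}), 10, rng_guard) == frozenset({0, 7})
    # no mutation event
    rng_skip = FakeRng(random_draws=[0.99])
    assert mutate(frozenset({1}), 10, rng_skip, prob=0.1) == frozenset({1})


def test_double_toggle_is_identity():
    ch = frozenset({1, 2})
    once = mutate(ch, 10, FakeRng([4], [0.0]))
    twice = mutate(once, 10, FakeRng([4], [0.0]))
    assert twice == ch


# --- fitness -----------------------------------------------------------------

def _folds(X, y, k=10, seed=0):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(X, y))


def test_separable_subset_reaches_perfect_mcc():
    table, truth = make_feature_table(
        n_instances=200, n_informative=3, n_noise=5, effect_size=6.0, seed=1
    )
    X = table.X.to_numpy()
    y = table.y.to_numpy()
    chrom = frozenset(
        i for i, n in enumerate(table.descriptor_names) if n in truth.informative
    )
    rec = evaluate_fitness(chrom, X, y, _folds(X, y), None)
    assert rec.mcc == pytest.approx(1.0)


def test_label_permutation_gives_near_zero_mcc():
    table, truth = make_feature_table(
        n_instances=200, n_informative=3, n_noise=5, effect_size=6.0, seed=2
    )
    X = table.X.to_numpy()
    y = np.random.default_rng(0).permutation(table.y.to_numpy())
    chrom = frozenset(range(3))
    rec = evaluate_fitness(chrom, X, y, _folds(X, y), None)
    assert abs(rec.mcc) < 0.15


def test_class_weights_do_not_reduce_minority_recall():
    table, truth = make_feature_table(
        n_instances=200, n_informative=3, n_noise=2, effect_size=1.0,
        class_balance=0.15, seed=3,
    )
    X = table.X.to_numpy()
    y = table.y.to_numpy()
    folds = _folds(X, y)
    chrom = frozenset(range(X.shape[1]))

    def minority_recall(cw):
        from sklearn.svm import LinearSVC

        hits = total = 0
        for train, test in folds:
            clf = LinearSVC(class_weight=cw, dual=False).fit(X[train], y[train])
            pred = clf.predict(X[test])
            mask = y[test] == "critical"
            hits += (pred[mask] == "critical").sum()
            total += mask.sum()
        return hits / total

    weighted = minority_recall({"critical": 9.0, "non-critical": 3.0})
    unweighted = minority_recall(None)
    assert weighted >= unweighted


def test_class_weight_preset_resolution():
    cw = _resolve_class_weight("set1", ["critical", "non-critical"])
    assert cw == CLASS_WEIGHT_PRESETS["set1"]
    cw01 = _resolve_class_weight({"critical": 5, "non-critical": 1.22}, [0, 1])
    assert cw01 == {1: 5, 0: 1.22}
    with pytest.raises(ValueError, match="preset"):
        _resolve_class_weight("set9", ["critical", "non-critical"])


# --- evolution ---------------------------------------------------------------

def test_identical_population_without_mutation_is_fixed_point():
    table, _ = make_feature_table(n_instances=60, n_informative=2, n_noise=18, seed=4)
    sel = GeneticSubsetSelector(
        population_size=6, mutation_prob=0.0, max_generations=3,
        stagnation=99, cv=3, random_state=0,
    )
    # force identical initial population by monkeypatching init
    import critres.selection_ga as ga

    fixed = frozenset({0, 1})
    orig = ga.init_population
    ga.init_population = lambda m, cfg, rng: [fixed] * 6
    try:
        sel.fit(table.X, table.y.to_numpy())
    finally:
        ga.init_population = orig
    assert sel.best_subset_ == (0, 1)
    assert all(h["best_mcc"] == sel.history_[0]["best_mcc"] for h in sel.history_)


def test_best_ever_fitness_monotone_and_run_reproducible():
    table, _ = make_feature_table(n_instances=80, n_informative=3, n_noise=27, seed=5)
    kw = dict(population_size=12, max_generations=6, stagnation=99, cv=4,
              random_state=7)
    sel1 = GeneticSubsetSelector(**kw).fit(table.X, table.y.to_numpy())
    best = [h["best_ever_mcc"] for h in sel1.history_]
    assert best == sorted(best)
    sel2 = GeneticSubsetSelector(**kw).fit(table.X, table.y.to_numpy())
    assert sel1.best_subset_ == sel2.best_subset_
    assert sel1.history_ == sel2.history_


def test_selector_transform_drops_unselected_columns():
    table, _ = make_feature_table(n_instances=60, n_informative=2, n_noise=18, seed=6)
    sel = GeneticSubsetSelector(population_size=8, max_generations=3, stagnation=99,
                                cv=3, random_state=1)
    sel.fit(table.X, table.y.to_numpy())
    reduced = sel.transform(table.X.to_numpy())
    assert reduced.shape == (60, len(sel.best_subset_))
    assert sel.selected_names_ == [table.descriptor_names[i] for i in sel.best_subset_]


def test_single_class_table_rejected():
    X = np.random.default_rng(0).normal(size=(30, 12))
    y = np.array(["critical"] * 30)
    with pytest.raises(ValueError, match="both classes"):
        GeneticSubsetSelector(cv=2).fit(X, y)
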