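"""Genetic-algorithm wrapper feature selection.

A chromosome is a non-empty set of descriptor indices.  Fitness is the
mean Matthews correlation coefficient of a class-weighted linear SVM over
stratified 10-fold cross-validation restricted to the selected columns.
The search uses binary tournament selection with replacement, the Subset
Size-Oriented Common Feature (SSOCF) crossover (children keep all common
features and split the symmetric difference so parent sizes are preserved
exactly), a single-index toggle mutation, and elitism, so the best-ever
fitness is monotone non-decreasing across generations.

Class-weight presets mirror the penalty rescaling used for imbalanced
residue datasets: ``"set1"`` weights (critical 9, non-critical 3) and
``"set3"`` weights (critical 5, non-critical 1.22).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.exceptions import ConvergenceWarning
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

log = logging.getLogger(__name__)

CLASS_WEIGHT_PRESETS = {
    "set1": {"critical": 9.0, "non-critical": 3.0},
    "set3": {"critical": 5.0, "non-critical": 1.22},
}

Chromosome = frozenset


@dataclass
class GAConfig:
    population_size: int = 50
    crossover_prob: float = 0.7
    mutation_prob: float = 0.1
    elitism: int = 1
    max_generations: int = 100
    stagnation: int = 20
    cv_folds: int = 10
    class_weight: object = None
    C: float = 1.0
    rng_seed: int | None = None

    def __post_init__(self):
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")


@dataclass
class FitnessRecord:
    chromosome: Chromosome
    mcc: float
    fold_mccs: list[float] = field(default_factory=list)

    @property
    def subset_size(self) -> int:
        return len(self.chromosome)


# --- GA primitives -----------------------------------------------------------

def init_population(m: int, cfg: GAConfig, rng: np.random.Generator) -> list[Chromosome]:
    """Random chromosomes with sizes uniform on [1, floor(m/10)]."""
    max_size = m // 10
    if max_size < 1:
        log.warning("m=%d < 10; chromosome size range clamps to [1, 1]", m)
        max_size = 1
    pop = []
    for _ in range(cfg.population_size):
        size = int(rng.integers(1, max_size + 1))
        pop.append(frozenset(int(i) for i in rng.choice(m, size=size, replace=False)))
    return pop


def _better(a: FitnessRecord, b: FitnessRecord) -> FitnessRecord:
    """Higher MCC wins; ties go to the smaller subset, then the first drawn."""
    if b.mcc > a.mcc or (b.mcc == a.mcc and b.subset_size < a.subset_size):
        return b
    return a


def tournament_select(
    population: list[Chromosome],
    fitness: dict[Chromosome, FitnessRecord],
    rng: np.random.Generator,
) -> Chromosome:
    i, j = rng.integers(0, len(population), size=2)
    return _better(fitness[population[int(i)]], fitness[population[int(j)]]).chromosome


def ssocf_crossover(
    p1: Chromosome, p2: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Children keep p1 & p2's common features; the rest of the union is
    partitioned so that |c1| = |p1| and |c2| = |p2|."""
    if not p1 or not p2:
        raise ValueError("parents must be non-empty")
    common = p1 & p2
    uncommon = sorted((p1 | p2) - common)
    if not uncommon:
        return frozenset(p1), frozenset(p2)
    n1 = len(p1) - len(common)
    picks = set(
        int(i) for i in rng.choice(len(uncommon), size=n1, replace=False)
    ) if n1 else set()
    c1 = set(common)
    c2 = set(common)
    for idx, feat in enumerate(uncommon):
        (c1 if idx in picks else c2).add(feat)
    return frozenset(c1), frozenset(c2)


def mutate(
    chrom: Chromosome, m: int, rng: np.random.Generator, prob: float = 0.1
) -> Chromosome:
    """With probability *prob*, toggle membership of one uniform index.

    A removal that would empty the chromosome re-draws until the drawn
    index is an addition, keeping chromosomes non-empty.
    """
    if rng.random() >= prob:
        return chrom
    idx = int(rng.integers(0, m))
    if idx in chrom:
        if len(chrom) == 1:
            while idx in chrom:
                idx = int(rng.integers(0, m))
            return chrom | {idx}
        return chrom - {idx}
    return chrom | {idx}


# --- fitness -----------------------------------------------------------------

def _resolve_class_weight(class_weight, classes) -> dict | None:
    if class_weight is None:
        return None
    if isinstance(class_weight, str):
        preset = CLASS_WEIGHT_PRESETS.get(class_weight)
        if preset is None:
            raise ValueError(
                f"unknown class-weight preset {class_weight!r}; "
                f"choose from {sorted(CLASS_WEIGHT_PRESETS)}"
            )
        class_weight = preset
    resolved = {}
    classes = list(classes)
    for key, w in class_weight.items():
        if key in classes:
            resolved[key] = w
        elif key == "critical" and 1 in classes:
            resolved[1] = w
        elif key == "non-critical" and 0 in classes:
            resolved[0] = w
        else:
            raise ValueError(f"class-weight key {key!r} not among classes {classes}")
    return resolved


def evaluate_fitness(
    chrom: Chromosome,
    X: np.ndarray,
    y: np.ndarray,
    folds: list[tuple[np.ndarray, np.ndarray]],
    class_weight: dict | None,
    C: float = 1.0,
) -> FitnessRecord:
    """Mean MCC of a weighted linear SVM over precomputed stratified folds."""
    cols = sorted(chrom)
    Xs = X[:, cols]
    fold_mccs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for train, test in folds:
            clf = LinearSVC(C=C, class_weight=class_weight, dual=False, tol=1e-4)
            clf.fit(Xs[train], y[train])
            fold_mccs.append(float(matthews_corrcoef(y[test], clf.predict(Xs[test]))))
    return FitnessRecord(chrom, float(np.mean(fold_mccs)), fold_mccs)


# --- the selector ------------------------------------------------------------

class GeneticSubsetSelector(SelectorMixin, BaseEstimator):
    """Wrapper feature selection by GA over cross-validated weighted-SVM MCC.

    Parameters mirror :class:`GAConfig`; ``class_weight`` accepts a dict,
    a preset name (``"set1"``, ``"set3"``) or None.  After :meth:`fit`:

    - ``support_``: boolean mask of selected descriptors;
    - ``best_subset_``: sorted tuple of selected column indices;
    - ``best_score_``: its cross-validated mean MCC;
    - ``history_``: per-generation best/mean fitness records.
    """

    def __init__(self, population_size=50, crossover_prob=0.7, mutation_prob=0.1,
                 elitism=1, max_generations=100, stagnation=20, cv=10,
                 class_weight=None, C=1.0, random_state=None):
        self.population_size = population_size
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.elitism = elitism
        self.max_generations = max_generations
        self.stagnation = stagnation
        self.cv = cv
        self.class_weight = class_weight
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need both classes present to evaluate fitness")
        m = X.shape[1]
        self.n_features_in_ = m

        cfg = GAConfig(
            population_size=self.population_size,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            elitism=self.elitism,
            max_generations=self.max_generations,
            stagnation=self.stagnation,
            cv_folds=self.cv,
            class_weight=self.class_weight,
            C=self.C,
            rng_seed=self.random_state,
        )
        rng = np.random.default_rng(self.random_state)
        cw = _resolve_class_weight(self.class_weight, classes)
        skf = StratifiedKFold(
            n_splits=self.cv, shuffle=True,
            random_state=None if self.random_state is None else int(self.random_state) % (2**31),
        )
        folds = [(tr, te) for tr, te in skf.split(X, y)]

        cache: dict[Chromosome, FitnessRecord] = {}

        def fit_of(ch: Chromosome) -> FitnessRecord:
            rec = cache.get(ch)
            if rec is None:
                rec = evaluate_fitness(ch, X, y, folds, cw, self.C)
                cache[ch] = rec
            return rec

        population = init_population(m, cfg, rng)
        records = {ch: fit_of(ch) for ch in population}
        best_ever = max(records.values(), key=lambda r: (r.mcc, -r.subset_size))
        self.history_ = []
        stagnant = 0

        for gen in range(self.max_generations):
            fitness = {ch: fit_of(ch) for ch in population}
            ordered = sorted(
                population,
                key=lambda ch: (-fitness[ch].mcc, len(ch), tuple(sorted(ch))),
            )
            elites = ordered[: self.elitism]
            offspring: list[Chromosome] = []
            while len(offspring) < self.population_size - self.elitism:
                pa = tournament_select(population, fitness, rng)
                pb = tournament_select(population, fitness, rng)
                if rng.random() < self.crossover_prob:
                    c1, c2 = ssocf_crossover(pa, pb, rng)
                else:
                    c1, c2 = pa, pb
                offspring.append(mutate(c1, m, rng, self.mutation_prob))
                if len(offspring) < self.population_size - self.elitism:
                    offspring.append(mutate(c2, m, rng, self.mutation_prob))
            population = elites + offspring

            gen_records = [fit_of(ch) for ch in population]
            gen_best = max(gen_records, key=lambda r: (r.mcc, -r.subset_size))
            if gen_best.mcc > best_ever.mcc:
                best_ever = gen_best
                stagnant = 0
            else:
                stagnant += 1
            self.history_.append(
                {
                    "generation": gen,
                    "best_mcc": gen_best.mcc,
                    "best_ever_mcc": best_ever.mcc,
                    "mean_mcc": float(np.mean([r.mcc for r in gen_records])),
                    "best_size": gen_best.subset_size,
                }
            )
            if stagnant >= self.stagnation:
                log.info("stopping after %d stagnant generations", stagnant)
                break

        self.best_record_ = best_ever
        self.best_subset_ = tuple(sorted(best_ever.chromosome))
        self.best_score_ = best_ever.mcc
        self.support_ = np.zeros(m, dtype=bool)
        self.support_[list(best_ever.chromosome)] = True
        if hasattr(self, "feature_names_in_"):
            self.selected_names_ = [
                str(self.feature_names_in_[i]) for i in self.best_subset_
            ]
        return self

    def _get_support_mask(self):
        return self.support_
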