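"""Genetic-algorithm tuning of an RBF support-vector classifier.

The penalty coefficient c and kernel coefficient g of an RBF SVM are tuned
by a real-coded genetic algorithm operating on (log10 c, log10 g):
tournament selection, uniform crossover and Gaussian mutation, with
cross-validated training accuracy as the fitness.  The search is fully
seeded and therefore reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = ["SvmConfig", "GASVMClassifier", "GASVMResults"]


@dataclass
class SvmConfig:
    """Search bounds (log-uniform) and GA settings for (c, g) tuning.

    Default bounds span several decades so both very smooth and very sharp
    kernels are reachable.
    """

    c_bounds: tuple[float, float] = (1e-2, 1e3)
    g_bounds: tuple[float, float] = (1e-5, 1e2)
    population: int = 20
    generations: int = 30
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    mutation_sigma: float = 0.3  # in log10 units
    cv_folds: int = 3
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.c_bounds, self.g_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must be positive and ordered")
        if self.population < 2 or self.generations < 1:
            raise ValueError("population >= 2 and generations >= 1 required")


@dataclass
class GASVMResults:
    """Best (c, g) found, its fitness trail, and accuracies."""

    c: float
    g: float
    accuracy_train: float
    accuracy_test: float
    cv_fitness: float
    fitness_history: np.ndarray = field(repr=False)
    initial_fitness: np.ndarray = field(repr=False)
    estimator: SVC = field(repr=False)

    def summary(self) -> str:
        return (
            f"GA-SVM (RBF): c = {self.c:.6g}, g = {self.g:.6g}\n"
            f"  CV fitness {self.cv_fitness:.2f}%\n"
            f"  accuracy: training {self.accuracy_train:.2f}%  "
            f"test {self.accuracy_test:.2f}%"
        )


class GASVMClassifier:
    """Model object: spectra + labels in, GA-tuned SVM results out."""

    def __init__(self, x_train, y_train, x_test, y_test, config: SvmConfig | None = None):
        self.x_train = np.atleast_2d(np.asarray(x_train, float))
        self.y_train = np.asarray(y_train)
        self.x_test = np.atleast_2d(np.asarray(x_test, float))
        self.y_test = np.asarray(y_test)
        if len(np.unique(self.y_train)) < 2:
            raise ValueError("need at least two classes")
        self.config = config or SvmConfig()

    # -- GA internals ---------------------------------------------------
    def _fitness(self, log_c: float, log_g: float) -> float:
        cfg = self.config
        _, counts = np.unique(self.y_train, return_counts=True)
        folds = max(2, min(cfg.cv_folds, counts.min()))
        cv = StratifiedKFold(n_splits=folds, shuffle=False)
        clf = SVC(C=10.0 ** log_c, gamma=10.0 ** log_g, kernel="rbf")
        return float(cross_val_score(clf, self.x_train, self.y_train, cv=cv).mean() * 100)

    def fit(self) -> GASVMResults:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        lo = np.log10([cfg.c_bounds[0], cfg.g_bounds[0]])
        hi = np.log10([cfg.c_bounds[1], cfg.g_bounds[1]])

        pop = rng.uniform(lo, hi, size=(cfg.population, 2))
        fit = np.array([self._fitness(*ind) for ind in pop])
        initial_fitness = fit.copy()
        history = [float(fit.max())]

        for _ in range(cfg.generations):
            new_pop = [pop[int(np.argmax(fit))].copy()]  # elitism
            while len(new_pop) < cfg.population:
                parents = []
                for _ in range(2):  # tournament of 3
                    idx = rng.integers(0, cfg.population, size=3)
                    parents.append(pop[idx[np.argmax(fit[idx])]].copy())
                a, b = parents
                if rng.random() < cfg.crossover_prob:  # uniform crossover
                    swap = rng.random(2) < 0.5
                    a[swap], b[swap] = b[swap], a[swap]
                for child in (a, b):
                    mut = rng.random(2) < cfg.mutation_prob
                    child[mut] += rng.normal(0.0, cfg.mutation_sigma, size=2)[mut]
                    np.clip(child, lo, hi, out=child)
                    if len(new_pop) < cfg.population:
                        new_pop.append(child)
            pop = np.array(new_pop)
            fit = np.array([self._fitness(*ind) for ind in pop])
            history.append(float(fit.max()))

        best = pop[int(np.argmax(fit))]
        c, g = float(10.0 ** best[0]), float(10.0 ** best[1])
        clf = SVC(C=c, gamma=g, kernel="rbf").fit(self.x_train, self.y_train)
        acc_train = float(np.mean(clf.predict(self.x_train) == self.y_train) * 100)
        acc_test = float(np.mean(clf.predict(self.x_test) == self.y_test) * 100)
        return GASVMResults(
            c=c, g=g, accuracy_train=acc_train, accuracy_test=acc_test,
            cv_fitness=float(fit.max()), fitness_history=np.array(history),
            initial_fitness=initial_fitness, estimator=clf,
        )
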