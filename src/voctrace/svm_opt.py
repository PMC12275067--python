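"""RBF-SVM origin classification with three (c, g) search strategies.

The classifier is a one-vs-one multi-class support vector machine with the
radial basis kernel K(u, v) = exp(-g ||u - v||^2); the penalty c and kernel
width g are tuned by one of

* GS  — exhaustive grid search on a log2 grid 2^-10 .. 2^10 (step 2^0.5),
* GA  — a real-coded genetic algorithm on linear ranges c in (0, 100),
          g in (0, 1000),
* GWO — the grey wolf optimizer on (1e-5, 1000) for both parameters,
          searched in log10 coordinates because the range spans 8 decades.

The fitness of a candidate (c, g) is stratified 5-fold cross-validated
accuracy on the training set only; the test set never enters the search.
All strategies are deterministic under a fixed seed and return the best
feasible pair together with the per-iteration best-fitness trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .chemometrics import ClassMetrics, class_metrics

Fitness = Callable[[float, float], float]


@dataclass
class SearchSpace:
    """Hyperparameter box for one search strategy."""

    strategy: str  # GS | GA | GWO
    c_range: tuple[float, float] = (2.0**-10, 2.0**10)
    g_range: tuple[float, float] = (2.0**-10, 2.0**10)
    grid_step_log2: float = 0.5  # GS
    population: int = 20  # GA / GWO
    iterations: int = 100  # GA generations / GWO iterations
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.c_range, self.g_range):
            if not (0 < lo < hi):
                raise ValueError("ranges must be positive and ordered")
        if self.strategy not in ("GS", "GA", "GWO"):
            raise ValueError("strategy must be GS, GA or GWO")


def ga_space(**kw) -> SearchSpace:
    kw.setdefault("c_range", (1e-6, 100.0))
    kw.setdefault("g_range", (1e-6, 1000.0))
    return SearchSpace(strategy="GA", **kw)


def gwo_space(**kw) -> SearchSpace:
    kw.setdefault("c_range", (1e-5, 1000.0))
    kw.setdefault("g_range", (1e-5, 1000.0))
    kw.setdefault("iterations", 50)
    return SearchSpace(strategy="GWO", **kw)


@dataclass
class SearchResult:
    """Best (c, g) with the optimizer trace and final model metrics."""

    c: float
    g: float
    fitness: float
    trace: list[float] = field(default_factory=list)
    train_metrics: ClassMetrics | None = None
    test_metrics: ClassMetrics | None = None
    n_evaluations: int = 0


# ---------------------------------------------------------------------------
# SVM fit / fitness
# ---------------------------------------------------------------------------

def svm_fit_predict(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    c: float,
    g: float,
) -> np.ndarray:
    """Train an RBF-SVM (one-vs-one) and predict labels for X_test."""
    if c <= 0 or g <= 0:
        raise ValueError("c and g must be > 0")
    if len(np.unique(np.asarray(y_train))) < 2:
        raise ValueError("training set has a single class")
    clf = SVC(C=c, gamma=g, kernel="rbf", decision_function_shape="ovo")
    clf.fit(X_train, y_train)
    return clf.predict(X_test)


def cv_accuracy_fitness(X: np.ndarray, y: np.ndarray, folds: int = 5, seed: int = 0) -> Fitness:
    """Stratified k-fold CV accuracy on (X, y), as a fitness of (c, g)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    smallest = int(np.unique(y, return_counts=True)[1].min())
    folds = max(2, min(folds, smallest))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))

    def fitness(c: float, g: float) -> float:
        correct = 0
        for train, test in splits:
            pred = svm_fit_predict(X[train], y[train], X[test], c, g)
            correct += int((pred == y[test]).sum())
        return correct / y.size

    return fitness


# ---------------------------------------------------------------------------
# search strategies
# ---------------------------------------------------------------------------

def grid_search(space: SearchSpace, fitness: Fitness) -> SearchResult:
    """Exhaustive log2-grid search; ties resolve to smaller c, then g."""
    lo_c, hi_c = np.log2(space.c_range)
    lo_g, hi_g = np.log2(space.g_range)
    cs = 2.0 ** np.arange(lo_c, hi_c + 1e-9, space.grid_step_log2)
    gs = 2.0 ** np.arange(lo_g, hi_g + 1e-9, space.grid_step_log2)
    best = None
    trace = []
    for c in cs:  # ascending c then g: first strict improvement wins ties
        for g in gs:
            f = fitness(c, g)
            if best is None or f > best[0]:
                best = (f, c, g)
            trace.append(best[0])
    f, c, g = best
    return SearchResult(c=c, g=g, fitness=f, trace=trace, n_evaluations=len(cs) * len(gs))


def ga_search(space: SearchSpace, fitness: Fitness) -> SearchResult:
    """Real-coded GA: tournament selection, blend crossover, Gaussian
    mutation, elitism of one."""
    rng = np.random.default_rng(space.seed)
    lo = np.array([space.c_range[0], space.g_range[0]])
    hi = np.array([space.c_range[1], space.g_range[1]])
    npop = space.population
    pop = rng.uniform(lo, hi, (npop, 2))
    fit = np.array([fitness(c, g) for c, g in pop])
    trace = [float(fit.max())]
    sigma0 = (hi - lo) / 10.0

    for gen in range(space.iterations):
        elite = pop[int(np.argmax(fit))].copy()
        children = [elite]
        while len(children) < npop:
            # tournament of 3 per parent
            idx1 = rng.choice(npop, 3, replace=False)
            idx2 = rng.choice(npop, 3, replace=False)
            p1 = pop[idx1[np.argmax(fit[idx1])]]
            p2 = pop[idx2[np.argmax(fit[idx2])]]
            alpha = rng.uniform(-0.5, 1.5, 2)  # BLX blend
            child = alpha * p1 + (1 - alpha) * p2
            if rng.random() < 0.2:
                child = child + rng.normal(0, sigma0)
            children.append(np.clip(child, lo, hi))
        pop = np.vstack(children)
        fit = np.concatenate([[fit.max()], [fitness(c, g) for c, g in pop[1:]]])
        trace.append(max(trace[-1], float(fit.max())))

    i = int(np.argmax(fit))
    return SearchResult(
        c=float(pop[i, 0]),
        g=float(pop[i, 1]),
        fitness=float(fit[i]),
        trace=trace,
        n_evaluations=npop * (space.iterations + 1),
    )


def gwo_search(space: SearchSpace, fitness: Fitness) -> SearchResult:
    """Canonical grey wolf optimizer in log10(c), log10(g) coordinates.

    Wolves are ranked alpha/beta/delta; every position update is the mean of
    three leader-guided moves with the control parameter decreasing linearly
    from 2 to 0 over the iterations; positions are clipped to the box.
    """
    if space.population < 4:
        raise ValueError("GWO needs a population of at least 4 (alpha, beta, delta + 1)")
    rng = np.random.default_rng(space.seed)
    lo = np.log10([space.c_range[0], space.g_range[0]])
    hi = np.log10([space.c_range[1], space.g_range[1]])
    npop, iters = space.population, space.iterations

    pos = rng.uniform(lo, hi, (npop, 2))
    fit = np.array([fitness(10.0**c, 10.0**g) for c, g in pos])
    order = np.argsort(-fit)
    leaders = pos[order[:3]].copy()
    leader_fit = fit[order[:3]].copy()
    trace = [float(leader_fit[0])]

    for it in range(iters):
        a = 2.0 * (1.0 - it / iters)
        moves = np.empty((3, npop, 2))
        for k in range(3):
            r1 = rng.random((npop, 2))
            r2 = rng.random((npop, 2))
            A = 2 * a * r1 - a
            C = 2 * r2
            D = np.abs(C * leaders[k] - pos)
            moves[k] = leaders[k] - A * D
        pos = np.clip(moves.mean(axis=0), lo, hi)
        fit = np.array([fitness(10.0**c, 10.0**g) for c, g in pos])
        for i in np.argsort(-fit):
            if fit[i] > leader_fit[2]:
                stack_f = np.concatenate([leader_fit, [fit[i]]])
                stack_p = np.vstack([leaders, pos[i]])
                order = np.argsort(-stack_f)[:3]
                leader_fit = stack_f[order]
                leaders = stack_p[order]
        trace.append(float(leader_fit[0]))

    return SearchResult(
        c=float(10.0 ** leaders[0, 0]),
        g=float(10.0 ** leaders[0, 1]),
        fitness=float(leader_fit[0]),
        trace=trace,
        n_evaluations=npop * (iters + 1),
    )


_STRATEGIES = {"GS": grid_search, "GA": ga_search, "GWO": gwo_search}


def search(space: SearchSpace, fitness: Fitness) -> SearchResult:
    return _STRATEGIES[space.strategy](space, fitness)


def default_space(strategy: str, seed: int = 0, **kw) -> SearchSpace:
    if strategy == "GS":
        return SearchSpace(strategy="GS", seed=seed, **kw)
    if strategy == "GA":
        return ga_space(seed=seed, **kw)
    if strategy == "GWO":
        return gwo_space(seed=seed, **kw)
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# factorial pipeline: {all, VIP>1} x {GS, GA, GWO}
# ---------------------------------------------------------------------------

def tune_and_evaluate(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    space: SearchSpace,
) -> SearchResult:
    """Run one search and attach train/test classification metrics."""
    fitness = cv_accuracy_fitness(X_train, y_train, folds=space.cv_folds, seed=space.seed)
    result = search(space, fitness)
    pred_train = svm_fit_predict(X_train, y_train, X_train, result.c, result.g)
    pred_test = svm_fit_predict(X_train, y_train, X_test, result.c, result.g)
    result.train_metrics = class_metrics(y_train, pred_train)
    result.test_metrics = class_metrics(y_test, pred_test)
    return result


def run_svm_pipeline(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    vip_scores: np.ndarray | None = None,
    strategies: tuple[str, ...] = ("GS", "GA", "GWO"),
    variable_filters: tuple[str, ...] = ("all", "VIP>1"),
    seed: int = 0,
    space_overrides: dict | None = None,
) -> pd.DataFrame:
    """Factorial design {variable filter} x {search strategy}.

    Returns one row per cell with best (c, g) and train/test ACC, F1, P, R.
    ``vip_scores`` (per input variable, from an OPLS-DA of the training set)
    is required when the VIP>1 filter is requested.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    rows = []
    for vf in variable_filters:
        if vf == "all":
            cols = np.arange(X_train.shape[1])
        elif vf == "VIP>1":
            if vip_scores is None:
                raise ValueError("VIP>1 filter requires vip_scores")
            cols = np.flatnonzero(np.asarray(vip_scores) > 1.0)
            if cols.size < 2:
                raise ValueError("VIP>1 retains < 2 variables")
        else:
            raise ValueError(f"unknown variable filter {vf!r}")
        for strat in strategies:
            space = default_space(strat, seed=seed, **(space_overrides or {}))
            res = tune_and_evaluate(
                X_train[:, cols], y_train, X_test[:, cols], y_test, space
            )
            rows.append(
                {
                    "variable_filter": vf,
                    "strategy": strat,
                    "n_variables": int(cols.size),
                    "c": res.c,
                    "g": res.g,
                    "train_ACC": res.train_metrics.accuracy,
                    "train_F1": res.train_metrics.f1,
                    "train_P": res.train_metrics.precision,
                    "train_R": res.train_metrics.recall,
                    "test_ACC": res.test_metrics.accuracy,
                    "test_F1": res.test_metrics.f1,
                    "test_P": res.test_metrics.precision,
                    "test_R": res.test_metrics.recall,
                }
            )
    return pd.DataFrame(rows)
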