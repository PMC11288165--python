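"""Stage-2 genetic algorithm: search per-class train/test splits.

A candidate solution assigns exactly N_cs training entries to every class
(the rest are test entries). It is scored by the held-out accuracy of a
cheap in-loop evaluator, weighted by a balance factor SF in [0, 1] that
compares the variance structure of the train and test sides: partitions
whose two sides carry equally variant class structure score SF near 1.
Solutions below the population-mean fitness are regenerated with fresh
per-class uniform index draws; a best-ever elite is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier

from .ngram_features import FeatureMatrix
from .selection import MUTATE, CROSSOVER, feature_scores, fitness_threshold

EVALUATORS = ("naive_bayes", "logistic", "random_forest", "full_ensemble")


@dataclass
class PartitionConfig:
    n_iterations: int = 10
    n_solutions: int = 8
    learning_rate: float = 0.01
    seed: int = 0
    p_test: float = 0.2
    p_val: float = 0.15
    evaluator: str = "naive_bayes"
    epsilon: float = 1e-9

    def validate(self) -> None:
        if self.n_iterations < 1 or self.n_solutions < 2:
            raise ValueError("need n_iterations >= 1 and n_solutions >= 2")
        if not 0 < self.p_test < 1:
            raise ValueError("p_test must be in (0, 1)")
        if not 0 <= self.p_val < 1 - self.p_test:
            raise ValueError("p_val must be in [0, 1 - p_test)")
        if self.evaluator not in EVALUATORS:
            raise ValueError(f"evaluator must be one of {EVALUATORS}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class PartitionSolution:
    train_idx: dict[int, np.ndarray]
    test_idx: np.ndarray
    f_train: float
    f_test: float
    sf: float
    acc_test: float
    fitness: float
    status: str | None = None

    @property
    def train_rows(self) -> np.ndarray:
        return np.sort(np.concatenate(list(self.train_idx.values())))


@dataclass
class PartitionResult:
    best: PartitionSolution
    history: list[dict] = field(default_factory=list)
    config: PartitionConfig | None = None
    n_evaluations: int = 0
    clamped_classes: list[int] = field(default_factory=list)
    final_solutions: list[PartitionSolution] = field(default_factory=list)


def entries_per_class(
    p_test: float,
    n_entries: int,
    n_classes: int,
    min_class_size: int | None = None,
) -> int:
    """Balanced per-class training quota.

    N_cs = floor((1 - p_test) * N_d / N_c), clamped so every class keeps at
    least one test entry when ``min_class_size`` is known.
    """
    if n_classes < 2 or n_entries < n_classes:
        raise ValueError("need n_entries >= n_classes >= 2")
    if not 0 < p_test < 1:
        raise ValueError("p_test must be in (0, 1)")
    n_cs = int(np.floor((1 - p_test) * n_entries / n_classes))
    n_cs = max(1, n_cs)
    if min_class_size is not None:
        if min_class_size < 2:
            raise ValueError(
                "a class with fewer than 2 records cannot be split into train and test"
            )
        n_cs = min(n_cs, min_class_size - 1)
    return n_cs


def optimization_factor(f_train: float, f_test: float, epsilon: float = 1e-9) -> float:
    """Balance factor SF = min/(max + eps) in [0, 1]; 1 means the train and
    test sides carry equally variant class structure."""
    if f_train < 0 or f_test < 0:
        raise ValueError("variance fitnesses must be non-negative")
    lo, hi = sorted((f_train, f_test))
    return lo / (hi + epsilon)


def partition_fitness(acc_test: float, sf: float) -> float:
    """Combined solution fitness: held-out accuracy times the balance factor."""
    if not 0 <= acc_test <= 1 or not 0 <= sf <= 1:
        raise ValueError("acc_test and sf must be in [0, 1]")
    return acc_test * sf


def make_evaluator(name: str, seed: int):
    if name == "naive_bayes":
        return GaussianNB()
    if name == "logistic":
        return LogisticRegression(max_iter=500, random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=50, random_state=seed)
    if name == "full_ensemble":
        from .ensemble import EnsembleEvaluator

        return EnsembleEvaluator(seed=seed)
    raise ValueError(f"unknown evaluator {name!r}")


def _sample_partition(
    rng: np.random.Generator,
    y: np.ndarray,
    class_rows: dict[int, np.ndarray],
    n_cs: int,
) -> tuple[dict[int, np.ndarray], np.ndarray]:
    train_idx: dict[int, np.ndarray] = {}
    train_mask = np.zeros(y.shape[0], dtype=bool)
    for c, rows in class_rows.items():
        quota = min(n_cs, rows.size - 1)
        chosen = rng.choice(rows, size=quota, replace=False)
        chosen = np.sort(chosen)
        train_idx[c] = chosen
        train_mask[chosen] = True
    return train_idx, np.nonzero(~train_mask)[0]


def _evaluate_partition(
    fm: FeatureMatrix,
    train_idx: dict[int, np.ndarray],
    test_idx: np.ndarray,
    config: PartitionConfig,
) -> PartitionSolution:
    train_rows = np.sort(np.concatenate(list(train_idx.values())))
    X, y = fm.X, fm.y
    f_train = float(
        feature_scores(X[train_rows], y[train_rows], fm.n_classes, config.epsilon).mean()
    )
    f_test = float(
        feature_scores(X[test_idx], y[test_idx], fm.n_classes, config.epsilon).mean()
    )
    sf = optimization_factor(f_train, f_test, config.epsilon)
    clf = make_evaluator(config.evaluator, config.seed)
    try:
        clf.fit(X[train_rows], y[train_rows])
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"evaluator {config.evaluator!r} failed to train") from exc
    acc = float(np.mean(clf.predict(X[test_idx]) == y[test_idx]))
    return PartitionSolution(
        train_idx=train_idx,
        test_idx=test_idx,
        f_train=f_train,
        f_test=f_test,
        sf=sf,
        acc_test=acc,
        fitness=partition_fitness(acc, sf),
    )


def run_partition_ga(fm: FeatureMatrix, config: PartitionConfig) -> PartitionResult:
    """Search train/test partitions of ``fm`` (already feature-reduced).

    All solutions start marked ``mutate``; each iteration, mutate-marked
    solutions are resampled and evaluated, the population-mean fitness forms
    the threshold, and below-threshold solutions are marked for regeneration.
    """
    config.validate()
    counts = np.bincount(fm.y, minlength=fm.n_classes)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 records")
    n_cs = entries_per_class(
        config.p_test, fm.n_records, fm.n_classes, int(counts.min())
    )
    class_rows = {c: np.nonzero(fm.y == c)[0] for c in range(fm.n_classes)}
    clamped = [c for c, rows in class_rows.items() if rows.size - 1 < n_cs]

    rng = np.random.default_rng(config.seed)
    solutions: list[PartitionSolution | None] = [None] * config.n_solutions
    statuses = [MUTATE] * config.n_solutions
    best: PartitionSolution | None = None
    history: list[dict] = []
    n_evaluations = 0

    for iteration in range(config.n_iterations):
        for i in range(config.n_solutions):
            if statuses[i] != MUTATE:
                continue
            train_idx, test_idx = _sample_partition(rng, fm.y, class_rows, n_cs)
            sol = _evaluate_partition(fm, train_idx, test_idx, config)
            solutions[i] = sol
            n_evaluations += 1
            if best is None or sol.fitness > best.fitness:
                best = sol
        fits = np.array([s.fitness for s in solutions])
        f_th = fitness_threshold(fits)
        for i, sol in enumerate(solutions):
            statuses[i] = MUTATE if sol.fitness < f_th else CROSSOVER
            sol.status = statuses[i]
        history.append(
            {
                "iteration": iteration,
                "threshold": f_th,
                "mean_fitness": f_th,
                "iteration_best": float(fits.max()),
                "best_fitness": best.fitness,
                "best_acc_test": best.acc_test,
                "fitnesses": [float(f) for f in fits],
                "statuses": list(statuses),
            }
        )

    return PartitionResult(
        best=best,
        history=history,
        config=config,
        n_evaluations=n_evaluations,
        clamped_classes=clamped,
        final_solutions=list(solutions),
    )


def save_partition(
    ids: list[str],
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    path: str | Path,
    val_rows: np.ndarray | None = None,
) -> None:
    split = {}
    for r in train_rows:
        split[int(r)] = "train"
    if val_rows is not None:
        for r in val_rows:
            split[int(r)] = "val"
    for r in test_rows:
        split[int(r)] = "test"
    with open(path, "w") as fh:
        fh.write("id\tsplit\n")
        for i, rid in enumerate(ids):
            fh.write(f"{rid}\t{split.get(i, 'unassigned')}\n")


def save_partition_history(result: PartitionResult, path: str | Path) -> None:
    payload = {
        "best_fitness": result.best.fitness,
        "best_acc_test": result.best.acc_test,
        "best_sf": result.best.sf,
        "n_evaluations": result.n_evaluations,
        "clamped_classes": result.clamped_classes,
        "config": asdict(result.config) if result.config else None,
        "history": result.history,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
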