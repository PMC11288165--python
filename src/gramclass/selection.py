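"""Stage-1 genetic algorithm: feature-subset selection by inter-class variance.

A candidate solution is a binary mask over the k-mer features. Its fitness is
the mean, over selected features, of the ratio of between-class variance
(variance of the per-class means) to within-class variance (mean of the
per-class population variances), stabilized by a small epsilon. Each
iteration, solutions below the population-mean fitness threshold are marked
``mutate`` and regenerated from scratch (a fresh stochastic feature-count
draw and a fresh uniform feature sample); the rest are marked ``crossover``
and pass unchanged. A best-ever elite is tracked so the returned optimum can
never be lost to regeneration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .ngram_features import FeatureMatrix

MUTATE = "mutate"
CROSSOVER = "crossover"


@dataclass
class GAConfig:
    """Knobs shared by both GA stages.

    ``stoch_lo``/``stoch_hi`` bound the stochastic feature-count draw as
    fractions of the total feature count; ``learning_rate`` is stored here
    but only drives gradient-trained ensemble members downstream.
    """

    n_iterations: int = 30
    n_solutions: int = 20
    learning_rate: float = 0.01
    stoch_lo: float = 0.1
    stoch_hi: float = 0.5
    seed: int = 0
    epsilon: float = 1e-9

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_solutions < 2:
            raise ValueError("n_solutions must be >= 2")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 < self.stoch_lo <= self.stoch_hi <= 1:
            raise ValueError("need 0 < stoch_lo <= stoch_hi <= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class SelectionSolution:
    mask: np.ndarray
    fitness: float
    status: str | None = None

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


@dataclass
class SelectionResult:
    best_mask: np.ndarray
    best_fitness: float
    history: list[dict] = field(default_factory=list)
    config: GAConfig | None = None
    n_evaluations: int = 0
    final_solutions: list[SelectionSolution] = field(default_factory=list)


def draw_nstoch(
    rng: np.random.Generator, n_features: int, stoch_lo: float, stoch_hi: float
) -> int:
    """Uniform integer draw in [max(1, ceil(lo*N_f)), ceil(hi*N_f)]."""
    if n_features < 2:
        raise ValueError("need at least 2 features")
    lo = max(1, int(np.ceil(stoch_lo * n_features)))
    hi = int(np.ceil(stoch_hi * n_features))
    if hi < 1 or hi < lo:
        raise ValueError(f"stochastic bounds collapse: [{lo}, {hi}]")
    return int(rng.integers(lo, hi + 1))


def class_variance_stats(
    X: np.ndarray, y: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature between-class variance B (population variance of the
    class means) and within-class variance W (mean of per-class population
    variances). Every class must be represented."""
    X = np.asarray(X, dtype=float)
    means = np.empty((n_classes, X.shape[1]))
    variances = np.empty((n_classes, X.shape[1]))
    for c in range(n_classes):
        rows = X[y == c]
        if rows.shape[0] == 0:
            raise ValueError(f"class index {c} has no records")
        means[c] = rows.mean(axis=0)
        variances[c] = rows.var(axis=0)
    return means.var(axis=0), variances.mean(axis=0)


def feature_scores(
    X: np.ndarray, y: np.ndarray, n_classes: int, epsilon: float = 1e-9
) -> np.ndarray:
    """Per-feature discriminativeness score B_j / (W_j + epsilon)."""
    B, W = class_variance_stats(X, y, n_classes)
    return B / (W + epsilon)


def solution_fitness(
    fm: FeatureMatrix, mask: np.ndarray, epsilon: float = 1e-9
) -> float:
    """Mean variance-ratio score over the selected features."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 1:
        raise ValueError("mask selects no features")
    if fm.n_classes < 2:
        raise ValueError("need at least 2 classes")
    scores = feature_scores(fm.X[:, mask], fm.y, fm.n_classes, epsilon)
    return float(scores.mean())


def fitness_threshold(fitnesses: list[float] | np.ndarray) -> float:
    """Population threshold: the arithmetic mean of current fitnesses."""
    arr = np.asarray(fitnesses, dtype=float)
    if arr.size == 0:
        raise ValueError("no fitnesses to threshold")
    return float(arr.mean())


def _random_mask(
    rng: np.random.Generator, n_features: int, cfg: GAConfig
) -> np.ndarray:
    n_pick = draw_nstoch(rng, n_features, cfg.stoch_lo, cfg.stoch_hi)
    mask = np.zeros(n_features, dtype=bool)
    mask[rng.choice(n_features, size=n_pick, replace=False)] = True
    return mask


def run_selection_ga(fm: FeatureMatrix, config: GAConfig) -> SelectionResult:
    """Run the feature-selection GA and return the best-ever mask.

    Per-feature scores do not depend on the mask, so they are computed once
    and a solution's fitness is just the mean score over its selected
    columns. Ties in best fitness are broken by earliest evaluation.
    """
    config.validate()
    if fm.n_classes < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(fm.y, minlength=fm.n_classes)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 records")

    rng = np.random.default_rng(config.seed)
    scores = feature_scores(fm.X, fm.y, fm.n_classes, config.epsilon)

    solutions: list[SelectionSolution | None] = [None] * config.n_solutions
    statuses = [MUTATE] * config.n_solutions
    best: SelectionSolution | None = None
    history: list[dict] = []
    n_evaluations = 0

    for iteration in range(config.n_iterations):
        for i in range(config.n_solutions):
            if statuses[i] != MUTATE:
                continue
            mask = _random_mask(rng, fm.n_features, config)
            fitness = float(scores[mask].mean())
            solutions[i] = SelectionSolution(mask=mask, fitness=fitness)
            n_evaluations += 1
            if best is None or fitness > best.fitness:
                best = SelectionSolution(mask=mask.copy(), fitness=fitness)
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
                "fitnesses": [float(f) for f in fits],
                "statuses": list(statuses),
            }
        )

    return SelectionResult(
        best_mask=best.mask,
        best_fitness=best.fitness,
        history=history,
        config=config,
        n_evaluations=n_evaluations,
        final_solutions=list(solutions),
    )


def save_mask(
    feature_names: list[str], mask: np.ndarray, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("feature_name\tselected\n")
        for name, m in zip(feature_names, mask):
            fh.write(f"{name}\t{int(m)}\n")


def load_mask(path: str | Path, feature_names: list[str]) -> np.ndarray:
    selected: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.rstrip("\n") != "feature_name\tselected":
            raise ValueError(f"{path}: unexpected header {header!r}")
        for line in fh:
            name, val = line.rstrip("\n").split("\t")
            selected[name] = int(val)
    try:
        return np.array([bool(selected[n]) for n in feature_names])
    except KeyError as exc:
        raise ValueError(f"{path}: mask is missing feature {exc}") from exc


def save_history(result: SelectionResult, path: str | Path) -> None:
    payload = {
        "best_fitness": result.best_fitness,
        "n_evaluations": result.n_evaluations,
        "config": asdict(result.config) if result.config else None,
        "history": result.history,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
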