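"""Genetic-algorithm predictor selection with cross-validated regression fitness.

A chromosome is a bit mask over candidate x-block columns; its fitness is
the root mean squared error of cross-validation (RMSECV) of an ordinary
least squares regression of the y-block on the masked columns.  Folds are
contiguous time blocks (no shuffling across time), respecting the serial
dependence of CGM data.  The GA is generational with tournament selection
(size 2), uniform crossover, per-bit mutation, and elitism; ties on fitness
break toward smaller selected sets, then lexicographically smaller masks,
so a run is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .records import DesignMatrix

RIDGE_LAMBDA = 1e-6  # fallback regularizer for rank-deficient subsets


@dataclass
class RmsecvResult:
    value: float
    ridge_folds: int = 0  # folds that needed the ridge fallback

    @property
    def used_ridge(self) -> bool:
        return self.ridge_folds > 0


def rmsecv_detail(x: np.ndarray, y: np.ndarray, folds: int,
                  seed: int = 0) -> RmsecvResult:
    """RMSECV of OLS of every y column on ``x``, contiguous time-block folds.

    Per fold, an intercept-augmented least squares fit on the remaining rows
    predicts the held-out block; squared residuals are pooled over folds and
    y columns.  Rank-deficient subsets fall back to a small fixed ridge and
    are flagged.  ``seed`` is accepted for interface stability but the
    computation is deterministic and does not use it.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and np.asarray(y).shape[0] != 1:
        x = x.T
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = x.shape[0]
    if y.shape[0] != n:
        raise DataError("x and y row counts differ")
    if folds < 2 or n < folds:
        raise ConfigError(f"need 2 <= folds <= n rows, got folds={folds}, n={n}")

    blocks = np.array_split(np.arange(n), folds)
    sq_sum = 0.0
    count = 0
    ridge_folds = 0
    A = np.column_stack([np.ones(n), x])
    p = A.shape[1]
    for held in blocks:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        At, yt = A[mask], y[mask]
        beta, _, rank, _ = np.linalg.lstsq(At, yt, rcond=None)
        if rank < p:
            ridge_folds += 1
            beta = np.linalg.solve(At.T @ At + RIDGE_LAMBDA * np.eye(p), At.T @ yt)
        resid = y[held] - A[held] @ beta
        sq_sum += float(np.sum(resid ** 2))
        count += resid.size
    return RmsecvResult(float(np.sqrt(sq_sum / count)), ridge_folds)


def rmsecv(x: np.ndarray, y: np.ndarray, folds: int, seed: int = 0) -> float:
    """Scalar RMSECV (mg/dL when y is glucose); see :func:`rmsecv_detail`."""
    return rmsecv_detail(x, y, folds, seed).value


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 40
    generations: int = 60
    crossover_rate: float = 0.8
    mutation_rate: float | None = None  # default 1 / n_candidates
    cv_folds: int = 5
    elitism_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.generations < 1:
            raise ConfigError("population_size >= 2 and generations >= 1 required")
        if not 0 <= self.crossover_rate <= 1:
            raise ConfigError("crossover_rate must lie in [0, 1]")
        if self.mutation_rate is not None and not 0 <= self.mutation_rate <= 1:
            raise ConfigError("mutation_rate must lie in [0, 1]")
        if self.cv_folds < 2 or self.elitism_count < 0:
            raise ConfigError("cv_folds >= 2 and elitism_count >= 0 required")


@dataclass
class Chromosome:
    mask: np.ndarray  # bool vector over candidates
    fitness: float = np.inf

    def key(self) -> tuple:
        return (self.fitness, int(self.mask.sum()), tuple(self.mask.tolist()))


def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(len(mask))] = True
    return mask


def select_mask(X: np.ndarray, Y: np.ndarray, config: GAConfig
                ) -> tuple[np.ndarray, dict]:
    """Run the GA over candidate columns of ``X``; returns (best mask, history).

    History holds per-generation best and mean fitness; elitism makes the
    best-fitness sequence monotone non-increasing.  A single candidate is
    returned immediately without search.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, n_var = X.shape
    if n_var < 1:
        raise DataError("no candidate variables")
    if n_var == 1:
        mask = np.array([True])
        fit = rmsecv(X, Y, config.cv_folds)
        return mask, {"best": [fit], "mean": [fit], "best_mask": mask}
    if n < 10 * config.cv_folds:
        raise DataError(
            f"need at least {10 * config.cv_folds} rows for {config.cv_folds}-fold "
            f"selection, got {n}"
        )

    rng = np.random.default_rng(config.seed)
    mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_var
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = rmsecv(X[:, mask], Y, config.cv_folds)
        return cache[key]

    pop = []
    for _ in range(config.population_size):
        mask = _repair(rng.random(n_var) < 0.5, rng)
        pop.append(Chromosome(mask, fitness(mask)))

    best_history: list[float] = []
    mean_history: list[float] = []
    best_ever = min(pop, key=Chromosome.key)

    def tournament() -> Chromosome:
        i, j = rng.integers(config.population_size, size=2)
        a, b = pop[i], pop[j]
        return a if a.key() <= b.key() else b

    for _ in range(config.generations):
        pop.sort(key=Chromosome.key)
        children = [Chromosome(c.mask.copy(), c.fitness)
                    for c in pop[:config.elitism_count]]
        while len(children) < config.population_size:
            p1, p2 = tournament(), tournament()
            if rng.random() < config.crossover_rate:
                take = rng.random(n_var) < 0.5
                mask = np.where(take, p1.mask, p2.mask)
            else:
                mask = p1.mask.copy()
            flip = rng.random(n_var) < mut
            mask = _repair(np.logical_xor(mask, flip), rng)
            children.append(Chromosome(mask, fitness(mask)))
        pop = children
        gen_best = min(pop, key=Chromosome.key)
        if gen_best.key() < best_ever.key():
            best_ever = gen_best
        best_history.append(best_ever.fitness)
        mean_history.append(float(np.mean([c.fitness for c in pop])))

    assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best_history, best_history[1:]))
    return best_ever.mask.copy(), {
        "best": best_history, "mean": mean_history, "best_mask": best_ever.mask.copy(),
    }


def select_inputs(design: DesignMatrix, config: GAConfig
                  ) -> tuple[np.ndarray, dict]:
    """GA selection over the columns of a design matrix.

    Returns the boolean mask over ``design.column_names`` and the fitness
    history; ``history["selected"]`` names the chosen variables.
    """
    mask, history = select_mask(design.X.to_numpy(dtype=float),
                                design.Y.to_numpy(dtype=float), config)
    history["selected"] = [n for n, m in zip(design.column_names, mask) if m]
    return mask, history


def reduction_percent(n_before: int, n_after: int) -> float:
    """Percent reduction in the input count (131 -> 40 gives 69.47)."""
    if n_before <= 0 or n_after < 0 or n_after > n_before:
        raise ConfigError("need 0 <= n_after <= n_before with n_before > 0")
    return 100.0 * (1.0 - n_after / n_before)
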