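"""Genetic-algorithm feature selection with joint SVM hyperparameter tuning.

A chromosome carries a descriptor bit mask together with indices into log2
grids of the SVM penalty C and RBF width gamma (the mixed-string
encoding).  Its fitness is cross-validated predictive quality penalized by
descriptor count:

    fitness = q2_cv − W · N_desp

where q2_cv is the squared Pearson correlation between the ±1 labels and
the out-of-fold SVM decision values of a stratified 5-fold CV (a config
switch substitutes CV accuracy), N_desp is the number of selected
descriptors, and W (> 0, default 0.007) sets the accuracy/parsimony
trade-off.

Before the GA runs, candidate descriptors are prefiltered: constant
columns and columns with missing values are dropped, then the later member
of any pair with |Pearson r| above the threshold (default 0.95).

Operators: tournament selection (size 3), uniform crossover on the mask,
per-bit mutation at rate 1/|mask|, single-step ± mutation on the grid
indices, elitism 1.  The best fitness is therefore non-decreasing across
generations.  The GA stops on its generation budget or after a run of
stagnant generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .svm import SVMConfig, cv_decision_values

#: LibSVM-style hyperparameter grids.
C_GRID = [2.0**e for e in range(-5, 16)]
GAMMA_GRID = [2.0**e for e in range(-15, 4)]


@dataclass
class GAConfig:
    W: float = 0.007
    population_size: int = 40
    generations: int = 30
    elitism_count: int = 1
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/|mask|
    r_max: float = 0.95
    cv_folds: int = 5
    stagnation_limit: int = 10
    fitness_metric: str = "q2"  # or 'accuracy'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.W <= 0:
            raise ValueError("W must be positive")
        if self.population_size < 2:
            raise ValueError("population must hold at least 2 chromosomes")
        if not (0 <= self.crossover_rate <= 1):
            raise ValueError("crossover_rate must lie in [0, 1]")


@dataclass
class Chromosome:
    feature_mask: np.ndarray  # bool
    c_index: int
    g_index: int

    def key(self) -> tuple:
        return (self.feature_mask.tobytes(), self.c_index, self.g_index)

    @property
    def C(self) -> float:
        return C_GRID[self.c_index]

    @property
    def gamma(self) -> float:
        return GAMMA_GRID[self.g_index]


@dataclass
class SelectionResult:
    selected_features: list[str]
    C: float
    gamma: float
    best_fitness: float
    fitness_history: list[float] = field(default_factory=list)


def prefilter_features(
    X: np.ndarray, names: list[str], r_max: float = 0.95
) -> tuple[np.ndarray, list[str]]:
    """Drop constant/missing columns, then break |r| > r_max pairs.

    The scan is in column order: for every correlated pair the later column
    is removed, so the output is order-deterministic and idempotent.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] == 0:
        raise ValueError("feature matrix has no columns")
    keep = [
        j
        for j in range(X.shape[1])
        if np.isfinite(X[:, j]).all() and np.ptp(X[:, j]) > 0
    ]
    if not keep:
        raise ValueError("all columns are constant or contain missing values")
    Xk = X[:, keep]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(Xk, rowvar=False)
    corr = np.atleast_2d(corr)
    surviving: list[int] = []
    for j in range(Xk.shape[1]):
        if all(abs(corr[j, i]) <= r_max for i in surviving):
            surviving.append(j)
    cols = [keep[j] for j in surviving]
    if not cols:
        raise ValueError("correlation prefilter removed every column")
    return X[:, cols], [names[j] for j in cols]


def chromosome_fitness(q2_cv: float, n_desp: int, W: float) -> float:
    """Penalized fitness: q2 − W × descriptor count (higher is better)."""
    if n_desp < 1:
        raise ValueError("a chromosome must select at least one descriptor")
    if W <= 0:
        raise ValueError("W must be positive")
    return q2_cv - W * n_desp


def _cv_quality(
    X: np.ndarray, y: np.ndarray, chrom: Chromosome, config: GAConfig
) -> float:
    cols = np.flatnonzero(chrom.feature_mask)
    Xm = X[:, cols]
    svm_cfg = SVMConfig(
        C=chrom.C, gamma=chrom.gamma, cv_folds=config.cv_folds, seed=config.seed
    )
    g = cv_decision_values(Xm, y, svm_cfg)
    if config.fitness_metric == "accuracy":
        return float((np.sign(g) == y).mean())
    if np.ptp(g) == 0:
        return 0.0
    r = np.corrcoef(y.astype(float), g)[0, 1]
    return 0.0 if not np.isfinite(r) else float(r**2)


def _random_chromosome(n_feat: int, rng: np.random.Generator) -> Chromosome:
    mask = rng.random(n_feat) < 0.5
    if not mask.any():
        mask[rng.integers(n_feat)] = True
    return Chromosome(
        feature_mask=mask,
        c_index=int(rng.integers(len(C_GRID))),
        g_index=int(rng.integers(len(GAMMA_GRID))),
    )


def _mutate(chrom: Chromosome, rate: float, rng: np.random.Generator) -> Chromosome:
    mask = chrom.feature_mask.copy()
    flips = rng.random(mask.size) < rate
    mask ^= flips
    if not mask.any():
        mask[rng.integers(mask.size)] = True
    ci, gi = chrom.c_index, chrom.g_index
    if rng.random() < 0.2:
        ci = int(np.clip(ci + rng.choice([-1, 1]), 0, len(C_GRID) - 1))
    if rng.random() < 0.2:
        gi = int(np.clip(gi + rng.choice([-1, 1]), 0, len(GAMMA_GRID) - 1))
    return Chromosome(feature_mask=mask, c_index=ci, g_index=gi)


def _crossover(
    a: Chromosome, b: Chromosome, rng: np.random.Generator
) -> Chromosome:
    pick = rng.random(a.feature_mask.size) < 0.5
    mask = np.where(pick, a.feature_mask, b.feature_mask)
    if not mask.any():
        mask[rng.integers(mask.size)] = True
    return Chromosome(
        feature_mask=mask,
        c_index=a.c_index if rng.random() < 0.5 else b.c_index,
        g_index=a.g_index if rng.random() < 0.5 else b.g_index,
    )


def run_ga(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    config: GAConfig | None = None,
    log: callable = None,
) -> SelectionResult:
    """Evolve descriptor masks and (C, gamma) against CV fitness.

    ``X`` must already be prefiltered.  Returns the best-ever chromosome
    decoded into feature names and grid values; ``fitness_history`` holds
    the per-generation best and is non-decreasing under elitism.
    """
    config = config or GAConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("dataset contains a single class")
    n_feat = X.shape[1]
    rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_feat
    rng = np.random.default_rng(config.seed)
    cache: dict[tuple, float] = {}

    def fitness(ch: Chromosome) -> float:
        k = ch.key()
        if k not in cache:
            q = _cv_quality(X, y, ch, config)
            cache[k] = chromosome_fitness(q, int(ch.feature_mask.sum()), config.W)
        return cache[k]

    population = [_random_chromosome(n_feat, rng) for _ in range(config.population_size)]
    scores = [fitness(c) for c in population]
    best_idx = int(np.argmax(scores))
    best, best_fit = population[best_idx], scores[best_idx]
    history: list[float] = []
    stagnant = 0

    for gen in range(config.generations):
        order = np.argsort(scores)[::-1]
        elites = [population[i] for i in order[: config.elitism_count]]
        children = list(elites)
        while len(children) < config.population_size:
            # tournament of 3
            ia = min(rng.integers(config.population_size, size=3).tolist(),
                     key=lambda i: -scores[i])
            ib = min(rng.integers(config.population_size, size=3).tolist(),
                     key=lambda i: -scores[i])
            child = (
                _crossover(population[ia], population[ib], rng)
                if rng.random() < config.crossover_rate
                else Chromosome(
                    feature_mask=population[ia].feature_mask.copy(),
                    c_index=population[ia].c_index,
                    g_index=population[ia].g_index,
                )
            )
            children.append(_mutate(child, rate, rng))
        population = children
        scores = [fitness(c) for c in population]
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_fit:
            best, best_fit = population[gen_best], scores[gen_best]
            stagnant = 0
        else:
            stagnant += 1
        history.append(best_fit)
        if log is not None:
            log(gen, best_fit, int(best.feature_mask.sum()))
        if stagnant >= config.stagnation_limit:
            break

    selected = [feature_names[j] for j in np.flatnonzero(best.feature_mask)]
    return SelectionResult(
        selected_features=selected,
        C=best.C,
        gamma=best.gamma,
        best_fitness=best_fit,
        fitness_history=history,
    )
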