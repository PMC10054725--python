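"""Variable subset selection and the outlier-removal / recalibration workflow.

Model building proceeds the way MLR-QSAR suites do it: an exhaustive
all-subset search where combinatorially feasible, otherwise a seeded
generational genetic algorithm over fixed-size descriptor subsets
(tournament selection, uniform crossover, per-gene mutation, elitism) with
leave-one-out Q2 as the default fitness.  The workflow helpers flag
chemicals that recur as outliers across the top models and recalibrate a
chosen model on pooled training + prediction data.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .appdomain import OUTLIER_SD, leverage_cutoff
from .models import LinearModel, MLRModel
from .validation import RankDeficiencyError, basic_stats, fit_ols, press_loo, q2_lmo

logger = logging.getLogger(__name__)


@dataclass
class GAConfig:
    model_size: int = 7
    population: int = 100
    generations: int = 500
    mutation_rate: float = 0.2
    elitism: int = 2
    tournament: int = 3
    fitness: str = "Q2LOO"  # or "R2", "Q2LMO"
    seed: int = 0

    def __post_init__(self):
        if self.model_size < 1:
            raise ValueError("model_size must be >= 1")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not 0 < self.mutation_rate < 1:
            raise ValueError("mutation_rate must be in (0, 1)")
        if self.fitness not in {"Q2LOO", "R2", "Q2LMO"}:
            raise ValueError(f"unknown fitness {self.fitness!r}")


@dataclass(frozen=True)
class ModelEntry:
    subset: tuple[str, ...]
    fitness: float


@dataclass
class ModelPopulation:
    """Ranked (descending fitness) collection of candidate descriptor subsets."""

    entries: list[ModelEntry] = field(default_factory=list)

    def __post_init__(self):
        self.entries.sort(key=lambda e: -e.fitness)

    def __len__(self):
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def best(self) -> ModelEntry:
        return self.entries[0]

    def top(self, k: int) -> list[ModelEntry]:
        return self.entries[:k]

    def descriptor_frequencies(self, top_k: int | None = None) -> dict[str, int]:
        freq: dict[str, int] = {}
        for e in self.top(top_k) if top_k else self.entries:
            for name in e.subset:
                freq[name] = freq.get(name, 0) + 1
        return dict(sorted(freq.items(), key=lambda kv: -kv[1]))


def _make_fitness(pool: pd.DataFrame, y: np.ndarray, kind: str, seed: int = 0):
    """Fitness of a descriptor-name subset; -inf for degenerate designs."""
    y = np.asarray(y, dtype=float)
    tss = float(np.sum((y - y.mean()) ** 2))
    cache: dict[tuple[str, ...], float] = {}

    def fitness(subset: tuple[str, ...]) -> float:
        if subset in cache:
            return cache[subset]
        X = pool[list(subset)].to_numpy(dtype=float)
        try:
            if kind == "Q2LMO":
                val = q2_lmo(X, y, seed=seed, iterations=100)
            else:
                fit = fit_ols(X, y)
                if kind == "R2":
                    val = fit.r2
                else:  # Q2LOO
                    val = 1.0 - press_loo(fit) / tss
        except (RankDeficiencyError, ValueError, np.linalg.LinAlgError) as exc:
            logger.debug("subset %s discarded: %s", subset, exc)
            val = -math.inf
        if not math.isfinite(val):
            val = -math.inf
        cache[subset] = val
        return val

    return fitness


def all_subset_search(
    pool: pd.DataFrame, y, max_size: int, fitness: str = "Q2LOO", budget: int = 200_000
) -> ModelPopulation:
    """Exhaustively evaluate every descriptor subset of size 1..max_size.

    Guarded by ``budget`` on the number of subsets; beyond it, use
    :func:`ga_vss` instead.
    """
    names = list(pool.columns)
    if len(names) < max_size:
        raise ValueError("pool has fewer descriptors than max_size")
    total = sum(math.comb(len(names), k) for k in range(1, max_size + 1))
    if total > budget:
        raise ValueError(
            f"{total} subsets exceed the all-subset budget ({budget}); "
            "use the genetic algorithm (ga_vss) instead"
        )
    fit_fn = _make_fitness(pool, np.asarray(y, float), fitness)
    entries = []
    for k in range(1, max_size + 1):
        for combo in itertools.combinations(names, k):
            val = fit_fn(combo)
            if math.isfinite(val):
                entries.append(ModelEntry(subset=combo, fitness=val))
    return ModelPopulation(entries=entries)


def ga_vss(pool: pd.DataFrame, y, cfg: GAConfig | None = None,
           initial: list[tuple[str, ...]] | None = None) -> ModelPopulation:
    """Genetic-algorithm variable subset selection over fixed-size subsets.

    Seeded and fully reproducible: tournament selection, uniform crossover
    (child genes drawn from the union of the parents), per-gene mutation to
    a random unused descriptor, and elitism.  Subsets whose OLS fit is
    degenerate get -inf fitness and die out.  ``initial`` can preload
    known-good subsets (elitism then guarantees they are never lost).
    """
    cfg = cfg or GAConfig()
    names = list(pool.columns)
    if len(names) <= cfg.model_size:
        raise ValueError("pool must contain more descriptors than model_size")
    rng = np.random.default_rng(cfg.seed)
    fit_fn = _make_fitness(pool, np.asarray(y, float), cfg.fitness, seed=cfg.seed)

    def random_subset() -> tuple[str, ...]:
        return tuple(sorted(rng.choice(names, size=cfg.model_size, replace=False)))

    population: list[tuple[str, ...]] = []
    if initial:
        population.extend(tuple(sorted(s)) for s in initial)
    while len(population) < cfg.population:
        population.append(random_subset())
    scores = [fit_fn(s) for s in population]

    for _gen in range(cfg.generations):
        order = np.argsort(scores)[::-1]
        new_pop = [population[i] for i in order[: cfg.elitism]]
        while len(new_pop) < cfg.population:
            parents = []
            for _ in range(2):
                idx = rng.integers(0, cfg.population, size=cfg.tournament)
                best = max(idx, key=lambda i: scores[i])
                parents.append(population[best])
            gene_pool = sorted(set(parents[0]) | set(parents[1]))  # stable order
            child = list(rng.choice(gene_pool, size=cfg.model_size, replace=False))
            for pos in range(cfg.model_size):
                if rng.random() < cfg.mutation_rate:
                    unused = [n for n in names if n not in child]
                    child[pos] = unused[rng.integers(0, len(unused))]
            new_pop.append(tuple(sorted(set(child))) if len(set(child)) == cfg.model_size
                           else random_subset())
        population = new_pop
        scores = [fit_fn(s) for s in population]

    uniq = {}
    for s, v in zip(population, scores):
        if math.isfinite(v):
            uniq[s] = v
    entries = [ModelEntry(subset=s, fitness=v) for s, v in uniq.items()]
    return ModelPopulation(entries=entries)


class GASubsetSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector backed by :func:`ga_vss`.

    ``fit(X, y)`` runs the GA on a DataFrame descriptor pool and exposes
    the winning subset through ``get_support()`` / ``transform``.
    """

    def __init__(self, model_size: int = 7, population: int = 100, generations: int = 500,
                 mutation_rate: float = 0.2, fitness: str = "Q2LOO", seed: int = 0):
        self.model_size = model_size
        self.population = population
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.fitness = fitness
        self.seed = seed

    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        cfg = GAConfig(
            model_size=self.model_size, population=self.population,
            generations=self.generations, mutation_rate=self.mutation_rate,
            fitness=self.fitness, seed=self.seed,
        )
        self.population_ = ga_vss(X, y, cfg)
        self.best_names_ = list(self.population_.best.subset)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.support_ = np.isin(self.feature_names_in_, self.best_names_)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def detect_recurrent_outliers(
    pop: ModelPopulation, pool: pd.DataFrame, y, top_k: int = 10, majority: float = 0.5
) -> list[dict]:
    """Chemicals repeatedly mispredicted or structurally out of domain.

    For each of the ``top_k`` best subsets, an OLS model is fitted and
    every record is checked for |standardized residual| > 2.5 or leverage
    > h*; records flagged in more than ``majority`` of the models are
    returned with per-model evidence.
    """
    if top_k > len(pop):
        raise ValueError("top_k exceeds population size")
    y = np.asarray(y, dtype=float)
    hits: dict[int, list[dict]] = {}
    models = pop.top(top_k)
    for rank, entry in enumerate(models):
        X = pool[list(entry.subset)].to_numpy(dtype=float)
        fit = fit_ols(X, y)
        std_res = fit.residuals / fit.s
        h_star = leverage_cutoff(fit.n, len(entry.subset))
        for i in range(fit.n):
            outlier = abs(std_res[i]) > OUTLIER_SD
            high_h = fit.hat_diag[i] > h_star
            if outlier or high_h:
                hits.setdefault(i, []).append(
                    {
                        "model_rank": rank,
                        "subset": entry.subset,
                        "std_residual": float(std_res[i]),
                        "leverage": float(fit.hat_diag[i]),
                        "response_outlier": bool(outlier),
                        "high_leverage": bool(high_h),
                    }
                )
    out = []
    for i, evidence in sorted(hits.items(), key=lambda kv: -len(kv[1])):
        if len(evidence) > majority * len(models):
            out.append(
                {
                    "index": i,
                    "id": pool.index[i] if pool.index is not None else i,
                    "n_models_flagged": len(evidence),
                    "evidence": evidence,
                }
            )
    return out


def recalibrate(model: LinearModel, pool: pd.DataFrame, y) -> LinearModel:
    """Refit a model's descriptor set by OLS on new (e.g. pooled) data.

    This is the split-model -> full-model step: the descriptor subset is
    kept, coefficients and standard errors are re-estimated.
    """
    est = MLRModel(descriptor_names=model.descriptor_names).fit(pool, np.asarray(y, float))
    lm = est.model_
    return LinearModel(
        model_id=f"{model.model_id}-recalibrated",
        intercept=lm.intercept,
        intercept_se=lm.intercept_se,
        terms=lm.terms,
        training_n=lm.training_n,
        endpoint=model.endpoint,
    )


def fit_subset(pool: pd.DataFrame, y, subset: tuple[str, ...]) -> dict:
    """Convenience: OLS fit + fit statistics for one descriptor subset."""
    X = pool[list(subset)].to_numpy(dtype=float)
    fit = fit_ols(X, y)
    r2, rmse, mae = basic_stats(y, fit.fitted)
    return {"fit": fit, "R2": r2, "RMSE_tr": rmse, "MAE_tr": mae}
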