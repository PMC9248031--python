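"""Indicator-based evolutionary optimisation of neuron-model parameters.

The loop is an elitist mu+lambda scheme: an initial population is scored
once; each generation produces lambda offspring — every offspring made by
exactly one of bounded simulated-binary crossover, bounded polynomial
mutation, or plain copying — scores them, pools parents with offspring, and
keeps the mu survivors of indicator-based (IBEA) environmental selection.
A hall of fame tracks the 10 lowest-total-score individuals ever seen and
has no influence on the evolution; the returned model is its argmin.

IBEA follows the additive-epsilon scheme of Zitzler & Kuenzli: objectives
are min-max normalised per component, the pairwise indicator is
``I(i, j) = max_k (o_i[k] - o_j[k])``, and each individual's fitness is the
sum of ``-exp(-I(i, j) / (c * kappa))`` over all rivals, with ``c`` the
largest indicator magnitude.  Environmental selection removes the
worst-fitness individual and adds its exponential terms back to the
survivors until mu remain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .efeatures import FeatureSet
from .errors import ConfigurationError
from .model import Individual, ParameterSpec, Population
from .rng import named_stream
from .scoring import SimulationParams, TargetFeatureTable, evaluate, total_score
from .stimuli import StimulusSuite

__all__ = [
    "EAConfig",
    "Problem",
    "HallOfFame",
    "HofEntry",
    "GenerationStats",
    "initialize",
    "variation",
    "ibea_fitness",
    "environmental_select",
    "optimize",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EAConfig:
    """Evolution settings.

    ``mu`` parents survive each generation and ``lambda_`` offspring are
    produced; the initial population has ``lambda_`` members.  ``cx_rate``
    and ``mut_rate`` are the exclusive-branch probabilities of crossover and
    mutation (the remainder is plain reproduction), ``kappa`` the IBEA
    fitness scaling, ``eta_cx`` / ``eta_mut`` the distribution indices of
    the bounded variation operators.
    """

    mu: int
    lambda_: int
    n_generations: int
    seed: int = 0
    cx_rate: float = 0.3
    mut_rate: float = 0.5
    hof_size: int = 10
    kappa: float = 0.05
    eta_cx: float = 10.0
    eta_mut: float = 20.0

    def __post_init__(self):
        if self.mu < 1 or self.lambda_ < 1:
            raise ConfigurationError("mu and lambda must be >= 1")
        if self.n_generations < 1:
            raise ConfigurationError("n_generations must be >= 1")
        if not (0 <= self.cx_rate <= 1 and 0 <= self.mut_rate <= 1):
            raise ConfigurationError("rates must lie in [0, 1]")
        if self.cx_rate + self.mut_rate > 1:
            raise ConfigurationError(
                "cx_rate + mut_rate must be <= 1 (the remainder is the "
                "reproduction probability)"
            )
        if self.kappa <= 0:
            raise ConfigurationError("kappa must be positive")


@dataclass
class Problem:
    """A complete fitting problem: search space, stimuli, targets, scorer."""

    spec: ParameterSpec
    suite: StimulusSuite
    targets: TargetFeatureTable
    feature_set: FeatureSet
    sim_params: SimulationParams


# ---------------------------------------------------------------------------
# Initialisation and variation
# ---------------------------------------------------------------------------

def initialize(spec: ParameterSpec, n: int, rng) -> Population:
    """``n`` individuals i.i.d. uniform within the spec bounds."""
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    lo, hi = spec.lower, spec.upper
    values = rng.uniform(lo, hi, size=(n, spec.count))
    return Population([Individual(v) for v in values])


def _sbx_crossover(x1, x2, lo, hi, eta, rng):
    """Bounded simulated-binary crossover; returns one child.

    Per gene (with probability 0.5) two complementary children are drawn
    around the parents and randomly swapped, the standard bounded-SBX
    construction; the first child is returned.
    """
    c1 = x1.copy()
    c2 = x2.copy()
    for i in range(len(x1)):
        if rng.random() > 0.5 or abs(x1[i] - x2[i]) < 1e-14:
            continue
        xs, xl_ = sorted((x1[i], x2[i]))
        xl, xu = lo[i], hi[i]
        rand = rng.random()
        # child biased toward the lower parent
        beta = 1.0 + 2.0 * (xs - xl) / (xl_ - xs)
        alpha = 2.0 - beta ** -(eta + 1.0)
        if rand <= 1.0 / alpha:
            beta_q = (rand * alpha) ** (1.0 / (eta + 1.0))
        else:
            beta_q = (1.0 / (2.0 - rand * alpha)) ** (1.0 / (eta + 1.0))
        lo_child = 0.5 * ((xs + xl_) - beta_q * (xl_ - xs))
        # child biased toward the upper parent
        beta = 1.0 + 2.0 * (xu - xl_) / (xl_ - xs)
        alpha = 2.0 - beta ** -(eta + 1.0)
        if rand <= 1.0 / alpha:
            beta_q = (rand * alpha) ** (1.0 / (eta + 1.0))
        else:
            beta_q = (1.0 / (2.0 - rand * alpha)) ** (1.0 / (eta + 1.0))
        hi_child = 0.5 * ((xs + xl_) + beta_q * (xl_ - xs))
        lo_child = min(max(lo_child, xl), xu)
        hi_child = min(max(hi_child, xl), xu)
        if rng.random() <= 0.5:
            c1[i], c2[i] = hi_child, lo_child
        else:
            c1[i], c2[i] = lo_child, hi_child
    return c1


def _polynomial_mutation(x, lo, hi, eta, indpb, rng):
    """Bounded polynomial mutation with per-gene probability ``indpb``."""
    y = x.copy()
    for i in range(len(x)):
        if rng.random() >= indpb:
            continue
        xl, xu = lo[i], hi[i]
        delta_1 = (y[i] - xl) / (xu - xl)
        delta_2 = (xu - y[i]) / (xu - xl)
        rand = rng.random()
        mut_pow = 1.0 / (eta + 1.0)
        if rand < 0.5:
            val = 2.0 * rand + (1.0 - 2.0 * rand) * (1.0 - delta_1) ** (eta + 1.0)
            delta_q = val ** mut_pow - 1.0
        else:
            val = (2.0 * (1.0 - rand)
                   + 2.0 * (rand - 0.5) * (1.0 - delta_2) ** (eta + 1.0))
            delta_q = 1.0 - val ** mut_pow
        y[i] = min(max(y[i] + delta_q * (xu - xl), xl), xu)
    return y


def variation(parents: Population, lambda_: int, cx_rate: float,
              mut_rate: float, rng, spec: ParameterSpec,
              eta_cx: float = 10.0, eta_mut: float = 20.0) -> Population:
    """Produce exactly ``lambda_`` offspring.

    Each offspring is made by exactly one branch: crossover with probability
    ``cx_rate``, mutation with ``mut_rate``, otherwise a plain copy of a
    sampled parent.  Offspring always respect the bounds and carry no
    scores.
    """
    if cx_rate + mut_rate > 1:
        raise ConfigurationError("cx_rate + mut_rate must be <= 1")
    if cx_rate > 0 and len(parents) < 2:
        raise ConfigurationError("crossover needs at least two parents")
    lo, hi = spec.lower, spec.upper
    indpb = 1.0 / spec.count
    out = []
    n = len(parents)
    for _ in range(lambda_):
        u = rng.random()
        if u < cx_rate:
            i = int(rng.integers(n))
            j = int(rng.integers(n - 1))
            if j >= i:
                j += 1
            child = _sbx_crossover(parents[i].values, parents[j].values,
                                   lo, hi, eta_cx, rng)
        elif u < cx_rate + mut_rate:
            i = int(rng.integers(n))
            child = _polynomial_mutation(parents[i].values, lo, hi,
                                         eta_mut, indpb, rng)
        else:
            child = parents[int(rng.integers(n))].values.copy()
        out.append(Individual(child))
    return Population(out)


# ---------------------------------------------------------------------------
# IBEA fitness and environmental selection
# ---------------------------------------------------------------------------

def _indicator_matrix(objectives: np.ndarray):
    """Additive-epsilon indicators on min-max normalised objectives.

    Returns (I, c) where ``I[i, j] = max_k (norm_i[k] - norm_j[k])`` and
    ``c`` is the largest indicator magnitude (1 if all comparisons tie).
    """
    obj = np.asarray(objectives, dtype=float)
    lo = obj.min(axis=0)
    span = obj.max(axis=0) - lo
    norm = np.zeros_like(obj)
    ok = span > 0
    norm[:, ok] = (obj[:, ok] - lo[ok]) / span[ok]
    ind = np.max(norm[:, None, :] - norm[None, :, :], axis=2)
    c = float(np.max(np.abs(ind)))
    if c == 0.0:
        c = 1.0
    return ind, c


def ibea_fitness(objectives: np.ndarray, kappa: float = 0.05) -> np.ndarray:
    """IBEA fitness per individual (higher is better)."""
    obj = np.asarray(objectives, dtype=float)
    if obj.shape[0] < 2:
        raise ConfigurationError("IBEA fitness needs >= 2 individuals")
    ind, c = _indicator_matrix(obj)
    expo = np.exp(-ind / (c * kappa))
    np.fill_diagonal(expo, 0.0)
    return -expo.sum(axis=0)


def environmental_select(population: Population, mu: int,
                         kappa: float = 0.05,
                         objectives: np.ndarray | None = None,
                         removal_log: list | None = None) -> Population:
    """Iteratively remove the worst-fitness individual until ``mu`` remain.

    After each removal the removed individual's exponential terms are added
    back to the survivors' fitness.  Ties are broken by insertion order;
    the survivors keep their original order and final fitness values.
    Pass a list as ``removal_log`` to record the removed indices in order.
    """
    n = len(population)
    if mu > n:
        raise ConfigurationError(f"cannot select {mu} from {n} individuals")
    if objectives is None:
        objectives = np.array([ind.scores for ind in population])
    ind_mat, c = _indicator_matrix(objectives)
    expo = np.exp(-ind_mat / (c * kappa))
    np.fill_diagonal(expo, 0.0)
    fitness = -expo.sum(axis=0)

    alive = np.ones(n, dtype=bool)
    for _ in range(n - mu):
        candidates = np.flatnonzero(alive)
        worst = candidates[int(np.argmin(fitness[candidates]))]
        alive[worst] = False
        fitness[alive] += expo[worst, alive]
        if removal_log is not None:
            removal_log.append(int(worst))

    survivors = []
    for i in np.flatnonzero(alive):
        ind = population[i]
        ind.fitness = float(fitness[i])
        survivors.append(ind)
    return Population(survivors)


# ---------------------------------------------------------------------------
# Hall of fame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HofEntry:
    total: float
    generation: int
    order: int               # insertion order within the generation
    individual: Individual


@dataclass
class HallOfFame:
    """The ``hof_size`` lowest-total-score individuals over all generations.

    Purely observational — never feeds back into selection.  Ties are
    broken by earlier generation, then insertion order; exact duplicates of
    a stored parameter vector are not re-inserted.
    """

    maxsize: int = 10
    entries: list[HofEntry] = field(default_factory=list)

    def update(self, population: Population, generation: int) -> "HallOfFame":
        for order, ind in enumerate(population):
            if ind.scores is None:
                raise ConfigurationError("hall-of-fame candidates must be scored")
            if any(np.array_equal(e.individual.values, ind.values)
                   for e in self.entries):
                continue
            self.entries.append(
                HofEntry(total_score(ind.scores), generation, order, ind.copy())
            )
        self.entries.sort(key=lambda e: (e.total, e.generation, e.order))
        del self.entries[self.maxsize:]
        return self

    @property
    def best(self) -> HofEntry:
        if not self.entries:
            raise ValueError("hall of fame is empty")
        return self.entries[0]

    def totals(self) -> list[float]:
        return [e.total for e in self.entries]

    def __len__(self):
        return len(self.entries)


# ---------------------------------------------------------------------------
# The full loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerationStats:
    generation: int
    best_total: float
    mean_total: float
    std_total: float
    evaluations: int
    hof_best: float


def _evaluate(population, problem, plan):
    if plan is None:
        return evaluate(population, problem.suite, problem.targets,
                        problem.feature_set, problem.sim_params)
    from .scheduler import pipelined_evaluate
    matrix, _ = pipelined_evaluate(population, problem.suite,
                                   problem.targets, problem.feature_set,
                                   problem.sim_params, plan)
    return matrix


def optimize(config: EAConfig, problem: Problem, plan=None,
             checkpoint_path: str | Path | None = None,
             hof: HallOfFame | None = None,
             ) -> tuple[Individual, list[GenerationStats]]:
    """Run the full evolutionary loop and return (best individual, history).

    The initial population (size lambda) is evaluated once; every later
    generation costs exactly lambda evaluations (parents keep their cached
    scores).  ``plan`` optionally routes evaluation through the
    parallel/pipelined scheduler — the scores, and hence the whole run, are
    identical to the sequential path.  Deterministic given
    ``(config, problem)``.  Pass an empty :class:`HallOfFame` as ``hof`` to
    inspect or export it afterwards.
    """
    rng_init = named_stream(config.seed, "init")
    rng_var = named_stream(config.seed, "variation")

    parents = initialize(problem.spec, config.lambda_, rng_init)
    _evaluate(parents, problem, plan)
    if hof is None:
        hof = HallOfFame(config.hof_size)
    hof.update(parents, generation=0)

    totals = np.array([total_score(ind.scores) for ind in parents])
    history = [GenerationStats(0, float(totals.min()), float(totals.mean()),
                               float(totals.std()), len(parents),
                               hof.best.total)]

    for gen in range(1, config.n_generations + 1):
        offspring = variation(parents, config.lambda_, config.cx_rate,
                              config.mut_rate, rng_var, problem.spec,
                              config.eta_cx, config.eta_mut)
        _evaluate(offspring, problem, plan)
        pool = Population(list(parents) + list(offspring))
        parents = environmental_select(pool, config.mu, config.kappa)
        hof.update(pool, generation=gen)

        totals = np.array([total_score(ind.scores) for ind in pool])
        history.append(GenerationStats(gen, float(totals.min()),
                                       float(totals.mean()),
                                       float(totals.std()),
                                       config.lambda_, hof.best.total))
        if checkpoint_path is not None:
            _save_checkpoint(checkpoint_path, gen, rng_var, parents, hof,
                             history)

    best = hof.best.individual
    return best, history


def _save_checkpoint(path, generation, rng_var, parents, hof, history):
    data = {
        "generation": generation,
        "rng_variation_state": rng_var.bit_generator.state,
        "parents": [{"values": ind.values.tolist(),
                     "scores": ind.scores.tolist()} for ind in parents],
        "hof": [{"total": e.total, "generation": e.generation,
                 "order": e.order,
                 "values": e.individual.values.tolist(),
                 "scores": e.individual.scores.tolist()}
                for e in hof.entries],
        "history": [vars(h) if not hasattr(h, "__dataclass_fields__")
                    else {k: getattr(h, k) for k in h.__dataclass_fields__}
                    for h in history],
    }
    Path(path).write_text(json.dumps(data))


def load_checkpoint(path) -> dict:
    """Read a checkpoint written during :func:`optimize`."""
    return json.loads(Path(path).read_text())


def resume(config: EAConfig, problem: Problem,
           checkpoint_path: str | Path, plan=None,
           ) -> tuple[Individual, list[GenerationStats]]:
    """Continue an interrupted run from its checkpoint file.

    Restores the variation RNG state, parents (with cached scores), hall of
    fame and history, then runs the remaining generations; the result is
    identical to an uninterrupted run.
    """
    data = load_checkpoint(checkpoint_path)
    rng_var = named_stream(config.seed, "variation")
    rng_var.bit_generator.state = data["rng_variation_state"]
    parents = Population([
        Individual(np.array(p["values"]), np.array(p["scores"]))
        for p in data["parents"]
    ])
    hof = HallOfFame(config.hof_size)
    hof.entries = [
        HofEntry(e["total"], e["generation"], e["order"],
                 Individual(np.array(e["values"]), np.array(e["scores"])))
        for e in data["hof"]
    ]
    history = [GenerationStats(**h) for h in data["history"]]

    for gen in range(data["generation"] + 1, config.n_generations + 1):
        offspring = variation(parents, config.lambda_, config.cx_rate,
                              config.mut_rate, rng_var, problem.spec,
                              config.eta_cx, config.eta_mut)
        _evaluate(offspring, problem, plan)
        pool = Population(list(parents) + list(offspring))
        parents = environmental_select(pool, config.mu, config.kappa)
        hof.update(pool, generation=gen)
        totals = np.array([total_score(ind.scores) for ind in pool])
        history.append(GenerationStats(gen, float(totals.min()),
                                       float(totals.mean()),
                                       float(totals.std()),
                                       config.lambda_, hof.best.total))
        if checkpoint_path is not None:
            _save_checkpoint(checkpoint_path, gen, rng_var, parents, hof,
                             history)
    return hof.best.individual, history
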