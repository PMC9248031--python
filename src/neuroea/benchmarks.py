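"""Scaling benchmark harness for the simulate-evaluate loop.

Five designs are supported, all desk-scale emulations of classic HPC
benchmarks:

* ``compute_fixed_problem_scales`` — worker allocation fixed, population
  grows (500 ... 5000 in steps of 500 in the full design);
* ``strong_scaling`` — population fixed (3000), partitions double
  (1, 2, 4, 8, 16);
* ``weak_scaling`` — 250 individuals per partition, partitions double;
* ``stimuli_scaling`` — S grows 1 ... 18 at N = 500, F = 20;
* ``scorefn_scaling`` — F grows 1 ... 180 at N = 500, S = 8.

Each trial times ``n_repeats`` simulate-evaluate steps on a fixed seeded
population after one discarded warm-up step, and records the mean and
standard deviation of the wall time together with the exact work done
(N*S*F scored objectives per step).  Timing numbers characterise the host
they ran on and are never comparison targets.

:func:`classify_scaling` fits the measured curve against constant,
logarithmic, linear and power-law shapes and reports the best-supported
one.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit
from scipy.stats import f as f_dist

from .errors import ConfigurationError
from .efeatures import FeatureSet
from .evolution import Problem, initialize
from .rng import named_stream
from .scheduler import ExecutionPlan, pipelined_evaluate, plan_batches

__all__ = [
    "BenchmarkTrial",
    "BenchmarkPlan",
    "BenchmarkResult",
    "TrialResult",
    "BENCHMARK_KINDS",
    "WEAK_SCALING_PER_PARTITION",
    "make_plan",
    "run_benchmark",
    "classify_scaling",
]

BENCHMARK_KINDS = ("compute_fixed_problem_scales", "strong_scaling",
                   "weak_scaling", "stimuli_scaling", "scorefn_scaling")
WEAK_SCALING_PER_PARTITION = 250


@dataclass(frozen=True)
class BenchmarkTrial:
    n: int                      # population size
    plan: ExecutionPlan
    s: int                      # number of stimuli
    f: int                      # number of score functions


@dataclass(frozen=True)
class BenchmarkPlan:
    kind: str
    trials: tuple[BenchmarkTrial, ...]
    n_repeats: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in BENCHMARK_KINDS:
            raise ConfigurationError(f"unknown benchmark kind {self.kind!r}")
        object.__setattr__(self, "trials", tuple(self.trials))
        ns = [t.n for t in self.trials]
        if self.kind == "strong_scaling" and len(set(ns)) > 1:
            raise ConfigurationError(
                "strong scaling requires a constant population size"
            )
        if self.kind == "weak_scaling":
            ratios = {t.n / t.plan.n_partitions for t in self.trials}
            if len(ratios) > 1:
                raise ConfigurationError(
                    "weak scaling requires a constant N / n_partitions ratio"
                )
        if self.kind == "compute_fixed_problem_scales":
            if len({t.plan for t in self.trials}) > 1:
                raise ConfigurationError(
                    "compute-fixed scaling requires a constant execution plan"
                )


@dataclass(frozen=True)
class TrialResult:
    trial: BenchmarkTrial
    mean_s: float
    std_s: float
    times_s: tuple[float, ...]
    evaluations: int            # N * S * F per step
    batches: int                # simulate batches per step


@dataclass
class BenchmarkResult:
    kind: str
    trials: list[TrialResult] = field(default_factory=list)


def make_plan(kind: str, *, base: dict | None = None,
              scale_steps=None, n_repeats: int = 5,
              seed: int = 0) -> BenchmarkPlan:
    """Build the trial grid for one benchmark design.

    Defaults reproduce the full designs; pass ``scale_steps`` (population
    sizes, partition counts, stimulus counts or score-function counts,
    depending on the kind) and ``base`` overrides (``n``, ``s``, ``f``,
    ``n_sim_workers``, ``n_eval_workers``, ``pipelined``,
    ``per_partition``) to shrink them to desk scale.
    """
    if kind not in BENCHMARK_KINDS:
        raise ConfigurationError(f"unknown benchmark kind {kind!r}")
    base = dict(base or {})
    nsw = int(base.get("n_sim_workers", 8))
    new = int(base.get("n_eval_workers", 4))
    pipelined = bool(base.get("pipelined", True))

    def plan(n_partitions=1):
        return ExecutionPlan(nsw, new, int(n_partitions), pipelined)

    s = int(base.get("s", 8))
    f = int(base.get("f", 20))
    trials = []
    if kind == "compute_fixed_problem_scales":
        steps = scale_steps if scale_steps is not None else range(500, 5001, 500)
        trials = [BenchmarkTrial(int(n), plan(), s, f) for n in steps]
    elif kind == "strong_scaling":
        n = int(base.get("n", 3000))
        steps = scale_steps if scale_steps is not None else (1, 2, 4, 8, 16)
        trials = [BenchmarkTrial(n, plan(p), s, f) for p in steps]
    elif kind == "weak_scaling":
        per = int(base.get("per_partition", WEAK_SCALING_PER_PARTITION))
        steps = scale_steps if scale_steps is not None else (1, 2, 4, 8, 16)
        trials = [BenchmarkTrial(per * int(p), plan(p), s, f) for p in steps]
    elif kind == "stimuli_scaling":
        n = int(base.get("n", 500))
        steps = scale_steps if scale_steps is not None else range(1, 19)
        trials = [BenchmarkTrial(n, plan(), int(si), f) for si in steps]
    else:  # scorefn_scaling
        n = int(base.get("n", 500))
        steps = (scale_steps if scale_steps is not None
                 else (1, *range(20, 181, 20)))
        trials = [BenchmarkTrial(n, plan(), s, int(fi)) for fi in steps]
    return BenchmarkPlan(kind, tuple(trials), n_repeats=n_repeats, seed=seed)


def _feature_subset(f: int, base_names) -> FeatureSet:
    """A feature list of length ``f``, cycling ``base_names`` when ``f``
    exceeds it (repeated score functions are genuine repeated work)."""
    base_names = tuple(base_names)
    names = [base_names[i % len(base_names)] for i in range(f)]
    return FeatureSet(tuple(names))


def run_benchmark(plan: BenchmarkPlan, problem: Problem) -> BenchmarkResult:
    """Time simulate-evaluate steps for every trial of ``plan``.

    ``problem`` supplies the model, stimulus suite and targets; each trial
    uses the first ``s`` stimuli of the suite and a feature list of length
    ``f``.  The population is drawn once per trial from the same seed (so
    trial populations of equal N are identical), one warm-up step is
    discarded, and ``n_repeats`` steps are timed with a monotonic clock
    around the simulate-evaluate call only.
    """
    result = BenchmarkResult(plan.kind)
    for trial in plan.trials:
        if trial.s > len(problem.suite):
            raise ConfigurationError(
                f"trial needs {trial.s} stimuli but the problem suite has "
                f"{len(problem.suite)}"
            )
        suite = problem.suite.take(trial.s)
        fset = _feature_subset(trial.f, problem.feature_set.names)
        problem.targets.check_covers(suite, fset)
        rng = named_stream(plan.seed, "benchmark-init")
        population = initialize(problem.spec, trial.n, rng)

        times = []
        for rep in range(plan.n_repeats + 1):   # first step is warm-up
            t0 = time.perf_counter()
            pipelined_evaluate(population, suite, problem.targets, fset,
                               problem.sim_params, trial.plan)
            elapsed = time.perf_counter() - t0
            if rep > 0:
                times.append(elapsed)
        times_arr = np.array(times)
        n_batches = (len(plan_batches(trial.s, trial.plan.n_sim_workers))
                     * min(trial.plan.n_partitions, trial.n))
        result.trials.append(TrialResult(
            trial, float(times_arr.mean()), float(times_arr.std()),
            tuple(times), trial.n * trial.s * trial.f, n_batches,
        ))
    return result


_SHAPES = ("constant", "logarithmic", "linear", "polynomial")


def classify_scaling(sizes, times) -> dict:
    """Classify a measured scaling curve.

    Fits ``t = a * g(n) + b`` for g in {1, log n, n} by least squares and a
    free-exponent power law ``t = a * n^k + b``, then picks the shape with
    the lowest AIC (simpler shapes win ties).  Returns the chosen label,
    per-shape R^2, and the fitted parameters of the winner.
    """
    sizes = np.asarray(sizes, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(sizes) < 4:
        raise ConfigurationError("need at least 4 points to classify")
    if np.any(np.diff(sizes) <= 0):
        raise ConfigurationError("sizes must be strictly increasing")
    if np.any(sizes <= 0):
        raise ConfigurationError("sizes must be positive")

    m = len(times)
    tss = float(np.sum((times - times.mean()) ** 2))
    results = {}

    def record(label, rss, n_params, params):
        r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss < 1e-30 else 0.0)
        results[label] = {"rss": rss, "p": n_params, "r2": r2,
                          "params": params}

    # constant: t = b
    b = times.mean()
    record("constant", float(np.sum((times - b) ** 2)), 1, {"b": b})

    for label, g in (("logarithmic", np.log(sizes)), ("linear", sizes)):
        a_mat = np.column_stack([g, np.ones(m)])
        coef, *_ = np.linalg.lstsq(a_mat, times, rcond=None)
        resid = times - a_mat @ coef
        record(label, float(np.sum(resid ** 2)), 2,
               {"a": float(coef[0]), "b": float(coef[1])})

    def power(n, a, k, b):
        return a * np.power(n, k) + b

    try:
        p0 = (max((times[-1] - times[0]) / max(sizes[-1] ** 2, 1e-12), 1e-9),
              2.0, float(times.min()))
        with warnings.catch_warnings():
            # degenerate (flat) inputs leave the power-law covariance
            # undefined; only the point estimate is used
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(power, sizes, times, p0=p0, maxfev=20000)
        resid = times - power(sizes, *popt)
        record("polynomial", float(np.sum(resid ** 2)), 3,
               {"a": float(popt[0]), "k": float(popt[1]), "b": float(popt[2])})
    except (RuntimeError, FloatingPointError):
        record("polynomial", float("inf"), 3, {})

    # nested-model selection: keep the extra parameter only when the RSS
    # drop is significant (partial F-test at the 1% level); a free-exponent
    # power law would otherwise win on pure noise
    def f_significant(simple, complex_, df_extra=1, alpha=0.01):
        rss_s, rss_c = results[simple]["rss"], results[complex_]["rss"]
        df_resid = m - results[complex_]["p"]
        if not np.isfinite(rss_c) or df_resid <= 0:
            return False
        if rss_c <= 0:
            return rss_s > 0
        f_stat = (rss_s - rss_c) / df_extra / (rss_c / df_resid)
        return f_stat > f_dist.ppf(1.0 - alpha, df_extra, df_resid)

    best2 = min(("logarithmic", "linear"), key=lambda s: results[s]["rss"])
    if not f_significant("constant", best2):
        best = "constant"
    elif f_significant(best2, "polynomial"):
        best = "polynomial"
    else:
        best = best2

    return {
        "shape": best,
        "r2": {lab: results[lab]["r2"] for lab in _SHAPES},
        "params": results[best]["params"],
        "rss": {lab: results[lab]["rss"] for lab in _SHAPES},
    }
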