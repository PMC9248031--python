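"""Parallel and pipelined execution of the simulate-evaluate loop.

The cluster architecture of the original method — populations scattered
across nodes, stimuli batched across per-node GPUs, feature scoring on CPU
cores — is emulated with local thread pools: ``n_partitions`` stands for
nodes, ``n_sim_workers`` for the GPUs that simulate a batch of stimuli, and
``n_eval_workers`` for the scoring cores.  With pipelining on, the
simulation of stimulus batch k+1 starts as soon as batch k's traces are
handed to the evaluators, so simulation and evaluation overlap exactly as
in the producer-consumer timeline of the original design.

Because every (individual, stimulus, feature) computation is independent
and executed in a fixed per-individual order, the resulting score matrix is
bit-identical to the sequential reference implementation for every
execution plan — scheduling changes wall time, never arithmetic.
"""

from __future__ import annotations

import threading
import time
from concurrent.futures import ThreadPoolExecutor, wait
from dataclasses import dataclass, field

import numpy as np

from .efeatures import FeatureSet, feature_vector
from .errors import ConfigurationError
from .model import Population, simulate
from .scoring import (SimulationParams, TargetFeatureTable, score_feature)
from .stimuli import StimulusSuite

__all__ = [
    "ExecutionPlan",
    "EventRecord",
    "EventLog",
    "partition_population",
    "plan_batches",
    "pipelined_evaluate",
    "makespan",
    "synthetic_timeline",
]


@dataclass(frozen=True)
class ExecutionPlan:
    """Worker counts for one simulate-evaluate pass (all stand-ins for
    hardware: no probing is done)."""

    n_sim_workers: int = 1
    n_eval_workers: int = 1
    n_partitions: int = 1
    pipelined: bool = False

    def __post_init__(self):
        if min(self.n_sim_workers, self.n_eval_workers,
               self.n_partitions) < 1:
            raise ConfigurationError("all worker counts must be >= 1")


@dataclass(frozen=True)
class EventRecord:
    kind: str          # "simulate" | "evaluate"
    batch: int         # batch index within the partition
    worker: str
    start: float       # seconds, monotonic clock
    end: float
    partition: int = 0


@dataclass
class EventLog:
    records: list[EventRecord] = field(default_factory=list)
    _lock: threading.Lock = field(default_factory=threading.Lock,
                                  repr=False)

    def add(self, record: EventRecord):
        with self._lock:
            self.records.append(record)

    def of_kind(self, kind: str) -> list[EventRecord]:
        return [r for r in self.records if r.kind == kind]

    def __len__(self):
        return len(self.records)

    def is_serial(self) -> bool:
        """True when no two records overlap in time at all."""
        recs = sorted(self.records, key=lambda r: r.start)
        return all(a.end <= b.start + 1e-9
                   for a, b in zip(recs[:-1], recs[1:]))


def partition_population(population: Population,
                         n_partitions: int) -> list[Population]:
    """Contiguous near-equal parts (sizes differ by <= 1); concatenating
    them restores the original order.  Empty parts are dropped."""
    if n_partitions < 1:
        raise ConfigurationError("n_partitions must be >= 1")
    n = len(population)
    base, extra = divmod(n, n_partitions)
    parts = []
    start = 0
    for p in range(n_partitions):
        size = base + (1 if p < extra else 0)
        if size == 0:
            continue
        parts.append(Population(list(population)[start:start + size]))
        start += size
    return parts


def plan_batches(s: int, n_sim_workers: int) -> list[list[int]]:
    """Stimulus indices grouped into ceil(S / workers) batches, order
    preserved, each batch at most ``n_sim_workers`` wide."""
    if s < 1:
        raise ConfigurationError("need at least one stimulus")
    if n_sim_workers < 1:
        raise ConfigurationError("n_sim_workers must be >= 1")
    return [list(range(i, min(i + n_sim_workers, s)))
            for i in range(0, s, n_sim_workers)]


def makespan(log: EventLog) -> float:
    """Span (max end - min start) of a non-empty event log."""
    if not log.records:
        raise ConfigurationError("event log is empty")
    return (max(r.end for r in log.records)
            - min(r.start for r in log.records))


def pipelined_evaluate(offspring: Population, suite: StimulusSuite,
                       targets: TargetFeatureTable, feature_set: FeatureSet,
                       params: SimulationParams, plan: ExecutionPlan,
                       sim_hook=None, eval_hook=None,
                       ) -> tuple[np.ndarray, EventLog]:
    """Score a population under an execution plan.

    Returns the N x (S*F) score matrix — element-wise identical to
    :func:`neuroea.scoring.evaluate` — and the event log of simulate /
    evaluate tasks (one record per stimulus batch per partition).

    ``sim_hook`` / ``eval_hook`` are test instrumentation called inside
    each task with (partition, batch); they may sleep (to shape the
    timeline) or raise (to emulate a worker crash, which scores the
    affected individuals' rows at ``max_score`` without aborting the run).
    """
    targets.check_covers(suite, feature_set)
    stims = list(suite)
    n = len(offspring)
    f = len(feature_set)
    matrix = np.empty((n, len(stims) * f))
    log_ = EventLog()

    parts = partition_population(offspring, plan.n_partitions)
    offsets = np.cumsum([0] + [len(p) for p in parts[:-1]])
    batches = plan_batches(len(stims), plan.n_sim_workers)

    failed: set[int] = set()
    failed_lock = threading.Lock()
    t0 = time.perf_counter()

    def sim_task(pi, part, offset, bi, batch):
        start = time.perf_counter() - t0
        traces = {}
        try:
            if sim_hook is not None:
                sim_hook(pi, bi)
            for li in range(len(part)):
                gi = offset + li
                try:
                    for si in batch:
                        traces[(gi, si)] = simulate(
                            params.model, part[li].values, stims[si],
                            dt=params.dt, v_init=params.v_init,
                        )
                except Exception:
                    with failed_lock:
                        failed.add(gi)
        except Exception:
            # whole-task crash: every individual of the partition is lost
            with failed_lock:
                failed.update(range(offset, offset + len(part)))
        log_.add(EventRecord("simulate", bi, threading.current_thread().name,
                             start, time.perf_counter() - t0, pi))
        return traces

    def eval_task(pi, part, offset, bi, batch, traces):
        start = time.perf_counter() - t0
        try:
            if eval_hook is not None:
                eval_hook(pi, bi)
            for li in range(len(part)):
                gi = offset + li
                if gi in failed:
                    continue
                try:
                    for si in batch:
                        trace = traces[(gi, si)]
                        feats = feature_vector(trace, stims[si], feature_set,
                                               threshold=params.threshold)
                        for fi, fv in enumerate(feats):
                            key = (stims[si].id, fv.name)
                            if key in targets.skipped:
                                matrix[gi, si * f + fi] = 0.0
                            else:
                                mean, std = targets.get(*key)
                                matrix[gi, si * f + fi] = score_feature(
                                    fv, mean, std, params.max_score)
                except Exception:
                    with failed_lock:
                        failed.add(gi)
        except Exception:
            with failed_lock:
                failed.update(range(offset, offset + len(part)))
        log_.add(EventRecord("evaluate", bi, threading.current_thread().name,
                             start, time.perf_counter() - t0, pi))

    sim_pool = ThreadPoolExecutor(plan.n_sim_workers,
                                  thread_name_prefix="sim")
    eval_pool = ThreadPoolExecutor(plan.n_eval_workers,
                                   thread_name_prefix="eval")
    eval_futures = []

    def run_partition(pi, part, offset):
        prev_eval = None
        for bi, batch in enumerate(batches):
            if not plan.pipelined and prev_eval is not None:
                prev_eval.result()
            traces = sim_pool.submit(sim_task, pi, part, offset, bi,
                                     batch).result()
            prev_eval = eval_pool.submit(eval_task, pi, part, offset, bi,
                                         batch, traces)
            eval_futures.append(prev_eval)

    try:
        if len(parts) == 1:
            run_partition(0, parts[0], 0)
        else:
            orchestrators = [
                threading.Thread(target=run_partition, args=(pi, part,
                                                             offsets[pi]))
                for pi, part in enumerate(parts)
            ]
            for th in orchestrators:
                th.start()
            for th in orchestrators:
                th.join()
        wait(eval_futures)
    finally:
        sim_pool.shutdown(wait=True)
        eval_pool.shutdown(wait=True)

    for gi in failed:
        matrix[gi, :] = params.max_score
    for gi, ind in enumerate(offspring):
        ind.scores = matrix[gi]
    return matrix, log_


def synthetic_timeline(n_batches: int, sim_time: float, eval_time: float,
                       pipelined: bool) -> EventLog:
    """Analytic timeline of one partition's batches with fixed task
    durations — the scheduling model behind the stimulus-scaling analysis.

    With pipelining, simulation of batch k+1 starts when batch k's
    simulation ends (the simulator is busy back-to-back) while evaluation
    proceeds concurrently; without it, each simulation waits for the
    previous evaluation.
    """
    if n_batches < 1:
        raise ConfigurationError("n_batches must be >= 1")
    log_ = EventLog()
    sim_end = 0.0
    eval_end = 0.0
    for k in range(n_batches):
        sim_start = sim_end if pipelined else max(sim_end, eval_end)
        sim_end = sim_start + sim_time
        log_.add(EventRecord("simulate", k, "sim_0", sim_start, sim_end))
        eval_start = max(sim_end, eval_end)
        eval_end = eval_start + eval_time
        log_.add(EventRecord("evaluate", k, "eval_0", eval_start, eval_end))
    return log_
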