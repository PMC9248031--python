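"""Objective function: feature deviations against a target table.

Each objective is one (stimulus, feature) pair.  An individual's score on
that objective is the absolute deviation of its simulated feature value
from the target mean, normalised by the target standard deviation and
clipped at ``max_score`` (default 250); an undefined simulated feature
scores the full ``max_score``.  The score matrix therefore has shape
N x (S*F), indexed stimulus-major / feature-minor, and the unweighted row
sum is the total used for hall-of-fame ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .efeatures import (DEFAULT_THRESHOLD_MV, FEATURE_UNITS, FeatureSet,
                        FeatureValue, feature_vector)
from .errors import ConfigurationError, IntegrationError
from .model import CellModel, Population, Trace, simulate, DEFAULT_DT
from .stimuli import Stimulus, StimulusSuite

__all__ = [
    "DEFAULT_MAX_SCORE",
    "STD_FLOORS",
    "StdPolicy",
    "TargetFeatureTable",
    "SimulationParams",
    "score_feature",
    "score_individual",
    "evaluate",
    "total_score",
    "targets_from_traces",
]

log = logging.getLogger(__name__)

DEFAULT_MAX_SCORE = 250.0

#: per-unit floors for the fractional std policy
STD_FLOORS = {
    "mV": 0.5,
    "ms": 1.0,
    "count": 0.5,
    "Hz": 0.5,
    "dimensionless": 0.05,
    "mV/ms": 1.0,
}


@dataclass(frozen=True)
class StdPolicy:
    """How target stds are constructed from target traces.

    ``fraction`` (default): std = max(fraction * |mean|, unit floor), from a
    single (or averaged) target trace.  ``empirical``: sample std of the
    feature across replicate traces, floored the same way.
    """

    kind: str = "fraction"
    fraction: float = 0.05

    def __post_init__(self):
        if self.kind not in ("fraction", "empirical"):
            raise ConfigurationError(f"unknown std policy {self.kind!r}")
        if self.fraction <= 0:
            raise ConfigurationError("std fraction must be positive")

    def floor(self, feature_name: str) -> float:
        return STD_FLOORS[FEATURE_UNITS[feature_name]]


@dataclass
class TargetFeatureTable:
    """Per (stimulus, feature) target mean and std.

    ``skipped`` lists pairs whose feature was undefined on the target trace;
    those objectives score 0 for every individual rather than being
    configuration errors.
    """

    rows: dict = field(default_factory=dict)   # (stim_id, feature) -> (mean, std)
    skipped: set = field(default_factory=set)  # {(stim_id, feature)}

    def add(self, stimulus_id: str, feature: str, mean: float, std: float):
        if std <= 0:
            raise ConfigurationError(
                f"target std for ({stimulus_id}, {feature}) must be > 0"
            )
        self.rows[(stimulus_id, feature)] = (float(mean), float(std))

    def get(self, stimulus_id: str, feature: str):
        return self.rows[(stimulus_id, feature)]

    def __len__(self):
        return len(self.rows)

    def check_covers(self, suite: StimulusSuite, feature_set: FeatureSet):
        for s in suite:
            for f in set(feature_set):
                key = (s.id, f)
                if key not in self.rows and key not in self.skipped:
                    raise ConfigurationError(
                        f"target table has no row for stimulus {s.id!r}, "
                        f"feature {f!r}"
                    )


@dataclass(frozen=True)
class SimulationParams:
    """Everything the objective needs besides the parameter vector."""

    model: CellModel
    dt: float = DEFAULT_DT
    v_init: float | None = None
    threshold: float = DEFAULT_THRESHOLD_MV
    max_score: float = DEFAULT_MAX_SCORE


def score_feature(sim: FeatureValue, target_mean: float, target_std: float,
                  max_score: float = DEFAULT_MAX_SCORE) -> float:
    """Normalised absolute deviation, clipped; undefined scores max."""
    if target_std <= 0:
        raise ConfigurationError("target std must be > 0")
    if not sim.is_defined:
        return float(max_score)
    return float(min(abs(sim.value - target_mean) / target_std, max_score))


def score_individual(values, suite: StimulusSuite,
                     targets: TargetFeatureTable, feature_set: FeatureSet,
                     params: SimulationParams) -> np.ndarray:
    """ScoreRow (length S*F) for one parameter vector.

    Simulates every stimulus in order and scores every feature;
    an integration failure fills the whole row with ``max_score``.
    """
    row = np.empty(len(suite) * len(feature_set))
    try:
        for si, stim in enumerate(suite):
            trace = simulate(params.model, values, stim, dt=params.dt,
                             v_init=params.v_init)
            feats = feature_vector(trace, stim, feature_set,
                                   threshold=params.threshold)
            for fi, fv in enumerate(feats):
                key = (stim.id, fv.name)
                if key in targets.skipped:
                    row[si * len(feature_set) + fi] = 0.0
                else:
                    mean, std = targets.get(key[0], key[1])
                    row[si * len(feature_set) + fi] = score_feature(
                        fv, mean, std, params.max_score
                    )
    except IntegrationError:
        row[:] = params.max_score
    return row


def evaluate(offspring: Population, suite: StimulusSuite,
             targets: TargetFeatureTable, feature_set: FeatureSet,
             params: SimulationParams) -> np.ndarray:
    """Score matrix (N x S*F) for a population; attaches rows to the
    individuals.

    A pure function of its inputs: each row depends only on that
    individual's parameter vector, so the computation is embarrassingly
    parallel across individuals and stimuli.
    """
    targets.check_covers(suite, feature_set)
    matrix = np.empty((len(offspring), len(suite) * len(feature_set)))
    for i, ind in enumerate(offspring):
        matrix[i] = score_individual(ind.values, suite, targets, feature_set,
                                     params)
        ind.scores = matrix[i]
    return matrix


def total_score(row) -> float:
    """Unweighted sum of a score row."""
    return float(np.sum(row))


def targets_from_traces(traces_by_stimulus: dict, suite: StimulusSuite,
                        feature_set: FeatureSet,
                        std_policy: StdPolicy = StdPolicy(),
                        threshold: float = DEFAULT_THRESHOLD_MV,
                        ) -> TargetFeatureTable:
    """Build a target table from one or more target traces per stimulus.

    The target mean is the feature computed on the sample-mean trace; the
    std follows ``std_policy``.  Features undefined on the target trace are
    recorded as skipped (they then score 0 for every candidate) with a
    logged warning.
    """
    table = TargetFeatureTable()
    stim_by_id = {s.id: s for s in suite}
    for stim_id, traces in traces_by_stimulus.items():
        if stim_id not in stim_by_id:
            raise ConfigurationError(f"unknown stimulus id {stim_id!r}")
        if not traces:
            raise ConfigurationError(
                f"no target traces for stimulus {stim_id!r}"
            )
        stim = stim_by_id[stim_id]
        if len(traces) == 1:
            mean_trace = traces[0]
        else:
            mean_trace = Trace(traces[0].t,
                               np.mean([tr.v for tr in traces], axis=0),
                               stimulus_id=stim_id)
        mean_feats = feature_vector(mean_trace, stim, feature_set, threshold)

        if std_policy.kind == "empirical" and len(traces) >= 2:
            rep = [feature_vector(tr, stim, feature_set, threshold)
                   for tr in traces]
        else:
            rep = None

        for fi, fv in enumerate(mean_feats):
            key = (stim_id, fv.name)
            if key in table.rows or key in table.skipped:
                continue  # duplicated feature names share one target row
            if not fv.is_defined:
                log.warning(
                    "feature %s undefined on target trace for stimulus %s; "
                    "objective skipped", fv.name, stim_id,
                )
                table.skipped.add(key)
                continue
            floor = std_policy.floor(fv.name)
            if rep is not None:
                vals = [r[fi].value for r in rep if r[fi].is_defined]
                std = float(np.std(vals, ddof=1)) if len(vals) >= 2 else 0.0
                std = max(std, floor)
            else:
                std = max(std_policy.fraction * abs(fv.value), floor)
            table.add(stim_id, fv.name, fv.value, std)
    return table
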