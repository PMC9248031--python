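"""Synthetic ground-truth fitting problems.

A ground-truth problem fixes a known parameter vector ("truth"), simulates
its responses to a stimulus suite, optionally corrupts the traces with
seeded Gaussian voltage noise, and freezes the extracted features into a
target table.  Fitting then becomes a parameter-recovery exercise whose
answer is known: with noiseless targets the truth scores exactly zero.

Problems can free any leading subset of the 13 default parameters; the
remaining parameters are pinned at their ground-truth values inside the
model, which yields the 2- and 4-parameter toy problems used for quick
recovery studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .efeatures import FeatureSet, default_feature_set
from .errors import ConfigurationError, IntegrationError
from .evolution import Problem
from .model import (CellModel, ParameterSpec, Trace, build_default_model,
                    default_parameter_spec, simulate, DEFAULT_DT,
                    _parse_entry)
from .rng import named_stream
from .scoring import (SimulationParams, StdPolicy, TargetFeatureTable,
                      targets_from_traces)
from .stimuli import StimulusSuite, default_suite

__all__ = [
    "FREE_PARAMETER_ORDER",
    "TOY_FEATURES",
    "GroundTruthProblem",
    "make_ground_truth",
    "make_toy_problem",
]

#: which parameters are freed first when only ``n_free_params`` are free;
#: the somatic and axonal spike conductances come before the slower
#: adaptation and passive parameters
FREE_PARAMETER_ORDER = (
    "gNabar_soma", "gKbar_soma", "gNabar_axon", "gKbar_axon",
    "gMbar_soma", "gMbar_axon", "g_pas_soma", "g_pas_axon", "g_pas_dend",
    "e_pas", "cm", "Ra", "tau_max",
)


@dataclass
class GroundTruthProblem:
    """A fitting problem whose answer is known.

    ``spec`` and ``truth`` cover only the free parameters; ``truth_full``
    holds all 13 ground-truth values (the fixed ones are baked into
    ``model`` as base values).
    """

    spec: ParameterSpec
    model: CellModel
    truth: np.ndarray
    truth_full: np.ndarray
    full_spec: ParameterSpec
    suite: StimulusSuite
    feature_set: FeatureSet
    targets: TargetFeatureTable
    noise_sd: float
    seed: int
    dt: float = DEFAULT_DT

    @property
    def sim_params(self) -> SimulationParams:
        return SimulationParams(self.model, dt=self.dt)

    def problem(self) -> Problem:
        return Problem(self.spec, self.suite, self.targets,
                       self.feature_set, self.sim_params)


def _truth_to_base(full_spec: ParameterSpec, truth_full: np.ndarray):
    """Split a full parameter vector into the model's base-value dicts."""
    density: dict[str, dict[str, float]] = {}
    glob: dict[str, float] = {}
    for entry, value in zip(full_spec.entries, truth_full):
        parsed = _parse_entry(entry)
        if parsed[0] == "density":
            density.setdefault(parsed[1], {})[entry.compartment] = float(value)
        else:
            glob[parsed[1]] = float(value)
    return density, glob


def make_ground_truth(
    seed: int,
    n_free_params: int = 13,
    noise_sd: float = 0.0,
    suite: StimulusSuite | None = None,
    feature_set: FeatureSet | None = None,
    std_policy: StdPolicy = StdPolicy(),
    dt: float = DEFAULT_DT,
    max_retries: int = 20,
) -> GroundTruthProblem:
    """Sample a ground truth and freeze its target feature table.

    The truth is drawn uniformly from the middle 60% of each parameter's
    bounds (avoiding boundary pathologies); ``noise_sd`` (mV) of seeded
    Gaussian noise is added to the target traces before feature extraction.
    A truth whose simulation blows up is resampled, up to ``max_retries``
    times.  Deterministic given ``seed``.
    """
    full_spec = default_parameter_spec()
    if not 1 <= n_free_params <= full_spec.count:
        raise ConfigurationError(
            f"n_free_params must be in [1, {full_spec.count}]"
        )
    if suite is None:
        suite = default_suite()
    if feature_set is None:
        feature_set = default_feature_set()

    free_names = FREE_PARAMETER_ORDER[:n_free_params]
    free_spec = full_spec.subset(free_names)

    rng_truth = named_stream(seed, "truth")
    rng_noise = named_stream(seed, "target-noise")
    lo, hi = full_spec.lower, full_spec.upper
    span = hi - lo

    last_error: Exception | None = None
    for _ in range(max_retries):
        truth_full = rng_truth.uniform(lo + 0.2 * span, hi - 0.2 * span)
        density, glob = _truth_to_base(full_spec, truth_full)
        model = build_default_model(free_spec, base_density=density,
                                    base_global=glob)
        name_to_idx = {e.name: i for i, e in enumerate(full_spec.entries)}
        truth = np.array([truth_full[name_to_idx[n]]
                          for n in free_spec.names])
        try:
            traces = {}
            for stim in suite:
                trace = simulate(model, truth, stim, dt=dt)
                if noise_sd > 0:
                    noisy_v = trace.v + rng_noise.normal(0.0, noise_sd,
                                                         size=len(trace.v))
                    trace = Trace(trace.t, noisy_v, stimulus_id=stim.id)
                traces[stim.id] = [trace]
        except IntegrationError as err:
            last_error = err
            continue
        targets = targets_from_traces(traces, suite, feature_set, std_policy)
        return GroundTruthProblem(free_spec, model, truth, truth_full,
                                  full_spec, suite, feature_set, targets,
                                  noise_sd, seed, dt)
    raise ConfigurationError(
        f"could not sample an integrable ground truth in {max_retries} "
        f"attempts (last failure: {last_error})"
    )


#: score functions of the reduced recovery problems: one spiking-rate,
#: latency, spike-shape and subthreshold summary each, mirroring the
#: annotated single-trace features of a typical fitting figure
TOY_FEATURES = (
    "spike_count", "time_to_first_spike", "mean_frequency",
    "AP_amplitude_mean", "AP_peak_mean", "AHP_depth_mean",
    "voltage_base", "steady_state_voltage_stimend",
)

#: ground-truth seed of the shipped toy problems
TOY_SEED = 1


def make_toy_problem(n_free_params: int = 2, seed: int = TOY_SEED,
                     noise_sd: float = 0.0) -> GroundTruthProblem:
    """The shipped quick parameter-recovery problem.

    Uses the 8 long-square stimuli and 8 score functions per stimulus (the
    reduced design of the population-size recovery study): free the somatic
    and axonal spike conductances first, pin everything else at the ground
    truth.
    """
    return make_ground_truth(
        seed, n_free_params=n_free_params, noise_sd=noise_sd,
        suite=default_suite().select("long_square"),
        feature_set=FeatureSet(TOY_FEATURES),
    )
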