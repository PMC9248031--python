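"""Readers and writers for every on-disk artifact.

All formats are plain text: TSV/JSON for parameter specifications, CSV for
traces, feature tables, targets, score matrices, histories, event logs and
benchmark results, JSON/YAML for stimulus suites and EA configurations.
Every writer's output round-trips through its reader with value equality.

A *fixture bundle* is a directory fully determining a fit (spec, stimulus
suite, target table, ground truth and metadata) with no absolute paths, so
a fit is reproducible from the bundle and a seed alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .efeatures import FeatureSet, FeatureValue
from .errors import ConfigurationError
from .evolution import EAConfig, GenerationStats, HallOfFame, Problem
from .fixtures import GroundTruthProblem, _truth_to_base
from .model import (Individual, ParameterEntry, ParameterSpec, Trace,
                    build_default_model)
from .scheduler import EventLog
from .scoring import TargetFeatureTable
from .stimuli import Stimulus, StimulusSuite

__all__ = [
    "write_spec_tsv", "read_spec_tsv", "write_spec_json", "read_spec_json",
    "write_trace_csv", "read_trace_csv",
    "write_suite", "read_suite",
    "write_targets_csv", "read_targets_csv",
    "write_feature_table_csv",
    "write_score_matrix_csv", "read_score_matrix_csv",
    "write_history_csv", "read_history_csv",
    "write_event_log_csv",
    "write_benchmark_csv",
    "write_ea_config", "read_ea_config",
    "write_fixture_bundle", "read_fixture_bundle",
    "write_hof_json", "write_best_json",
]

_SPEC_COLUMNS = ["name", "compartment", "lower", "upper", "units"]


# -- parameter specification ------------------------------------------------

def write_spec_tsv(spec: ParameterSpec, path):
    df = pd.DataFrame([[e.name, e.compartment, e.lower, e.upper, e.units]
                       for e in spec.entries], columns=_SPEC_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_spec_tsv(path) -> ParameterSpec:
    df = pd.read_csv(path, sep="\t")
    missing = set(_SPEC_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(
            f"{path}: missing columns {sorted(missing)}"
        )
    return ParameterSpec(tuple(
        ParameterEntry(r["name"], r["compartment"], float(r["lower"]),
                       float(r["upper"]), r["units"])
        for _, r in df.iterrows()
    ))


def write_spec_json(spec: ParameterSpec, path):
    Path(path).write_text(json.dumps(
        [asdict(e) for e in spec.entries], indent=2
    ))


def read_spec_json(path) -> ParameterSpec:
    rows = json.loads(Path(path).read_text())
    return ParameterSpec(tuple(ParameterEntry(**r) for r in rows))


# -- traces -----------------------------------------------------------------

def write_trace_csv(trace: Trace, path):
    with open(path, "w") as fh:
        fh.write(f"# stimulus_id={trace.stimulus_id}\n")
        fh.write("time_ms,voltage_mV\n")
        # full round-trip precision: the reader recovers the values exactly
        for t, v in zip(trace.t, trace.v):
            fh.write(f"{t:.17g},{v:.17g}\n")


def read_trace_csv(path) -> Trace:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# stimulus_id="):
            raise ConfigurationError(
                f"{path}: line 1 must be a '# stimulus_id=' comment"
            )
        stimulus_id = first.split("=", 1)[1]
        df = pd.read_csv(fh, float_precision="round_trip")
    return Trace(df["time_ms"].to_numpy(), df["voltage_mV"].to_numpy(),
                 stimulus_id=stimulus_id)


# -- stimulus suites --------------------------------------------------------

def _stim_dict(s: Stimulus) -> dict:
    d = {"id": str(s.id), "kind": str(s.kind),
         "amplitude": float(s.amplitude), "delay": float(s.delay),
         "duration": float(s.duration), "t_stop": float(s.t_stop)}
    if s.kind == "noisy":
        d["seed"] = int(s.seed)
        d["noise_cv"] = float(s.noise_cv)
    return d


def write_suite(suite: StimulusSuite, path):
    """JSON or YAML by file extension."""
    payload = {"stimuli": [_stim_dict(s) for s in suite]}
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def read_suite(path) -> StimulusSuite:
    path = Path(path)
    text = path.read_text()
    payload = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
               else json.loads(text))
    stims = []
    for i, d in enumerate(payload["stimuli"]):
        try:
            stims.append(Stimulus(
                d["id"], d["kind"], float(d["amplitude"]), float(d["delay"]),
                float(d["duration"]), float(d["t_stop"]),
                seed=d.get("seed"), noise_cv=float(d.get("noise_cv", 0.0)),
            ))
        except (KeyError, ConfigurationError) as err:
            raise ConfigurationError(
                f"{path}: stimulus #{i}: {err}"
            ) from err
    return StimulusSuite(tuple(stims))


# -- target tables ----------------------------------------------------------

def write_targets_csv(targets: TargetFeatureTable, path):
    """Skipped objectives are kept as rows with empty mean/std."""
    rows = [
        {"stimulus_id": k[0], "feature": k[1], "mean": v[0], "std": v[1]}
        for k, v in targets.rows.items()
    ] + [
        {"stimulus_id": k[0], "feature": k[1], "mean": np.nan, "std": np.nan}
        for k in sorted(targets.skipped)
    ]
    pd.DataFrame(rows, columns=["stimulus_id", "feature", "mean", "std"]
                 ).to_csv(path, index=False)


def read_targets_csv(path) -> TargetFeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    table = TargetFeatureTable()
    for i, r in df.iterrows():
        if pd.isna(r["mean"]) or pd.isna(r["std"]):
            table.skipped.add((r["stimulus_id"], r["feature"]))
            continue
        try:
            table.add(r["stimulus_id"], r["feature"], float(r["mean"]),
                      float(r["std"]))
        except ConfigurationError as err:
            raise ConfigurationError(f"{path}: row {i}: {err}") from err
    return table


# -- feature tables ---------------------------------------------------------

def write_feature_table_csv(features_by_stimulus: dict, path):
    """``{stimulus_id: [FeatureValue, ...]}`` to CSV; undefined -> NA."""
    rows = []
    for stim_id, feats in features_by_stimulus.items():
        for fv in feats:
            rows.append({
                "stimulus_id": stim_id, "feature": fv.name,
                "value": fv.value if fv.is_defined else "NA",
            })
    pd.DataFrame(rows, columns=["stimulus_id", "feature", "value"]
                 ).to_csv(path, index=False)


# -- score matrices ---------------------------------------------------------

def objective_ids(suite: StimulusSuite, feature_set: FeatureSet) -> list[str]:
    return [f"{s.id}:{name}" for s in suite for name in feature_set]


def write_score_matrix_csv(matrix, suite, feature_set, path):
    pd.DataFrame(np.atleast_2d(matrix),
                 columns=objective_ids(suite, feature_set)
                 ).to_csv(path, index=False)


def read_score_matrix_csv(path) -> np.ndarray:
    return pd.read_csv(path, float_precision="round_trip").to_numpy()


# -- run history / event logs / benchmark results ---------------------------

_HISTORY_COLUMNS = ["generation", "best_total", "mean_total", "std_total",
                    "evaluations", "hof_best"]


def write_history_csv(history, path):
    pd.DataFrame([{c: getattr(h, c) for c in _HISTORY_COLUMNS}
                  for h in history]).to_csv(path, index=False)


def read_history_csv(path) -> list[GenerationStats]:
    df = pd.read_csv(path)
    return [GenerationStats(int(r["generation"]), r["best_total"],
                            r["mean_total"], r["std_total"],
                            int(r["evaluations"]), r["hof_best"])
            for _, r in df.iterrows()]


def write_event_log_csv(log: EventLog, path):
    pd.DataFrame([{"kind": r.kind, "batch": r.batch, "worker": r.worker,
                   "start_s": r.start, "end_s": r.end,
                   "partition": r.partition} for r in log.records]
                 ).to_csv(path, index=False)


def write_benchmark_csv(result, path):
    rows = []
    for tr in result.trials:
        rows.append({
            "kind": result.kind, "N": tr.trial.n,
            "partitions": tr.trial.plan.n_partitions,
            "S": tr.trial.s, "F": tr.trial.f,
            "mean_s": tr.mean_s, "std_s": tr.std_s,
            "evaluations": tr.evaluations, "batches": tr.batches,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# -- EA configuration -------------------------------------------------------

_CONFIG_KEYS = {"mu", "lambda_", "n_generations", "seed", "cx_rate",
                "mut_rate", "hof_size", "kappa", "eta_cx", "eta_mut"}


def write_ea_config(config: EAConfig, path):
    payload = {k: getattr(config, k) for k in _CONFIG_KEYS}
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_ea_config(path, **overrides) -> EAConfig:
    path = Path(path)
    text = path.read_text()
    payload = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
               else json.loads(text))
    if "lambda" in payload:
        payload["lambda_"] = payload.pop("lambda")
    unknown = set(payload) - _CONFIG_KEYS
    if unknown:
        raise ConfigurationError(
            f"{path}: unknown EA config fields {sorted(unknown)}"
        )
    payload.update(overrides)
    try:
        return EAConfig(**payload)
    except (TypeError, ConfigurationError) as err:
        raise ConfigurationError(f"{path}: {err}") from err


# -- fixture bundles --------------------------------------------------------

def write_fixture_bundle(gtp: GroundTruthProblem, directory):
    """Write a self-contained problem directory.

    Files: spec.json (free parameters), full_spec.json, suite.json,
    targets.csv, truth.json (free and full vectors), meta.json.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_spec_json(gtp.spec, d / "spec.json")
    write_spec_json(gtp.full_spec, d / "full_spec.json")
    write_suite(gtp.suite, d / "suite.json")
    write_targets_csv(gtp.targets, d / "targets.csv")
    (d / "truth.json").write_text(json.dumps({
        "free_names": gtp.spec.names,
        "truth": gtp.truth.tolist(),
        "truth_full": gtp.truth_full.tolist(),
    }, indent=2))
    (d / "meta.json").write_text(json.dumps({
        "seed": gtp.seed, "noise_sd": gtp.noise_sd, "dt": gtp.dt,
        "n_free_params": gtp.spec.count,
        "features": list(gtp.feature_set.names),
    }, indent=2))


def read_fixture_bundle(directory) -> GroundTruthProblem:
    d = Path(directory)
    spec = read_spec_json(d / "spec.json")
    full_spec = read_spec_json(d / "full_spec.json")
    suite = read_suite(d / "suite.json")
    targets = read_targets_csv(d / "targets.csv")
    truth_info = json.loads((d / "truth.json").read_text())
    meta = json.loads((d / "meta.json").read_text())
    truth_full = np.array(truth_info["truth_full"])
    density, glob = _truth_to_base(full_spec, truth_full)
    model = build_default_model(spec, base_density=density, base_global=glob)
    return GroundTruthProblem(
        spec, model, np.array(truth_info["truth"]), truth_full, full_spec,
        suite, FeatureSet(tuple(meta["features"])), targets,
        float(meta["noise_sd"]), int(meta["seed"]), float(meta["dt"]),
    )


# -- fit outputs ------------------------------------------------------------

def write_best_json(best: Individual, spec: ParameterSpec, path):
    Path(path).write_text(json.dumps({
        "parameters": dict(zip(spec.names, best.values.tolist())),
        "total_score": best.total_score,
    }, indent=2))


def write_hof_json(hof: HallOfFame, spec: ParameterSpec, path):
    Path(path).write_text(json.dumps([
        {"total": e.total, "generation": e.generation,
         "parameters": dict(zip(spec.names, e.individual.values.tolist()))}
        for e in hof.entries
    ], indent=2))
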