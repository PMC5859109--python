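"""File formats: model JSON, trace CSV (+ JSON sidecar), criteria YAML
and target-specification YAML.  All quantities carry explicit units in
the files (ms, mV, pA, pF, nS)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .classify import ClassCriteria, ClassLabel
from .features import FeatureSet
from .model import MCModel, Trace
from .objective import TargetSpec, TraceTarget, WeightConfig

__all__ = [
    "save_model", "load_model",
    "save_trace", "load_trace_frame",
    "save_criteria", "load_criteria",
    "save_target_spec", "load_target_spec",
]

UNITS = {"t": "ms", "V": "mV", "I": "pA", "C": "pF", "G": "nS"}


def save_model(model: MCModel, path) -> None:
    doc = {"units": UNITS, **model.to_dict()}
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path) -> MCModel:
    return MCModel.from_dict(json.loads(Path(path).read_text()))


def save_trace(trace: Trace, csv_path, sidecar_path=None) -> None:
    """CSV with header time_ms, V_<compartment>[, U_<compartment>] plus a
    JSON sidecar holding spike times and the stimulus description."""
    trace.to_frame().to_csv(csv_path, index=False)
    side = {
        "units": UNITS,
        "spikes_ms": {k: [float(t) for t in v] for k, v in trace.spikes.items()},
        "stimuli": [
            {
                "kind": s.kind, "target": s.target,
                "onset_ms": s.onset,
                "offset_ms": None if np.isinf(s.offset) else s.offset,
                "amplitude_pA": s.amplitude, "slope_pA_per_ms": s.slope,
                "resolution_ms": s.resolution,
                "events": [list(e) for e in s.events],
            }
            for s in trace.stimuli
        ],
    }
    if sidecar_path is None:
        sidecar_path = Path(csv_path).with_suffix(".json")
    Path(sidecar_path).write_text(json.dumps(side, indent=1))


def load_trace_frame(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


def save_criteria(criteria: ClassCriteria, path) -> None:
    Path(path).write_text(yaml.safe_dump(criteria.to_dict(), sort_keys=False))


def load_criteria(path) -> ClassCriteria:
    return ClassCriteria.from_dict(yaml.safe_load(Path(path).read_text()))


def _trace_target_to_dict(tt: TraceTarget) -> dict:
    return {
        "features": tt.features.to_dict(),
        "class": tt.label.composite,
        "S": list(tt.S),
        "onset_ms": tt.onset,
        "offset_ms": tt.offset,
        "duration_ms": tt.duration,
        "I_exp_pA": tt.I_exp,
        "target_compartment": tt.target_compartment,
    }


def _trace_target_from_dict(d: dict) -> TraceTarget:
    return TraceTarget(
        features=FeatureSet.from_dict(d["features"]),
        label=ClassLabel.parse(d["class"]),
        S=tuple(d["S"]),
        onset=float(d["onset_ms"]),
        offset=float(d["offset_ms"]),
        duration=float(d["duration_ms"]),
        I_exp=d.get("I_exp_pA"),
        target_compartment=d.get("target_compartment"),
    )


def save_target_spec(spec: TargetSpec, path) -> None:
    doc = {
        "units": UNITS,
        "traces": [_trace_target_to_dict(t) for t in spec.traces],
        "criteria": spec.criteria.to_dict(),
        "weights": {"w_base": spec.weight_config.w_base,
                    "w_gain": spec.weight_config.w_gain,
                    "clip": spec.weight_config.clip},
        "fast_spiking": spec.fast_spiking,
        "min_freq_hz": spec.min_freq_hz,
        "mc_constraints": spec.mc_constraints,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_target_spec(path) -> TargetSpec:
    doc = yaml.safe_load(Path(path).read_text())
    w = doc.get("weights", {})
    return TargetSpec(
        traces=tuple(_trace_target_from_dict(t) for t in doc["traces"]),
        criteria=ClassCriteria.from_dict(doc["criteria"]),
        weight_config=WeightConfig(w.get("w_base", 1.0), w.get("w_gain", 9.0),
                                   w.get("clip", 1.0)),
        fast_spiking=bool(doc.get("fast_spiking", False)),
        min_freq_hz=float(doc.get("min_freq_hz", 25.0)),
        mc_constraints=bool(doc.get("mc_constraints", False)),
    )
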