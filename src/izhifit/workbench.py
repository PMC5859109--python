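"""Reference fixtures, working-current search, synthetic targets and the
reproduction battery tying the pipeline together.

The packaged fixtures are published optimized parameter sets for nine
hippocampal neuron-type models (one per single-behavior spike-pattern
class) plus a four-compartment CA2 pyramidal model.  Published sources
rarely print the stimulation currents behind each pattern, so
:func:`find_working_current` scans step currents until the simulated
pattern classifies to the expected label; :func:`make_synthetic_target`
turns any model into a feature-level fitting target for the optimizer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace as _dc_replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classify import ClassCriteria, ClassLabel, class_distance, classify
from .features import FeatureSet, SpikeTrain, extract_features
from .model import MCModel, SimConfig, Stimulus, SynapseConfig, Trace
from .objective import (CONTINUOUS_S, INTERRUPTED_S, TargetSpec, TraceTarget,
                        mc_constraint_errors, minimum_firing_frequency,
                        somatic_epsp, spike_propagation_rate)
from .simulate import simulate

__all__ = [
    "FixtureEntry",
    "load_fixtures",
    "load_mc_fixture",
    "default_criteria",
    "characterize",
    "find_working_current",
    "SyntheticTarget",
    "make_synthetic_target",
    "reproduce",
]

# characterization protocol: 1000 ms step after a 100 ms pre-stimulus
# window (the rest state is exact, so the window only aids inspection)
CHAR_ONSET = 100.0
CHAR_DURATION = 1100.0
ACCURATE_SIM = SimConfig(dt=0.05, duration=CHAR_DURATION, method="rk4")


@dataclass(frozen=True)
class FixtureEntry:
    """One packaged reference model with its published class label."""

    name: str
    label: ClassLabel
    model: MCModel
    provenance: str = ""
    working_currents: Tuple[float, ...] = ()


def _fixture_path(fname: str):
    return resources.files("izhifit.fixtures").joinpath(fname)


def load_fixtures() -> List[FixtureEntry]:
    """The nine packaged single-behavior reference models (the stuttering
    entries are symmetric two-compartment constructions with their
    published coupling conductance)."""
    doc = json.loads(_fixture_path("table1_models.json").read_text())
    out = []
    for e in doc["models"]:
        out.append(FixtureEntry(
            name=e["name"],
            label=ClassLabel.parse(e["class"]),
            model=MCModel.from_dict(e["model"]),
            provenance=e.get("provenance", ""),
            working_currents=tuple(e.get("working_currents_pA", ())),
        ))
    if len(out) != 9:
        raise RuntimeError(f"fixture file corrupt: expected 9 models, got {len(out)}")
    return out


def load_mc_fixture() -> FixtureEntry:
    """The packaged four-compartment CA2 pyramidal chain (SO-SP-SR-SLM)."""
    e = json.loads(_fixture_path("table3_ca2_mc.json").read_text())
    return FixtureEntry(
        name=e["name"], label=ClassLabel.parse(e["class"]),
        model=MCModel.from_dict(e["model"]),
        provenance=e.get("provenance", ""),
        working_currents=tuple(e.get("working_currents_pA", ())),
    )


def default_criteria() -> ClassCriteria:
    from .io import load_criteria

    return load_criteria(_fixture_path("criteria_default.yaml"))


def fixture(name: str) -> FixtureEntry:
    for e in load_fixtures():
        if e.name == name:
            return e
    mc = load_mc_fixture()
    if mc.name == name:
        return mc
    raise KeyError(name)


def characterize(model: MCModel, I: float,
                 criteria: Optional[ClassCriteria] = None,
                 config: Optional[SimConfig] = None,
                 onset: float = CHAR_ONSET,
                 compartment: Optional[str] = None):
    """Simulate a step of I pA, extract features and classify.

    Returns (trace, train, features, label)."""
    crit = criteria or ClassCriteria()
    cfg = config or ACCURATE_SIM
    name = compartment or model.soma
    trace = simulate(model, Stimulus.step(I, onset, cfg.duration, target=name), cfg)
    sp = trace.spikes[name]
    train = SpikeTrain(sp[(sp >= onset) & (sp <= cfg.duration)], onset, cfg.duration)
    feats = extract_features(trace, compartment=name, gap_factor=crit.gap_factor,
                             sfa_transform=crit.sfa_transform,
                             sfa_alpha=crit.piecewise_alpha)
    label = classify(trace, train, features=feats, criteria=crit, compartment=name)
    return trace, train, feats, label


def find_working_current(model: MCModel, label: ClassLabel,
                         lo: float = 50.0, hi: float = 800.0, step: float = 5.0,
                         criteria: Optional[ClassCriteria] = None,
                         config: Optional[SimConfig] = None) -> Optional[float]:
    """First step current in [lo, hi] whose simulated pattern classifies
    to ``label`` (the published tables omit stimulation currents).
    Deterministic for a fixed grid; None when no current matches."""
    want = label.composite
    for I in np.arange(lo, hi + step / 2, step):
        _, _, _, got = characterize(model, float(I), criteria=criteria, config=config)
        if got.composite == want:
            return float(I)
    return None


@dataclass(frozen=True)
class SyntheticTarget:
    """A feature-level fitting target generated from a known model."""

    spec: TargetSpec
    source_model: MCModel
    currents: Tuple[float, ...]
    seed: int
    noise: Optional[dict] = None


def _feature_subset(features: FeatureSet) -> Tuple[str, ...]:
    if features.nbs >= 2:
        return INTERRUPTED_S
    if features.sfa is None:
        # too few spikes for an adaptation fit: latency + spike count
        return ("fsl", "nspikes")
    return CONTINUOUS_S


def make_synthetic_target(model: MCModel, currents: Sequence[float],
                          noise: Optional[Dict[str, float]] = None,
                          seed: int = 0,
                          criteria: Optional[ClassCriteria] = None,
                          config: Optional[SimConfig] = None,
                          fast_spiking: bool = False,
                          mc_constraints: bool = False,
                          max_retries: int = 20) -> SyntheticTarget:
    """Simulate the model at each current, extract features/classes and
    emit a TargetSpec.

    ``noise`` maps feature names (fsl, pss) to Gaussian jitter standard
    deviations; jittered targets are re-verified to stay inside their own
    class region (class_distance <= 0) and redrawn up to ``max_retries``.
    With zero noise the target features equal the simulated ones exactly.
    """
    crit = criteria or ClassCriteria()
    cfg = config or ACCURATE_SIM
    rng = np.random.default_rng(seed)
    targets = []
    for I in currents:
        trace, train, feats, label = characterize(model, I, criteria=crit, config=cfg)
        if label.composite == "subthreshold":
            raise ValueError(f"current {I} pA is subthreshold; not a spiking target")
        if noise:
            ok = False
            for _ in range(max_retries):
                jittered = _dc_replace(feats)
                for fname, sd in noise.items():
                    val = getattr(jittered, fname, None)
                    if val is not None:
                        setattr(jittered, fname, float(val + rng.normal(0.0, sd)))
                dists = class_distance(jittered, label, crit, train=train)
                if all(v <= 0 for v in dists.values()):
                    feats = jittered
                    ok = True
                    break
            if not ok:
                raise RuntimeError("feature jitter left the target class region "
                                   f"{max_retries} times in a row")
        targets.append(TraceTarget(
            features=feats, label=label, S=_feature_subset(feats),
            onset=CHAR_ONSET, offset=cfg.duration, duration=cfg.duration,
            I_exp=float(I)))
    spec = TargetSpec(traces=tuple(targets), criteria=crit,
                      fast_spiking=fast_spiking, mc_constraints=mc_constraints)
    return SyntheticTarget(spec=spec, source_model=model,
                           currents=tuple(float(I) for I in currents),
                           seed=seed, noise=dict(noise) if noise else None)


# ---------------------------------------------------------------------------
# reproduction battery


def latency_battery() -> dict:
    """First-spike latencies of the CA1 OR-LM reference model at its
    three published depolarizing currents (ms from step onset)."""
    entry = fixture("CA1 OR-LM")
    out = {}
    for I in (156.0, 108.0, 46.0):
        trace, train, _, _ = characterize(entry.model, I)
        out[f"{int(I)} pA"] = {
            "fsl_ms": float(train.spike_times[0] - CHAR_ONSET) if train.n_spikes
            else None,
            "n_spikes": train.n_spikes,
        }
    return out


def mc_latency() -> dict:
    """Somatic first-spike latency and class of the four-compartment CA2
    model under its published 401 pA somatic step."""
    entry = load_mc_fixture()
    crit = default_criteria()
    trace, train, feats, label = characterize(entry.model, 401.0, criteria=crit)
    return {
        "fsl_ms": float(train.spike_times[0] - CHAR_ONSET) if train.n_spikes else None,
        "class": label.composite,
        "n_spikes": train.n_spikes,
    }


def fast_spiking_minimum() -> dict:
    """Minimum first-ISI instantaneous frequency of the CA3 Basket model
    over 500 ms steps scanned upward (1 pA grid) from its step rheobase."""
    entry = fixture("CA3 Basket")
    fmin = minimum_firing_frequency(entry.model, step_ms=500.0, scan_step=1.0)
    return {"min_first_isi_freq_hz": fmin}


def class_battery(criteria: Optional[ClassCriteria] = None) -> dict:
    """For each packaged reference model, the first step current in
    [50, 800] pA whose simulated pattern classifies to the published
    label (the calibration check of the default criteria)."""
    crit = criteria or default_criteria()
    out = {}
    for e in load_fixtures():
        I = find_working_current(e.model, e.label, criteria=crit)
        out[e.name] = {"class": e.label.composite, "working_current_pA": I,
                       "matched": I is not None}
    return out


def mc_constraint_battery() -> dict:
    """The four dendritic constraint error terms of the packaged
    four-compartment model, plus the raw measurements behind them."""
    entry = load_mc_fixture()
    model = entry.model
    errs = mc_constraint_errors(model)
    raw = {}
    for name in model.names:
        if name == model.soma:
            continue
        raw[name] = {"somatic_epsp_mV": somatic_epsp(model, name)}
    return {"errors": errs, "epsp": raw}


def reproduce(out_dir=None, criteria: Optional[ClassCriteria] = None) -> dict:
    """Run the full reproduction battery and (optionally) write the
    report JSON.  Failures are reported, never raised."""
    report = {
        "latency_battery": latency_battery(),
        "mc_latency": mc_latency(),
        "fast_spiking_minimum": fast_spiking_minimum(),
        "class_battery": class_battery(criteria),
        "mc_constraint_battery": mc_constraint_battery(),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "reproduction_report.json").write_text(
            json.dumps(report, indent=1, default=float))
    return report
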