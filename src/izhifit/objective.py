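"""Scalar fitness of a candidate model against feature targets.

The core error is a class-aware weighted sum over the feature set S of
each target trace::

    error = sum_{f in S} W_f * log(1 + |target_f - model_f|)

with features entering in their native units (ms, counts,
transformed-slope units); the log compresses scale differences.  The
weights W_f are assigned dynamically: when the candidate's qualitative
class differs from the target class, the features violating the target
class criteria are up-weighted in proportion to their distance from the
class boundary, which steers the search toward the target class region
quickly while leaving within-class exploration slow.

Multi-compartment candidates additionally pay four per-dendrite
constraint penalties (relative excitability, relative input resistance,
forward spike propagation, unitary somatic EPSP amplitude) and, for
fast-spiking targets, a penalty when the minimum near-rheobase
instantaneous frequency falls short of a floor (default 25 Hz).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classify import ClassCriteria, ClassLabel, class_distance, classify
from .features import FeatureSet, SpikeTrain, extract_features
from .model import MCModel, SimConfig, SimulationDiverged, Stimulus, SynapseConfig
from .simulate import (MeasurementInvalid, default_ramp, rheobase_by_ramp,
                       simulate, voltage_deflection)

__all__ = [
    "TraceTarget",
    "TargetSpec",
    "WeightConfig",
    "ErrorBreakdown",
    "feature_error",
    "dynamic_weights",
    "mc_constraint_errors",
    "fast_spiking_penalty",
    "minimum_firing_frequency",
    "step_rheobase",
    "evaluate_model",
]

CONTINUOUS_S = ("fsl", "pss", "m", "c", "nisi")
INTERRUPTED_S = ("fsl", "pss", "nbs", "bw", "pbi", "nspikes")
_ALLOWED_S = set(CONTINUOUS_S) | set(INTERRUPTED_S) | {"rbv"}

MAX_ERROR = 1e6
MISSING_PENALTY = 100.0  # |target - model| surrogate for an absent feature


@dataclass(frozen=True)
class TraceTarget:
    """One target trace: its features, class, stimulus window and the
    feature subset S compared for it."""

    features: FeatureSet
    label: ClassLabel
    S: Tuple[str, ...]
    onset: float
    offset: float
    duration: float
    I_exp: Optional[float] = None  # pA; None when unknown
    target_compartment: Optional[str] = None

    def __post_init__(self):
        bad = set(self.S) - _ALLOWED_S
        if bad:
            raise ValueError(f"unknown objective features {sorted(bad)}")


@dataclass(frozen=True)
class WeightConfig:
    """Dynamic feature-weight rule: W = w_base within the target class,
    W = w_base + w_gain * clip(distance, 0, clip) on class-violating
    features outside it."""

    w_base: float = 1.0
    w_gain: float = 9.0
    clip: float = 1.0


@dataclass(frozen=True)
class TargetSpec:
    traces: Tuple[TraceTarget, ...]
    criteria: ClassCriteria = field(default_factory=ClassCriteria)
    weight_config: WeightConfig = field(default_factory=WeightConfig)
    fast_spiking: bool = False
    min_freq_hz: float = 25.0
    mc_constraints: bool = False

    @property
    def n_traces(self) -> int:
        return len(self.traces)


@dataclass
class ErrorBreakdown:
    """Per-term decomposition of one evaluation; total is their sum."""

    trace_terms: List[Dict[str, float]] = field(default_factory=list)
    trace_weights: List[Dict[str, float]] = field(default_factory=list)
    trace_labels: List[str] = field(default_factory=list)
    constraint_terms: Dict[str, Dict[str, float]] = field(default_factory=dict)
    fast_spiking_term: float = 0.0
    accepted: bool = False
    diagnostic: Optional[str] = None

    @property
    def total(self) -> float:
        t = sum(sum(d.values()) for d in self.trace_terms)
        t += sum(sum(d.values()) for d in self.constraint_terms.values())
        return t + self.fast_spiking_term


def _log_term(delta: float) -> float:
    return math.log1p(abs(delta))


def _scalar_terms(name: str, tval, mval, out: Dict[str, float], w: float):
    if tval is None:
        return
    if mval is None:
        out[name] = out.get(name, 0.0) + w * _log_term(MISSING_PENALTY)
    else:
        out[name] = out.get(name, 0.0) + w * _log_term(tval - mval)


def feature_error(target: FeatureSet, model: FeatureSet,
                  weights: Dict[str, float], S: Sequence[str]) -> Dict[str, float]:
    """Weighted per-feature error terms for one trace.

    Adaptation-fit parameters (m, c, nisi) are compared piece by piece;
    list-valued features (bw, pbi, nspikes) are compared elementwise on
    sorted values truncated to the shorter list, plus a length-mismatch
    term in the same log form.  A feature present in the target but
    absent in the model contributes a fixed large deviation, so silent
    or degenerate candidates never score better than spiking ones.
    """
    if (target.sfa is not None and model.sfa is not None
            and target.sfa.transform != model.sfa.transform):
        raise ValueError(
            f"sfa transform mismatch: target {target.sfa.transform!r} "
            f"vs model {model.sfa.transform!r}")
    terms: Dict[str, float] = {}
    for f in S:
        w = weights.get(f, 1.0)
        if f in ("fsl", "pss", "rbv"):
            _scalar_terms(f, target.scalar(f), model.scalar(f), terms, w)
        elif f == "nbs":
            _scalar_terms(f, target.nbs, model.nbs, terms, w)
        elif f in ("m", "c", "nisi"):
            npieces = target.sfa.n_pieces if target.sfa is not None else 0
            for p in range(npieces):
                _scalar_terms(f, target.scalar(f, p), model.scalar(f, p), terms, w)
        elif f in ("bw", "pbi", "nspikes"):
            tv = sorted(getattr(target, f))
            mv = sorted(getattr(model, f))
            n = min(len(tv), len(mv))
            tot = sum(_log_term(a - b) for a, b in zip(tv[:n], mv[:n]))
            tot += _log_term(len(tv) - len(mv))
            terms[f] = terms.get(f, 0.0) + w * tot
    return terms


def dynamic_weights(model_class: ClassLabel, target_class: ClassLabel,
                    boundary_distances: Dict[str, float],
                    weight_config: Optional[WeightConfig] = None,
                    S: Sequence[str] = CONTINUOUS_S) -> Dict[str, float]:
    """Per-feature weights from the class comparison (see module docs)."""
    cfg = weight_config or WeightConfig()
    weights = {f: cfg.w_base for f in S}
    if model_class.composite == target_class.composite:
        return weights
    for f, dist in boundary_distances.items():
        if dist > 0:
            weights[f] = cfg.w_base + cfg.w_gain * min(dist, cfg.clip)
    return weights


# ---------------------------------------------------------------------------
# multi-compartment dendritic constraints


def spike_propagation_rate(model: MCModel, source: str, dest: str,
                           n_synapses: int = 200, weight: float = 10.0,
                           syn: Optional[SynapseConfig] = None,
                           config: Optional[SimConfig] = None,
                           extra_current: float = 0.0,
                           t_event: float = 40.0) -> Tuple[float, int, int]:
    """Forward propagation: spikes at ``dest`` per spike initiated at
    ``source`` by a simultaneous multi-synapse barrage.

    Returns (R, n_source, n_dest); R is nan when no source spike was
    initiated (a supplementary ``extra_current`` step may then be
    supplied, mirroring distal compartments that cannot spike from
    synaptic drive alone).
    """
    syn = syn or SynapseConfig()
    config = config or SimConfig(dt=0.05, duration=200.0)
    stims = [Stimulus.synaptic([(t_event, n_synapses, weight)], target=source)]
    if extra_current:
        stims.append(Stimulus.step(extra_current, t_event - 10.0, t_event + 40.0,
                                   target=source))
    trace = simulate(model, stims, config, syn=syn)
    n_src = int(len(trace.spikes[source]))
    n_dst = int(len(trace.spikes[dest]))
    if n_src == 0:
        return math.nan, 0, n_dst
    return n_dst / n_src, n_src, n_dst


def somatic_epsp(model: MCModel, source: str, weight: float = 10.0,
                 syn: Optional[SynapseConfig] = None,
                 config: Optional[SimConfig] = None,
                 t_event: float = 40.0) -> float:
    """Amplitude (mV) of the somatic EPSP evoked by a single synapse at
    ``source``."""
    syn = syn or SynapseConfig()
    config = config or SimConfig(dt=0.05, duration=300.0)
    stim = Stimulus.synaptic([(t_event, 1, weight)], target=source)
    trace = simulate(model, [stim], config, syn=syn)
    v = trace.V[model.soma]
    vr = model.params(model.soma).Vr
    return float(np.max(v[trace.times >= t_event]) - vr)


def _towards_soma(model: MCModel, name: str) -> str:
    """The adjacent compartment on the soma side of ``name``."""
    for link in model.links:
        if link.distal == name:
            return link.proximal
    raise ValueError(f"cannot orient compartment {name!r} toward the soma")


def mc_constraint_errors(model: MCModel,
                         syn: Optional[SynapseConfig] = None,
                         sim_config: Optional[SimConfig] = None,
                         I_hyper: float = -500.0,
                         epsp_range: Tuple[float, float] = (0.1, 0.9),
                         n_synapses: int = 200,
                         syn_weight: float = 10.0,
                         propagation_extra_current: float = 1200.0,
                         ramp: Optional[Stimulus] = None) -> Dict[str, Dict[str, float]]:
    """The four dendritic constraint error terms, per dendritic compartment.

    rheo : decoupled dendrites must not be more excitable than the soma
           (ramp-probed rheobase); error log(1 + (I_soma - I_dend)) when
           I_dend < I_soma, else 0.
    vdef : decoupled dendrites must have higher input resistance, i.e.
           larger steady deflection under a strong hyperpolarizing step;
           error log(1 + (V_soma - V_dend)) when smaller, else 0.
    R    : forward propagation rate of synaptically initiated dendritic
           spikes to the soma-adjacent compartment; error log(1 + (1-R))
           when R < 1, else 0.  A compartment that cannot spike from the
           barrage alone is retried with a supplementary current step.
    epsp : somatic EPSP from a single dendritic synapse must fall inside
           ``epsp_range`` mV; error log(1 + shortfall/overshoot) outside.

    Simulation failures yield the maximal penalty instead of raising, so
    optimization loops survive pathological candidates.
    """
    if model.n_compartments < 2:
        raise ValueError("multi-compartment constraints need >= 2 compartments")
    syn = syn or SynapseConfig()
    out: Dict[str, Dict[str, float]] = {}
    soma = model.soma

    def _rheo(name):
        return rheobase_by_ramp(model.decoupled(name),
                                ramp=ramp, config=sim_config)

    try:
        i_soma = _rheo(soma)
        v_soma = voltage_deflection(model.decoupled(soma), I_hyper, sim_config)
    except (MeasurementInvalid, SimulationDiverged):
        i_soma = v_soma = None

    for name in model.names:
        if name == soma:
            continue
        terms = {"rheo": 0.0, "vdef": 0.0, "R": 0.0, "epsp": 0.0}
        try:
            if i_soma is None:
                raise MeasurementInvalid("somatic reference unavailable")
            i_dend = _rheo(name)
            if i_dend < i_soma:
                terms["rheo"] = _log_term(i_soma - i_dend)
            v_dend = voltage_deflection(model.decoupled(name), I_hyper, sim_config)
            if v_dend < v_soma:
                terms["vdef"] = _log_term(v_soma - v_dend)
        except (MeasurementInvalid, SimulationDiverged):
            terms["rheo"] = terms["vdef"] = _log_term(MISSING_PENALTY)
        try:
            dest = _towards_soma(model, name)
            R, n_src, _ = spike_propagation_rate(
                model, name, dest, n_synapses=n_synapses, weight=syn_weight,
                syn=syn, config=sim_config)
            extra = propagation_extra_current
            while n_src == 0 and extra <= 8 * propagation_extra_current:
                # distal compartments may need a supplementary current step
                # to fire at all; escalate until the source spikes
                R, n_src, _ = spike_propagation_rate(
                    model, name, dest, n_synapses=n_synapses, weight=syn_weight,
                    syn=syn, config=sim_config, extra_current=extra)
                extra *= 2.0
            if n_src == 0:
                terms["R"] = _log_term(MISSING_PENALTY)
            elif R < 1.0:
                terms["R"] = _log_term(1.0 - R)
            epsp = somatic_epsp(model, name, weight=syn_weight, syn=syn,
                                config=sim_config)
            lo, hi = epsp_range
            if epsp < lo:
                terms["epsp"] = _log_term(lo - epsp)
            elif epsp > hi:
                terms["epsp"] = _log_term(epsp - hi)
        except (MeasurementInvalid, SimulationDiverged):
            terms["R"] = terms["epsp"] = _log_term(MISSING_PENALTY)
        out[name] = terms
    return out


# ---------------------------------------------------------------------------
# fast-spiking minimum-frequency constraint


def step_rheobase(model: MCModel, step_ms: float = 500.0, onset: float = 100.0,
                  lo: float = 0.0, hi: float = 1000.0, coarse: float = 10.0,
                  fine: float = 1.0, config: Optional[SimConfig] = None,
                  compartment: Optional[str] = None) -> Optional[float]:
    """Minimum step current (pA, to ``fine`` resolution) eliciting at
    least one spike within a step of ``step_ms``, from rest.

    Distinct from the slow-ramp probe: a step from rest can fire well
    below the quasi-static threshold because the recovery variable has
    not built up.
    """
    name = compartment or model.soma
    cfg = config or SimConfig(dt=0.05, duration=onset + step_ms + 50.0)

    def n_spikes(I):
        tr = simulate(model, Stimulus.step(I, onset, onset + step_ms, target=name), cfg)
        return len(tr.spikes[name])

    first = None
    for I in np.arange(lo + coarse, hi + coarse / 2, coarse):
        if n_spikes(I) >= 1:
            first = I
            break
    if first is None:
        return None
    for I in np.arange(first - coarse + fine, first + fine / 2, fine):
        if n_spikes(I) >= 1:
            return float(I)
    return float(first)


def minimum_firing_frequency(model: MCModel, step_ms: float = 500.0,
                             scan_above: float = 100.0, scan_step: float = 1.0,
                             onset: float = 100.0,
                             config: Optional[SimConfig] = None,
                             compartment: Optional[str] = None) -> Optional[float]:
    """Minimum first-ISI instantaneous frequency (Hz) over step currents
    scanned upward from the step rheobase.

    Returns None when no scanned current produces repetitive firing
    (>= 2 spikes).
    """
    name = compartment or model.soma
    cfg = config or SimConfig(dt=0.05, duration=onset + step_ms + 50.0)
    rheo = step_rheobase(model, step_ms=step_ms, onset=onset, config=cfg,
                         compartment=name, fine=scan_step)
    if rheo is None:
        return None
    fmin = None
    for I in np.arange(rheo, rheo + scan_above + scan_step / 2, scan_step):
        tr = simulate(model, Stimulus.step(I, onset, onset + step_ms, target=name), cfg)
        s = tr.spikes[name]
        if len(s) >= 2:
            f = float(1000.0 / (s[1] - s[0]))
            if fmin is None or f < fmin:
                fmin = f
    return fmin


def fast_spiking_penalty(model: MCModel, target_min_hz: float = 25.0,
                         sim_config: Optional[SimConfig] = None,
                         scan_step: float = 5.0, step_ms: float = 500.0) -> float:
    """log(1 + max(0, target_min_hz - f_min)); maximal when the model
    never fires repetitively over the scan."""
    try:
        fmin = minimum_firing_frequency(model, step_ms=step_ms,
                                        scan_step=scan_step, config=sim_config)
    except SimulationDiverged:
        fmin = None
    if fmin is None:
        return _log_term(MISSING_PENALTY)
    return _log_term(max(0.0, target_min_hz - fmin))


# ---------------------------------------------------------------------------
# whole-candidate evaluation


def evaluate_model(model: MCModel, currents: Sequence[float], spec: TargetSpec,
                   sim_config: Optional[SimConfig] = None,
                   syn: Optional[SynapseConfig] = None) -> ErrorBreakdown:
    """Simulate every target trace, extract and classify features, apply
    the dynamic weighting and sum all error terms.

    ``currents`` holds one stimulation amplitude per target trace (the
    EA's current genes).  The candidate is accepted when its class
    matches the target class for every trace.
    """
    if len(currents) != spec.n_traces:
        raise ValueError("need one stimulation current per target trace")
    crit = spec.criteria
    bd = ErrorBreakdown(accepted=True)
    for tt, I in zip(spec.traces, currents):
        cfg = sim_config or SimConfig(dt=0.1, duration=tt.duration, method="euler")
        if cfg.duration != tt.duration:
            cfg = SimConfig(dt=cfg.dt, duration=tt.duration, method=cfg.method,
                            spike_time_interpolation=cfg.spike_time_interpolation)
        name = tt.target_compartment or model.soma
        try:
            trace = simulate(model, Stimulus.step(I, tt.onset, tt.offset, target=name),
                             cfg, syn=syn)
        except SimulationDiverged as e:
            bd.trace_terms.append({"diverged": MAX_ERROR})
            bd.trace_weights.append({})
            bd.trace_labels.append("diverged")
            bd.accepted = False
            bd.diagnostic = str(e)
            continue
        sp = trace.spikes[name]
        offset = min(tt.offset, tt.duration)
        train = SpikeTrain(sp[(sp >= tt.onset) & (sp <= offset)], tt.onset, offset)
        feats = extract_features(trace, compartment=name,
                                 gap_factor=crit.gap_factor,
                                 sfa_transform=crit.sfa_transform,
                                 sfa_alpha=crit.piecewise_alpha)
        label = classify(trace, train, features=feats, criteria=crit,
                         compartment=name)
        dists = class_distance(feats, tt.label, crit, train=train)
        weights = dynamic_weights(label, tt.label, dists,
                                  spec.weight_config, S=tt.S)
        bd.trace_terms.append(feature_error(tt.features, feats, weights, tt.S))
        bd.trace_weights.append(weights)
        bd.trace_labels.append(label.composite)
        if label.composite != tt.label.composite:
            bd.accepted = False
    if spec.mc_constraints and model.n_compartments >= 2:
        bd.constraint_terms = mc_constraint_errors(model, syn=syn)
    if spec.fast_spiking:
        bd.fast_spiking_term = fast_spiking_penalty(model, spec.min_freq_hz)
    return bd
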