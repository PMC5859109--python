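"""Qualitative spike-pattern classification.

A spike pattern is labelled by a composite class: an ordered (possibly
empty) list of transient elements followed by at most one steady-state
element.

Transient elements
    D      delayed spiking: long latency to the first spike
    ASP.   adapting spiking: spike frequency decreases over time
    TSTUT  transient stuttering: a high-frequency cluster followed by a
           quiescent period and resumed firing
    TSWB   transient slow-wave bursting: TSTUT plus a slow
           after-hyperpolarizing wave between clusters
Steady-state elements
    NASP   non-adapting spiking persisting to the stimulus end
    SLN    silence: a sufficiently long quiescence after the last spike
    PSTUT  persistent stuttering: clusters separated by long gaps to the end
    PSWB   persistent slow-wave bursting

Records that end mid-transient carry only the transient element(s)
(e.g. "ASP.", "D.ASP.").  The numeric thresholds separating these
elements are not part of the model itself; they are configurable
:class:`ClassCriteria`, with defaults calibrated so that the packaged
reference parameter sets reproduce their published labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np

from .features import FeatureSet, SpikeTrain, segment_bursts
from .model import Trace

__all__ = ["ClassCriteria", "ClassLabel", "classify", "class_distance"]

SUBTHRESHOLD = "subthreshold"


@dataclass(frozen=True)
class ClassCriteria:
    """Configurable thresholds for the qualitative class elements.

    delay_abs_ms / delay_ratio
        D fires when fsl > max(delay_abs_ms, delay_ratio * mean ISI).
    sln_pss_abs_ms / sln_pss_ratio
        SLN fires when pss > max(sln_pss_abs_ms, sln_pss_ratio * max ISI).
    asp_slope_min
        ASP fires when the first-piece sfa slope exceeds this value
        (transformed-ISI units per ms) and the slope is statistically
        positive at piecewise_alpha.
    gap_factor
        burst/stutter segmentation threshold (dimensionless, times the
        median ISI).
    swb_dip_mv
        slow-wave detection: inter-cluster voltage dipping at least this
        far below the post-spike reset baseline.
    sfa_transform
        ISI transform used for adaptation fits ("log10" or "identity").
    """

    delay_abs_ms: float = 70.0
    delay_ratio: float = 2.0
    sln_pss_abs_ms: float = 50.0
    sln_pss_ratio: float = 2.0
    asp_slope_min: float = 0.0
    slope_scale: float = 5e-4
    gap_factor: float = 3.0
    swb_dip_mv: float = 10.0
    piecewise_alpha: float = 0.05
    sfa_transform: str = "log10"
    version: str = "1"

    def __post_init__(self):
        for name in ("delay_abs_ms", "delay_ratio", "sln_pss_abs_ms",
                     "sln_pss_ratio", "gap_factor", "swb_dip_mv",
                     "piecewise_alpha", "slope_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"criterion {name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassCriteria":
        return cls(**d)


@dataclass(frozen=True)
class ClassLabel:
    """Composite qualitative class: transient elements + steady state."""

    transient: Tuple[str, ...] = ()
    steady: Optional[str] = None

    def __post_init__(self):
        for el in self.transient:
            if el not in ("D", "ASP", "TSTUT", "TSWB"):
                raise ValueError(f"unknown transient element {el!r}")
        if self.steady not in (None, "SLN", "NASP", "PSTUT", "PSWB", SUBTHRESHOLD):
            raise ValueError(f"unknown steady-state element {self.steady!r}")

    @property
    def composite(self) -> str:
        if self.steady == SUBTHRESHOLD:
            return SUBTHRESHOLD
        parts = list(self.transient) + ([self.steady] if self.steady else [])
        s = ".".join(parts)
        if self.steady is None:
            s += "."
        return s

    def __str__(self) -> str:
        return self.composite

    @classmethod
    def parse(cls, s: str) -> "ClassLabel":
        s = s.strip()
        if s == SUBTHRESHOLD:
            return cls(steady=SUBTHRESHOLD)
        trailing = s.endswith(".")
        parts = [p for p in s.split(".") if p]
        if trailing:
            return cls(transient=tuple(parts), steady=None)
        return cls(transient=tuple(parts[:-1]), steady=parts[-1])


def _delay_threshold(isis: np.ndarray, crit: ClassCriteria) -> float:
    # the delay is judged against the firing it leads into: the first
    # post-delay ISI (late ISIs of strong adapters would inflate a mean)
    post = float(isis[0]) if isis.size else 0.0
    return max(crit.delay_abs_ms, crit.delay_ratio * post)


def _sln_threshold(isis: np.ndarray, crit: ClassCriteria) -> float:
    mx = float(np.max(isis)) if isis.size else 0.0
    return max(crit.sln_pss_abs_ms, crit.sln_pss_ratio * mx)


def _adapting(features: FeatureSet, crit: ClassCriteria):
    """(first piece adapting?, second piece flat?) from the sfa fit."""
    sfa = features.sfa
    if sfa is None:
        return False, False
    def sig_pos(piece):
        if piece.m <= crit.asp_slope_min:
            return False
        if not np.isfinite(piece.m_stderr) or piece.m_stderr == 0:
            return True
        t = (piece.m - crit.asp_slope_min) / piece.m_stderr
        return t > 2.0  # ~one-sided 0.025 level
    first = sig_pos(sfa.pieces[0])
    second_flat = sfa.n_pieces == 2 and not sig_pos(sfa.pieces[1])
    return first, second_flat


def _reset_baseline(trace: Trace, name: str, spikes: np.ndarray) -> float:
    """Median voltage right after each spike reset (the post-spike floor)."""
    dt = trace.times[1] - trace.times[0]
    # +2: the sample at the crossing step is clamped to Vpeak; the next
    # one holds the post-reset voltage
    idx = np.minimum((spikes / dt).astype(int) + 2, trace.times.size - 1)
    return float(np.median(trace.V[name][idx]))


def _slow_wave(trace: Trace, name: str, spikes: np.ndarray, windows,
               crit: ClassCriteria) -> bool:
    """Does V dip >= swb_dip_mv below the reset baseline inside any of the
    given (t0, t1) quiescent windows?"""
    if trace is None or not windows:
        return False
    base = _reset_baseline(trace, name, spikes)
    t = trace.times
    v = trace.V[name]
    for t0, t1 in windows:
        m = (t >= t0) & (t <= t1)
        if np.any(m) and float(np.min(v[m])) <= base - crit.swb_dip_mv:
            return True
    return False


def classify(trace: Optional[Trace], train: SpikeTrain,
             features: Optional[FeatureSet] = None,
             criteria: Optional[ClassCriteria] = None,
             compartment: Optional[str] = None) -> ClassLabel:
    """Assign the composite qualitative class of one spike pattern.

    ``trace`` may be None when only spike times are available; slow-wave
    elements (TSWB/PSWB) then cannot be detected and stutter falls back
    to TSTUT/PSTUT.
    """
    crit = criteria or ClassCriteria()
    if features is None:
        if trace is not None:
            from .features import extract_features
            features = extract_features(trace, compartment=compartment,
                                        gap_factor=crit.gap_factor,
                                        sfa_transform=crit.sfa_transform,
                                        sfa_alpha=crit.piecewise_alpha)
        else:
            from .features import features_from_train
            features = features_from_train(train, gap_factor=crit.gap_factor,
                                           sfa_transform=crit.sfa_transform,
                                           sfa_alpha=crit.piecewise_alpha)
    if train.n_spikes == 0:
        return ClassLabel(steady=SUBTHRESHOLD)
    name = None
    if trace is not None:
        name = compartment or (trace.model.soma if trace.model else next(iter(trace.V)))
    spikes = train.spike_times
    isis = train.isis
    clusters, gaps, nbs, bw, pbi, nspikes = segment_bursts(train, crit.gap_factor)
    fsl = float(spikes[0] - train.stim_onset)
    pss = float(train.stim_offset - spikes[-1])
    transient = []
    if fsl > _delay_threshold(isis, crit):
        transient.append("D")

    if nbs >= 2:
        # stuttering path
        gap_windows = [(c[-1], clusters[i + 1][0]) for i, c in enumerate(clusters[:-1])]
        wave = _slow_wave(trace, name, spikes, gap_windows, crit) if trace is not None else False
        stut, pstut = ("TSWB", "PSWB") if wave else ("TSTUT", "PSTUT")
        last = clusters[-1]
        last_span = float(last[-1] - last[0])
        sln = pss > _sln_threshold(isis, crit) and pss > max(gaps)
        if last_span > max(gaps):
            # stuttering died out: final uninterrupted run is the steady state
            transient.append(stut)
            steady = "SLN" if sln else "NASP"
        elif sln:
            transient.append(stut)
            steady = "SLN"
        else:
            steady = pstut
        return ClassLabel(transient=tuple(transient), steady=steady)

    # single uninterrupted cluster
    sln = pss > _sln_threshold(isis, crit)
    adapting, second_flat = _adapting(features, crit)
    post_sln_wave = False
    if sln and trace is not None:
        post_sln_wave = _slow_wave(trace, name, spikes,
                                   [(spikes[-1], train.stim_offset)], crit)
    if adapting:
        transient.append("ASP")
    elif sln and post_sln_wave and train.n_spikes >= 2:
        # a compact burst followed by a slow wave and silence
        transient.append("TSWB")
    if sln:
        return ClassLabel(transient=tuple(transient), steady="SLN")
    if adapting and not second_flat:
        # record ends while still adapting: transient-only class
        return ClassLabel(transient=tuple(transient), steady=None)
    return ClassLabel(transient=tuple(transient), steady="NASP")


def class_distance(features: FeatureSet, target: ClassLabel,
                   criteria: Optional[ClassCriteria] = None,
                   train: Optional[SpikeTrain] = None) -> Dict[str, float]:
    """Signed, scale-normalized distances from the target class boundary.

    One entry per criterion feature implicated in the target class
    definition; negative values mean the feature satisfies the
    corresponding criterion (inside the class region), positive values
    are proportional to the shortfall.  Dimensionless.
    """
    crit = criteria or ClassCriteria()
    out: Dict[str, float] = {}
    isis = train.isis if train is not None else np.empty(0)
    fsl = features.fsl
    pss = features.pss

    if fsl is not None:
        thr = _delay_threshold(isis, crit)
        d = (thr - fsl) / thr
        out["fsl"] = d if "D" in target.transient else -d
    elif "D" in target.transient:
        out["fsl"] = 1.0

    if pss is not None:
        thr = _sln_threshold(isis, crit)
        d = (thr - pss) / thr
        if target.steady == "SLN":
            out["pss"] = d
        elif target.steady in ("NASP", "PSTUT", "PSWB"):
            out["pss"] = -d
    elif target.steady == "SLN":
        out["pss"] = 1.0

    wants_asp = "ASP" in target.transient
    slope = features.sfa.pieces[0].m if features.sfa is not None else None
    if slope is not None:
        d = (crit.asp_slope_min - slope) / crit.slope_scale
        out["m"] = d if wants_asp else -d
    elif wants_asp:
        out["m"] = 1.0

    wants_stutter = (target.steady in ("PSTUT", "PSWB")
                     or any(e in ("TSTUT", "TSWB") for e in target.transient))
    need = 2 if wants_stutter else 1
    d = (need - features.nbs) / need
    out["nbs"] = d if wants_stutter else -d
    return out
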