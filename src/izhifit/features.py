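"""Quantitative spike-pattern and subthreshold feature extraction.

Features are measured on a spike-time list referenced to a stimulus
window (first-spike latency, post-spike silence, burst segmentation) and
on the voltage trace itself (post-inhibitory rebound).  Spike-frequency
adaptation is quantified by (piecewise) linear regression of transformed
inter-spike intervals against their latencies; the default transform is
log10 of the ISI in ms, and the transform used is recorded in every fit
so that slopes and intercepts are never compared across conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .model import Trace

__all__ = [
    "SpikeTrain",
    "SfaFit",
    "FeatureSet",
    "isi_latency_pairs",
    "first_spike_latency",
    "post_spike_silence",
    "fit_sfa",
    "segment_bursts",
    "rebound_amplitude",
    "instantaneous_frequencies",
    "extract_features",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (ms, strictly increasing) within a stimulus window."""

    spike_times: np.ndarray
    stim_onset: float
    stim_offset: float

    def __post_init__(self):
        t = np.asarray(self.spike_times, dtype=np.float64)
        object.__setattr__(self, "spike_times", t)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def isis(self) -> np.ndarray:
        return np.diff(self.spike_times)

    def shifted(self, delta: float) -> "SpikeTrain":
        return SpikeTrain(self.spike_times + delta,
                          self.stim_onset + delta, self.stim_offset + delta)


@dataclass(frozen=True)
class SfaPiece:
    m: float          # slope, transformed-ISI units per ms of latency
    c: float          # intercept, transformed-ISI units
    n_isi: int
    m_stderr: float = math.nan
    sse: float = math.nan


@dataclass(frozen=True)
class SfaFit:
    """(Piecewise) linear fit of transformed ISI against latency."""

    pieces: Tuple[SfaPiece, ...]
    transform: str = "log10"
    breakpoint: Optional[float] = None  # latency ms, two-piece fits only

    @property
    def n_pieces(self) -> int:
        return len(self.pieces)

    @property
    def slope(self) -> float:
        return self.pieces[0].m

    @property
    def intercept(self) -> float:
        return self.pieces[0].c


@dataclass
class FeatureSet:
    """The measurable features of one (model, stimulus) pair.

    Absent features are None (e.g. sfa for a single-spike trace).
    Units: latencies/widths/intervals in ms, rbv in mV, frequencies in Hz.
    """

    fsl: Optional[float] = None
    pss: Optional[float] = None
    sfa: Optional[SfaFit] = None
    nbs: int = 0
    bw: Tuple[float, ...] = ()
    pbi: Tuple[float, ...] = ()
    nspikes: Tuple[int, ...] = ()
    rbv: Optional[float] = None
    rebound_spike: bool = False
    min_inst_freq: Optional[float] = None
    first_isi_freq: Optional[float] = None

    @property
    def total_spikes(self) -> int:
        return int(sum(self.nspikes))

    def scalar(self, name: str, piece: int = 0):
        """Look a scalar feature up by its short name (``m``/``c``/``nisi``
        address the adaptation fit pieces)."""
        if name in ("m", "c", "nisi"):
            if self.sfa is None or piece >= self.sfa.n_pieces:
                return None
            p = self.sfa.pieces[piece]
            return {"m": p.m, "c": p.c, "nisi": p.n_isi}[name]
        if name == "nspikes_total":
            return self.total_spikes
        return getattr(self, name)

    def to_dict(self) -> dict:
        d = {
            "fsl_ms": self.fsl,
            "pss_ms": self.pss,
            "nbs": self.nbs,
            "bw_ms": list(self.bw),
            "pbi_ms": list(self.pbi),
            "nspikes": list(self.nspikes),
            "rbv_mV": self.rbv,
            "rebound_spike": self.rebound_spike,
            "min_inst_freq_hz": self.min_inst_freq,
            "first_isi_freq_hz": self.first_isi_freq,
        }
        if self.sfa is not None:
            d["sfa"] = {
                "transform": self.sfa.transform,
                "breakpoint_ms": self.sfa.breakpoint,
                "pieces": [
                    {"m": p.m, "c": p.c, "n_isi": p.n_isi} for p in self.sfa.pieces
                ],
            }
        else:
            d["sfa"] = None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        sfa = None
        if d.get("sfa") is not None:
            s = d["sfa"]
            sfa = SfaFit(
                pieces=tuple(SfaPiece(m=p["m"], c=p["c"], n_isi=int(p["n_isi"]))
                             for p in s["pieces"]),
                transform=s.get("transform", "log10"),
                breakpoint=s.get("breakpoint_ms"))
        return cls(
            fsl=d.get("fsl_ms"), pss=d.get("pss_ms"), sfa=sfa,
            nbs=int(d.get("nbs", 0)),
            bw=tuple(d.get("bw_ms", ())), pbi=tuple(d.get("pbi_ms", ())),
            nspikes=tuple(int(n) for n in d.get("nspikes", ())),
            rbv=d.get("rbv_mV"), rebound_spike=bool(d.get("rebound_spike", False)),
            min_inst_freq=d.get("min_inst_freq_hz"),
            first_isi_freq=d.get("first_isi_freq_hz"))


def isi_latency_pairs(train: SpikeTrain) -> np.ndarray:
    """(latency, ISI) pairs, the latency of each ISI referenced to the
    second spike of the pair (both in ms from stimulus onset)."""
    if train.n_spikes < 2:
        raise ValueError("no ISIs: need at least 2 spikes")
    t = train.spike_times
    return np.column_stack([t[1:] - train.stim_onset, np.diff(t)])


def first_spike_latency(train: SpikeTrain) -> float:
    if train.n_spikes < 1:
        raise ValueError("no spikes: first-spike latency undefined")
    return float(train.spike_times[0] - train.stim_onset)


def post_spike_silence(train: SpikeTrain) -> float:
    if train.n_spikes < 1:
        raise ValueError("no spikes: post-spike silence undefined")
    return float(train.stim_offset - train.spike_times[-1])


def _linfit(x: np.ndarray, y: np.ndarray) -> SfaPiece:
    n = x.size
    if n == 2:
        m = (y[1] - y[0]) / (x[1] - x[0])
        return SfaPiece(m=float(m), c=float(y[0] - m * x[0]), n_isi=2,
                        m_stderr=math.inf, sse=0.0)
    res = stats.linregress(x, y)
    pred = res.intercept + res.slope * x
    sse = float(np.sum((y - pred) ** 2))
    return SfaPiece(m=float(res.slope), c=float(res.intercept), n_isi=int(n),
                    m_stderr=float(res.stderr), sse=sse)


def fit_sfa(pairs: np.ndarray, max_pieces: int = 2, transform: str = "log10",
            alpha: float = 0.05, min_piece: int = 2) -> SfaFit:
    """Least-squares fit of transformed ISI vs latency, optionally piecewise.

    A two-piece fit (independent segments, breakpoint chosen by brute
    force over all admissible splits) is preferred over the single line
    only when an F-test on the residual reduction fires at ``alpha``.
    Needs >= 3 pairs for one piece, >= 5 for two.
    """
    pairs = np.asarray(pairs, dtype=np.float64)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (latency, ISI)")
    x = pairs[:, 0]
    if transform == "log10":
        y = np.log10(pairs[:, 1])
    elif transform == "identity":
        y = pairs[:, 1].copy()
    else:
        raise ValueError(f"unknown sfa transform {transform!r}")
    n = x.size
    if n < 3:
        raise ValueError("sfa fit needs at least 3 ISI pairs")
    single = _linfit(x, y)
    fit1 = SfaFit(pieces=(single,), transform=transform)
    if max_pieces < 2 or n < 5:
        return fit1
    # O(n) breakpoint scan via prefix sums of the normal equations
    cx, cy = np.cumsum(x), np.cumsum(y)
    cxx, cxy, cyy = np.cumsum(x * x), np.cumsum(x * y), np.cumsum(y * y)

    def _seg_sse(lo, hi):  # [lo, hi) with hi - lo >= 2
        m = hi - lo
        sx = cx[hi - 1] - (cx[lo - 1] if lo else 0.0)
        sy = cy[hi - 1] - (cy[lo - 1] if lo else 0.0)
        sxx = cxx[hi - 1] - (cxx[lo - 1] if lo else 0.0)
        sxy = cxy[hi - 1] - (cxy[lo - 1] if lo else 0.0)
        syy = cyy[hi - 1] - (cyy[lo - 1] if lo else 0.0)
        vx = sxx - sx * sx / m
        vy = syy - sy * sy / m
        cov = sxy - sx * sy / m
        if vx <= 0:
            return np.inf
        return max(vy - cov * cov / vx, 0.0)

    best = None
    for j in range(min_piece, n - min_piece + 1):
        sse = _seg_sse(0, j) + _seg_sse(j, n)
        if best is None or sse < best[0]:
            best = (sse, j)
    j = best[1]
    p1 = _linfit(x[:j], y[:j])
    p2 = _linfit(x[j:], y[j:])
    sse2 = p1.sse + p2.sse
    sse1 = single.sse
    # F-test: 2 -> 4 regression parameters (+1 for the free breakpoint)
    df_extra, df_resid = 3, n - 5
    if df_resid <= 0 or sse1 <= 0:
        return fit1
    if sse2 <= 0:
        pval = 0.0
    else:
        F = ((sse1 - sse2) / df_extra) / (sse2 / df_resid)
        pval = float(stats.f.sf(F, df_extra, df_resid))
    if pval < alpha:
        bp = 0.5 * (x[j - 1] + x[j])
        return SfaFit(pieces=(p1, p2), transform=transform, breakpoint=float(bp))
    return fit1


def segment_bursts(train: SpikeTrain, gap_factor: float = 3.0):
    """Partition spikes into maximal clusters separated by long gaps.

    A gap is an ISI exceeding ``gap_factor`` times the median ISI (the
    minimum ISI when fewer than 4 spikes make the median unreliable).
    Returns (clusters, gaps, nbs, bw, pbi, nspikes): clusters are arrays
    of spike times, bw the per-cluster widths, pbi the inter-cluster
    quiescent intervals.
    """
    if train.n_spikes < 1:
        raise ValueError("burst segmentation needs at least 1 spike")
    t = train.spike_times
    if t.size == 1:
        return [t], [], 1, (0.0,), (), (1,)
    isis = np.diff(t)
    ref = np.median(isis) if t.size >= 4 else np.min(isis)
    thr = gap_factor * ref
    cut = np.nonzero(isis > thr)[0]
    clusters = np.split(t, cut + 1)
    gaps = [float(isis[i]) for i in cut]
    bw = tuple(float(c[-1] - c[0]) for c in clusters)
    pbi = tuple(gaps)
    nspikes = tuple(int(c.size) for c in clusters)
    return clusters, gaps, len(clusters), bw, pbi, nspikes


def rebound_amplitude(trace: Trace, stim_offset: float,
                      window_ms: float = 500.0,
                      compartment: Optional[str] = None):
    """Post-stimulus rebound: max of (V - Vr) over the window after the
    stimulus ends, in mV.  Returns (rbv, rebound_spike_flag)."""
    name = compartment or (trace.model.soma if trace.model else next(iter(trace.V)))
    vr = trace.model.params(name).Vr if trace.model else trace.V[name][0]
    tmask = (trace.times >= stim_offset) & (trace.times <= stim_offset + window_ms)
    if not np.any(tmask):
        raise ValueError("stimulus offset lies outside the recorded trace")
    v = trace.V[name][tmask]
    rbv = float(np.max(v) - vr)
    spikes = trace.spikes.get(name, np.empty(0))
    flag = bool(np.any((spikes >= stim_offset) & (spikes <= stim_offset + window_ms)))
    return rbv, flag


def instantaneous_frequencies(train: SpikeTrain):
    """Per-ISI instantaneous frequencies (1000/ISI, Hz) plus the
    first-ISI and mean-ISI summary frequencies."""
    if train.n_spikes < 2:
        raise ValueError("instantaneous frequencies need at least 2 spikes")
    isis = train.isis
    freqs = 1000.0 / isis
    return freqs, float(freqs[0]), float(1000.0 / np.mean(isis))


def features_from_train(train: SpikeTrain, gap_factor: float = 3.0,
                        sfa_transform: str = "log10", sfa_alpha: float = 0.05,
                        max_pieces: int = 2) -> FeatureSet:
    """Spike-time-only feature battery (no voltage-dependent features)."""
    fs = FeatureSet()
    if train.n_spikes == 0:
        return fs
    fs.fsl = first_spike_latency(train)
    fs.pss = post_spike_silence(train)
    _, _, fs.nbs, fs.bw, fs.pbi, fs.nspikes = segment_bursts(train, gap_factor)
    if train.n_spikes >= 2:
        freqs, fs.first_isi_freq, _ = instantaneous_frequencies(train)
        fs.min_inst_freq = float(np.min(freqs))
    if train.n_spikes >= 4 and fs.nbs == 1:
        fs.sfa = fit_sfa(isi_latency_pairs(train), max_pieces=max_pieces,
                         transform=sfa_transform, alpha=sfa_alpha)
    return fs


def extract_features(trace: Trace, compartment: Optional[str] = None,
                     gap_factor: float = 3.0, sfa_transform: str = "log10",
                     sfa_alpha: float = 0.05, max_pieces: int = 2,
                     rebound_window_ms: float = 500.0) -> FeatureSet:
    """Full feature battery for one simulated (or loaded) trace.

    The stimulus window is taken from the first stimulus attached to the
    trace; a hyperpolarizing step additionally yields the rebound
    amplitude.
    """
    name = compartment or (trace.model.soma if trace.model else next(iter(trace.V)))
    stim = trace.stimuli[0]
    onset, offset = stim.onset, min(stim.offset, float(trace.times[-1]))
    spikes = trace.spikes[name]
    fs = FeatureSet()
    hyper = stim.kind == "step" and stim.amplitude < 0
    if hyper and offset < trace.times[-1]:
        fs.rbv, fs.rebound_spike = rebound_amplitude(
            trace, offset, window_ms=rebound_window_ms, compartment=name)
    in_win = spikes[(spikes >= onset) & (spikes <= offset)]
    if in_win.size == 0:
        return fs
    train = SpikeTrain(in_win, onset, offset)
    spiked = features_from_train(train, gap_factor=gap_factor,
                                 sfa_transform=sfa_transform,
                                 sfa_alpha=sfa_alpha, max_pieces=max_pieces)
    spiked.rbv, spiked.rebound_spike = fs.rbv, fs.rebound_spike
    return spiked
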