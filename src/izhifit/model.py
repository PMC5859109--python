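"""Domain types for single- and multi-compartment Izhikevich models.

The nine-parameter Izhikevich formalism describes each compartment by a
quadratic voltage equation coupled to a linear recovery variable::

    C dV/dt = k (V - Vr)(V - Vt) - U + I
      dU/dt = a (b (V - Vr) - U)
    if V >= Vpeak:  V <- Vmin,  U <- U + d

Units are fixed throughout the package: time in ms, voltage in mV,
current in pA, capacitance in pF, conductance in nS.

Multi-compartment models are unbranched chains of compartments joined by
asymmetric resistive links: a link with conductance G and asymmetry share
P in [0.01, 0.99] contributes the outward current G*P*(V_prox - V_dist)
at its proximal (soma-ward) end and G*(1-P)*(V_dist - V_prox) at its
distal end, so current flows from the depolarized to the hyperpolarized
side with direction-dependent attenuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "CompartmentParams",
    "CouplingLink",
    "MCModel",
    "Stimulus",
    "SynapseConfig",
    "SimConfig",
    "Trace",
    "SimulationDiverged",
]

PARAM_NAMES = ("k", "a", "b", "d", "C", "Vr", "Vt", "Vpeak", "Vmin")


class SimulationDiverged(RuntimeError):
    """Raised when the integrator produces a non-finite state."""

    def __init__(self, compartment: str, time_ms: float):
        self.compartment = compartment
        self.time_ms = time_ms
        super().__init__(
            f"non-finite state in compartment {compartment!r} at t={time_ms:.3f} ms"
        )


@dataclass(frozen=True)
class CompartmentParams:
    """The nine Izhikevich parameters of one compartment.

    k : spike-upstroke shape factor (pA/mV^2)
    a : recovery time constant (1/ms)
    b : V-U coupling (nS)
    d : after-spike recovery increment (pA)
    C : capacitance (pF)
    Vr, Vt : resting and threshold potentials (mV)
    Vpeak : spike cutoff (mV)
    Vmin : after-spike voltage reset (mV)
    """

    k: float
    a: float
    b: float
    d: float
    C: float
    Vr: float
    Vt: float
    Vpeak: float
    Vmin: float

    def __post_init__(self):
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")
        if not self.Vr < self.Vt:
            raise ValueError(f"Vr must lie below Vt ({self.Vr} >= {self.Vt})")
        if not self.Vpeak > self.Vt:
            raise ValueError(f"Vpeak must lie above Vt ({self.Vpeak} <= {self.Vt})")
        if not self.Vmin < self.Vpeak:
            raise ValueError(f"Vmin must lie below Vpeak ({self.Vmin} >= {self.Vpeak})")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=np.float64)

    @classmethod
    def from_dict(cls, d: dict) -> "CompartmentParams":
        return cls(**{n: float(d[n]) for n in PARAM_NAMES})

    def to_dict(self) -> dict:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    def replace(self, **kw) -> "CompartmentParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CouplingLink:
    """A resistive link between two adjacent compartments.

    ``proximal`` names the soma-ward end; ``P`` scales the coupling
    current on that side, ``1 - P`` on the distal side.
    """

    proximal: str
    distal: str
    G: float
    P: float

    def __post_init__(self):
        if self.G < 0:
            raise ValueError(f"coupling conductance must be >= 0, got {self.G}")
        if not 0.01 <= self.P <= 0.99:
            raise ValueError(f"asymmetry share P must lie in [0.01, 0.99], got {self.P}")


@dataclass(frozen=True)
class MCModel:
    """An ordered chain of named compartments plus coupling links.

    All compartments share the same resting potential Vr; the single
    compartment case is ``c == 1`` with no links.
    """

    compartments: tuple  # of (name, CompartmentParams)
    links: tuple = ()
    soma: str = ""

    def __post_init__(self):
        comps = tuple((str(n), p) for n, p in self.compartments)
        object.__setattr__(self, "compartments", comps)
        object.__setattr__(self, "links", tuple(self.links))
        if not comps:
            raise ValueError("model needs at least one compartment")
        names = [n for n, _ in comps]
        if len(set(names)) != len(names):
            raise ValueError("compartment names must be unique")
        soma = self.soma or names[0]
        object.__setattr__(self, "soma", soma)
        if soma not in names:
            raise ValueError(f"unknown somatic compartment {soma!r}")
        vrs = {p.Vr for _, p in comps}
        if len(vrs) > 1 and (max(vrs) - min(vrs)) > 1e-9:
            raise ValueError("all compartments must share the same Vr")
        for link in self.links:
            for end in (link.proximal, link.distal):
                if end not in names:
                    raise ValueError(f"link references unknown compartment {end!r}")
        if len(self.links) != len(comps) - 1:
            raise ValueError("links must form a chain: expected c-1 links")

    @classmethod
    def single(cls, params: CompartmentParams, name: str = "soma") -> "MCModel":
        return cls(compartments=((name, params),), links=(), soma=name)

    @property
    def names(self) -> list:
        return [n for n, _ in self.compartments]

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def params(self, name: str) -> CompartmentParams:
        for n, p in self.compartments:
            if n == name:
                return p
        raise KeyError(name)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def decoupled(self, name: str) -> "MCModel":
        """The named compartment simulated in isolation (all links removed)."""
        return MCModel.single(self.params(name), name=name)

    def param_arrays(self) -> tuple:
        """(c, 9) parameter matrix and (n_links, 4) link matrix for the kernels."""
        pmat = np.stack([p.as_array() for _, p in self.compartments])
        if self.links:
            lmat = np.array(
                [
                    [self.index(l.proximal), self.index(l.distal), l.G, l.P]
                    for l in self.links
                ],
                dtype=np.float64,
            )
        else:
            lmat = np.zeros((0, 4), dtype=np.float64)
        return pmat, lmat

    def to_dict(self) -> dict:
        return {
            "soma": self.soma,
            "compartments": [{"name": n, **p.to_dict()} for n, p in self.compartments],
            "links": [
                {"proximal": l.proximal, "distal": l.distal, "G": l.G, "P": l.P}
                for l in self.links
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MCModel":
        comps = tuple(
            (c["name"], CompartmentParams.from_dict(c)) for c in d["compartments"]
        )
        links = tuple(
            CouplingLink(l["proximal"], l["distal"], float(l["G"]), float(l["P"]))
            for l in d.get("links", ())
        )
        return cls(compartments=comps, links=links, soma=d.get("soma", ""))


@dataclass(frozen=True)
class Stimulus:
    """A current stimulus delivered to one compartment.

    kind:
      step            constant ``amplitude`` pA on [onset, offset)
      ramp            staircase ramp rising by ``slope * resolution`` pA
                      every ``resolution`` ms from onset
      synaptic_events transient synaptic currents; ``events`` is a list of
                      (time ms, synapse count, weight)
    """

    kind: str
    target: str = "soma"
    onset: float = 0.0
    offset: float = np.inf
    amplitude: float = 0.0
    slope: float = 0.0
    resolution: float = 1.0
    events: tuple = ()

    def __post_init__(self):
        if self.kind not in ("step", "ramp", "synaptic_events"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if not self.onset < self.offset:
            raise ValueError("stimulus onset must precede offset")
        if self.kind == "ramp" and not self.resolution > 0:
            raise ValueError("ramp resolution must be positive")
        if self.kind == "synaptic_events":
            for t, n, w in self.events:
                if n < 0:
                    raise ValueError(f"negative synapse count {n}")

    @classmethod
    def step(cls, amplitude, onset, offset, target="soma"):
        return cls("step", target=target, onset=onset, offset=offset, amplitude=amplitude)

    @classmethod
    def ramp(cls, slope, onset, offset, target="soma", resolution=1.0):
        return cls("ramp", target=target, onset=onset, offset=offset,
                   slope=slope, resolution=resolution)

    @classmethod
    def synaptic(cls, events, target="soma", onset=0.0, offset=np.inf):
        return cls("synaptic_events", target=target, onset=onset, offset=offset,
                   events=tuple(tuple(e) for e in events))

    def drive(self, t_half: np.ndarray, syn: "SynapseConfig") -> np.ndarray:
        """Stimulus drive sampled on a time grid: injected current (pA)
        for step/ramp stimuli and cuba synapses, open conductance (nS)
        for coba synapses."""
        i = np.zeros_like(t_half)
        if self.kind == "step":
            m = (t_half >= self.onset) & (t_half < self.offset)
            i[m] = self.amplitude
        elif self.kind == "ramp":
            m = (t_half >= self.onset) & (t_half < self.offset)
            nsteps = np.floor((t_half[m] - self.onset) / self.resolution) + 1.0
            i[m] = self.slope * self.resolution * nsteps
        else:
            for t0, n, w in self.events:
                m = t_half >= t0
                i[m] += n * syn.peak_drive(w) * np.exp(-(t_half[m] - t0) / syn.tau_ms)
        return i


@dataclass(frozen=True)
class SynapseConfig:
    """Excitatory synapse kernel: instantaneous rise, single-exponential
    decay with time constant ``tau_ms``.

    mode "coba" (default): conductance-based; one synapse of weight w
    opens ``gain * w`` nS with reversal potential ``E_mV``, so the
    injected current is g(t) * (E - V).  mode "cuba": current-based; one
    synapse injects ``gain * w`` pA directly.  N simultaneous synapses
    scale the drive by N.
    """

    tau_ms: float = 5.0
    gain: float = 1.0
    mode: str = "coba"
    E_mV: float = 0.0

    def __post_init__(self):
        if self.mode not in ("coba", "cuba"):
            raise ValueError(f"unknown synapse mode {self.mode!r}")
        if self.tau_ms <= 0:
            raise ValueError("synaptic decay time constant must be positive")

    def peak_drive(self, weight: float) -> float:
        """Peak drive of one synapse: nS (coba) or pA (cuba)."""
        return self.gain * weight


@dataclass(frozen=True)
class SimConfig:
    """Integration settings (the model itself does not prescribe them)."""

    dt: float = 0.05
    duration: float = 1000.0
    method: str = "rk4"
    spike_time_interpolation: bool = True
    record_all_compartments: bool = True
    settle_ms: float = 0.0
    record_u: bool = False

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.method not in ("euler", "rk4"):
            raise ValueError(f"unknown integration method {self.method!r}")


@dataclass
class Trace:
    """Simulated voltage (and optionally recovery) per compartment."""

    times: np.ndarray
    V: dict
    spikes: dict
    stimuli: tuple
    U: Optional[dict] = None
    model: Optional[MCModel] = None
    config: Optional[SimConfig] = None

    def spike_train(self, compartment: Optional[str] = None) -> np.ndarray:
        name = compartment or (self.model.soma if self.model else next(iter(self.spikes)))
        return self.spikes[name]

    def voltage(self, compartment: Optional[str] = None) -> np.ndarray:
        name = compartment or (self.model.soma if self.model else next(iter(self.V)))
        return self.V[name]

    def to_frame(self):
        import pandas as pd

        data = {"time_ms": self.times}
        for name, v in self.V.items():
            data[f"V_{name}"] = v
        if self.U is not None:
            for name, u in self.U.items():
                data[f"U_{name}"] = u
        return pd.DataFrame(data)
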