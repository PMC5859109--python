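"""Hybrid continuous/reset integration of Izhikevich models.

Between spikes the dynamics are smooth and are integrated with a
fixed-step scheme (RK4 by default, forward Euler selectable for speed in
optimizer inner loops).  After each step, any compartment whose voltage
has reached its spike cutoff Vpeak records a spike (with linear
interpolation of the crossing time within the step), has the recorded
sample clamped to Vpeak, and is reset to (Vmin, U + d) before the next
step.  Stimulus currents are pre-sampled on a half-step grid so the RK4
stages see the correct current at t, t + dt/2 and t + dt.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .model import (
    CompartmentParams,
    MCModel,
    SimConfig,
    SimulationDiverged,
    Stimulus,
    SynapseConfig,
    Trace,
)

__all__ = [
    "simulate",
    "subthreshold_fixed_point",
    "rheobase_by_ramp",
    "voltage_deflection",
    "synaptic_current",
    "MeasurementInvalid",
]

_MAX_SPIKES = 4000


class MeasurementInvalid(RuntimeError):
    """A protocol measurement was contaminated (e.g. a spike during a
    hyperpolarizing step)."""


@njit(cache=True)
def _step_derivs(V, U, iext, gsyn, esyn, pmat, lmat, dV, dU):
    nc = pmat.shape[0]
    for x in range(nc):
        dV[x] = 0.0
    # asymmetric coupling: outward current G*share*(V_self - V_other)
    for l in range(lmat.shape[0]):
        ip = int(lmat[l, 0])
        idist = int(lmat[l, 1])
        G = lmat[l, 2]
        P = lmat[l, 3]
        dV[ip] -= G * P * (V[ip] - V[idist])
        dV[idist] -= G * (1.0 - P) * (V[idist] - V[ip])
    for x in range(nc):
        k = pmat[x, 0]
        a = pmat[x, 1]
        b = pmat[x, 2]
        C = pmat[x, 4]
        Vr = pmat[x, 5]
        Vt = pmat[x, 6]
        isyn = gsyn[x] * (esyn - V[x])
        dV[x] = (k * (V[x] - Vr) * (V[x] - Vt) - U[x] + iext[x] + isyn + dV[x]) / C
        dU[x] = a * (b * (V[x] - Vr) - U[x])


@njit(cache=True)
def _integrate(pmat, lmat, I_half, G_half, esyn, dt, n_steps, rk4, interp, v0, u0,
               Vrec, Urec, spike_t, spike_n):
    nc = pmat.shape[0]
    V = v0.copy()
    U = u0.copy()
    Vold = np.empty(nc)
    dV1 = np.empty(nc); dU1 = np.empty(nc)
    dV2 = np.empty(nc); dU2 = np.empty(nc)
    dV3 = np.empty(nc); dU3 = np.empty(nc)
    dV4 = np.empty(nc); dU4 = np.empty(nc)
    Vt_ = np.empty(nc); Ut_ = np.empty(nc)
    for x in range(nc):
        Vrec[0, x] = V[x]
        Urec[0, x] = U[x]
    for i in range(n_steps):
        for x in range(nc):
            Vold[x] = V[x]
        if rk4:
            _step_derivs(V, U, I_half[2 * i], G_half[2 * i], esyn, pmat, lmat, dV1, dU1)
            for x in range(nc):
                Vt_[x] = V[x] + 0.5 * dt * dV1[x]
                Ut_[x] = U[x] + 0.5 * dt * dU1[x]
            _step_derivs(Vt_, Ut_, I_half[2 * i + 1], G_half[2 * i + 1], esyn, pmat, lmat, dV2, dU2)
            for x in range(nc):
                Vt_[x] = V[x] + 0.5 * dt * dV2[x]
                Ut_[x] = U[x] + 0.5 * dt * dU2[x]
            _step_derivs(Vt_, Ut_, I_half[2 * i + 1], G_half[2 * i + 1], esyn, pmat, lmat, dV3, dU3)
            for x in range(nc):
                Vt_[x] = V[x] + dt * dV3[x]
                Ut_[x] = U[x] + dt * dU3[x]
            _step_derivs(Vt_, Ut_, I_half[2 * i + 2], G_half[2 * i + 2], esyn, pmat, lmat, dV4, dU4)
            for x in range(nc):
                V[x] += dt / 6.0 * (dV1[x] + 2.0 * dV2[x] + 2.0 * dV3[x] + dV4[x])
                U[x] += dt / 6.0 * (dU1[x] + 2.0 * dU2[x] + 2.0 * dU3[x] + dU4[x])
        else:
            _step_derivs(V, U, I_half[2 * i], G_half[2 * i], esyn, pmat, lmat, dV1, dU1)
            for x in range(nc):
                V[x] += dt * dV1[x]
                U[x] += dt * dU1[x]
        t_next = (i + 1) * dt
        for x in range(nc):
            if not (math.isfinite(V[x]) and math.isfinite(U[x])):
                return x, t_next
            vpeak = pmat[x, 7]
            if V[x] >= vpeak:
                if interp and V[x] > Vold[x]:
                    frac = (vpeak - Vold[x]) / (V[x] - Vold[x])
                    if frac < 0.0:
                        frac = 0.0
                    elif frac > 1.0:
                        frac = 1.0
                    ts = i * dt + frac * dt
                else:
                    ts = t_next
                if spike_n[x] < spike_t.shape[1]:
                    spike_t[x, spike_n[x]] = ts
                    spike_n[x] += 1
                Vrec[i + 1, x] = vpeak
                V[x] = pmat[x, 8]
                U[x] += pmat[x, 3]
            else:
                Vrec[i + 1, x] = V[x]
            Urec[i + 1, x] = U[x]
    return -1, 0.0


def _half_grid_drives(model: MCModel, stimuli: Sequence[Stimulus],
                      n_steps: int, dt: float, syn: SynapseConfig):
    """Injected current (pA) and synaptic conductance (nS) per half-step
    sample and compartment."""
    t_half = np.arange(2 * n_steps + 1) * (dt / 2.0)
    I = np.zeros((2 * n_steps + 1, model.n_compartments))
    G = np.zeros_like(I)
    names = model.names
    for stim in stimuli:
        if stim.target not in names:
            raise ValueError(
                f"stimulus targets unknown compartment {stim.target!r}; "
                f"model has {names}"
            )
        dest = G if (stim.kind == "synaptic_events" and syn.mode == "coba") else I
        dest[:, model.index(stim.target)] += stim.drive(t_half, syn)
    return I, G


def simulate(model: MCModel, stimuli, config: SimConfig,
             syn: Optional[SynapseConfig] = None,
             v0: Optional[np.ndarray] = None,
             u0: Optional[np.ndarray] = None) -> Trace:
    """Integrate the model under the given stimuli.

    Initial conditions default to the exact rest state (Vr, 0).  Returns
    a :class:`~izhifit.model.Trace` with per-compartment voltage samples
    and spike times; raises :class:`SimulationDiverged` if the state
    becomes non-finite.
    """
    if isinstance(model, CompartmentParams):
        model = MCModel.single(model)
    if isinstance(stimuli, Stimulus):
        stimuli = [stimuli]
    syn = syn or SynapseConfig()
    nc = model.n_compartments
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    I_half, G_half = _half_grid_drives(model, stimuli, n_steps, dt, syn)
    pmat, lmat = model.param_arrays()
    if v0 is None:
        v0 = pmat[:, 5].copy()
    else:
        v0 = np.asarray(v0, dtype=np.float64).copy()
    if u0 is None:
        u0 = np.zeros(nc)
    else:
        u0 = np.asarray(u0, dtype=np.float64).copy()
    Vrec = np.empty((n_steps + 1, nc))
    Urec = np.empty((n_steps + 1, nc))
    spike_t = np.empty((nc, _MAX_SPIKES))
    spike_n = np.zeros(nc, dtype=np.int64)
    bad, t_bad = _integrate(pmat, lmat, I_half, G_half, syn.E_mV, dt, n_steps,
                            config.method == "rk4",
                            config.spike_time_interpolation,
                            v0, u0, Vrec, Urec, spike_t, spike_n)
    if bad >= 0:
        raise SimulationDiverged(model.names[bad], t_bad)
    times = np.arange(n_steps + 1) * dt
    names = model.names
    V = {n: Vrec[:, x] for x, n in enumerate(names)}
    U = {n: Urec[:, x] for x, n in enumerate(names)} if config.record_u else None
    spikes = {n: spike_t[x, : spike_n[x]].copy() for x, n in enumerate(names)}
    return Trace(times=times, V=V, spikes=spikes, stimuli=tuple(stimuli),
                 U=U, model=model, config=config)


def subthreshold_fixed_point(params: CompartmentParams, I: float) -> Optional[float]:
    """Analytic subthreshold equilibrium voltage under constant current I.

    Solves ``k (V - Vr)(V - Vt) - b (V - Vr) + I = 0`` (the steady state
    has U = b (V - Vr)) and returns the stable root below Vt, or None
    when no subthreshold equilibrium exists (suprathreshold I).
    """
    k, b = params.k, params.b
    delta = params.Vt - params.Vr
    # in x = V - Vr:  k x^2 - (k*delta + b) x + I = 0
    beta = k * delta + b
    disc = beta * beta - 4.0 * k * I
    if disc < 0:
        return None
    x = (beta - math.sqrt(disc)) / (2.0 * k)
    V = params.Vr + x
    if V >= params.Vt:
        return None
    return V


def default_ramp(slope: float = 0.1, resolution: float = 1.0,
                 i_max: float = 1000.0, onset: float = 0.0,
                 target: str = "soma") -> Stimulus:
    """The excitability-probe ramp: a slow staircase (+0.1 pA per 1 ms by
    default) rising to ``i_max`` pA."""
    offset = onset + i_max / slope
    return Stimulus.ramp(slope, onset, offset, target=target, resolution=resolution)


def rheobase_by_ramp(params, ramp: Optional[Stimulus] = None,
                     config: Optional[SimConfig] = None) -> float:
    """Minimum depolarizing current eliciting a spike, probed by a slow ramp.

    Returns the instantaneous ramp current at the first spike.  Raises
    ``MeasurementInvalid`` if no spike occurs before the ramp ends.
    """
    if isinstance(params, CompartmentParams):
        model = MCModel.single(params)
    else:
        model = params
    name = model.names[0] if model.n_compartments == 1 else model.soma
    if ramp is None:
        ramp = default_ramp(target=name)
    if ramp.slope <= 0:
        raise ValueError("rheobase ramp must have positive slope")
    if config is None:
        config = SimConfig(dt=0.05, duration=ramp.offset, method="rk4")
    else:
        config = SimConfig(dt=config.dt, duration=ramp.offset, method=config.method,
                           spike_time_interpolation=config.spike_time_interpolation)
    trace = simulate(model, [ramp], config)
    spikes = trace.spikes[ramp.target]
    if len(spikes) == 0:
        raise MeasurementInvalid(
            f"no rheobase found below ramp maximum "
            f"({ramp.slope * (ramp.offset - ramp.onset):.1f} pA)"
        )
    t = spikes[0]
    n_increments = math.floor((t - ramp.onset) / ramp.resolution) + 1
    return ramp.slope * ramp.resolution * n_increments


def voltage_deflection(params, I_hyper: float,
                       config: Optional[SimConfig] = None) -> float:
    """Steady-state voltage deflection from rest under a sustained
    hyperpolarizing step, reported positive for hyperpolarization."""
    if I_hyper > 0:
        raise ValueError("voltage_deflection expects a hyperpolarizing (<= 0) current")
    if isinstance(params, CompartmentParams):
        model = MCModel.single(params)
    else:
        model = params
    name = model.names[0] if model.n_compartments == 1 else model.soma
    config = config or SimConfig(dt=0.05, duration=1500.0, method="rk4")
    # the step outlasts the record so the final RK4 stage still sees it
    stim = Stimulus.step(I_hyper, onset=0.0, offset=config.duration + 1.0, target=name)
    trace = simulate(model, [stim], config)
    if any(len(s) for s in trace.spikes.values()):
        raise MeasurementInvalid("spike during hyperpolarizing deflection protocol")
    vr = model.params(name).Vr
    return vr - trace.V[name][-1]


def synaptic_current(events, times: np.ndarray,
                     syn: Optional[SynapseConfig] = None) -> np.ndarray:
    """Total synaptic drive on a time grid for (time, count, weight)
    activation events under the configured kernel: injected current (pA)
    in cuba mode, open conductance (nS) in coba mode (the injected
    current is then g * (E - V), evaluated inside the integrator)."""
    syn = syn or SynapseConfig()
    stim = Stimulus.synaptic(events)
    return stim.drive(np.asarray(times, dtype=np.float64), syn)
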