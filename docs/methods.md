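# Methods

## The model

Each compartment follows the nine-parameter Izhikevich formalism, a hybrid
dynamical system with a quadratic voltage equation, a linear recovery
variable, and an after-spike reset:

    C dV/dt = k (V - Vr)(V - Vt) - U + I
      dU/dt = a (b (V - Vr) - U)
    if V >= Vpeak:   record a spike,  V <- Vmin,  U <- U + d

Units are fixed package-wide: ms, mV, pA, pF, nS; with them the nine
parameters have their conventional magnitudes (C in pF, k in pA/mV², a in
1/ms, b in nS, d in pA). `a` sets the recovery time constant, `b` the degree
of V–U coupling (together they place the model in the integrator or
resonator regime), `d` and `Vmin` the after-spike resets, `k` and `Vt` the
spike upstroke. (Vr, 0) is an exact rest state and is the default initial
condition, so no settling simulation is needed before a stimulus.

Multi-compartment models are unbranched chains (a morphology-by-layer
reduction: e.g. SO–SP–SR–SLM for a CA2 pyramidal cell, soma = SP). Adjacent
compartments exchange current through an asymmetric resistive link with
conductance G and share P ∈ [0.01, 0.99]: the proximal (soma-ward) end feels
G·P·(V_prox − V_dist) as an outward current, the distal end
G·(1−P)·(V_dist − V_prox). All compartments share one resting potential, so
a c-compartment chain has 8c + 1 intrinsic parameters plus 2(c−1) coupling
parameters. In the packaged four-compartment set each non-somatic table row
carries the (G, P) of its soma-ward link, with P applied on the soma-ward
side; this placement uniquely reproduces the published dendritic
measurements (deflections within 0.05 mV for the fast-recovery
compartments).

## Integration

Fixed-step RK4 at dt = 0.05 ms is the reference integrator (all reported
numbers); forward Euler at dt = 0.1 ms is the default inside evolutionary
search loops for speed. Stimulus drives are pre-sampled on a half-step grid
so RK4 stages see the exact current at t, t+dt/2, t+dt. After each step any
compartment at or above Vpeak records a spike (crossing time linearly
interpolated within the step), has its recorded sample clamped to Vpeak, and
is reset before the next step. Convergence is verified against the analytic
subthreshold fixed point — the stable root of
k(V−Vr)(V−Vt) − b(V−Vr) + I = 0 — and by halving dt (latency changes
< 0.1%). Divergence (non-finite state) raises a diagnostic naming the
compartment and time; optimizer loops convert it into a maximal penalty.

## Stimuli and synapses

Step, staircase-ramp (default +0.1 pA per 1 ms, the excitability probe) and
synaptic-event stimuli are supported. The synapse is an instantaneous-rise,
single-exponential-decay (τ = 5 ms) excitatory kernel. The default is
conductance-based with reversal 0 mV and peak conductance = weight (nS),
matching the conductance-based synapses of the large-scale model family this
weight convention comes from; a current-based variant (peak = weight pA) is
selectable. The choice matters: with the packaged four-compartment
parameters the conductance kernel places all three unitary somatic EPSPs
inside the 0.1–0.9 mV constraint window and initiates dendritic spikes with
a 200-synapse barrage, while the current-based kernel at the same weight is
two orders of magnitude too weak to do either.

## Measurement protocols

- Rheobase (ramp): slow staircase ramp; the current value at the first
  spike. Used for relative compartment excitability, where its slow
  quasi-static build-up of U is exactly what makes the soma (slowest
  recovery) probe as most excitable.
- Step rheobase: minimum step amplitude from rest that fires within 500 ms
  (bisected to 1 pA). A step from rest fires far below the ramp value
  because U has not built up; the fast-spiking minimum-frequency scan must
  start here, not at the ramp value.
- Voltage deflection: Vr minus the terminal voltage of a long
  hyperpolarizing step (1.5 s default); spikes invalidate the measurement.
- Minimum firing frequency: 500 ms steps from the step rheobase upward in
  1 pA increments (the optimizer's current genes are integers); minimum over
  currents with ≥ 2 spikes of 1000 / first ISI.
- Rebound: maximum of V − Vr in a 500 ms window after release from
  hyperpolarization; a 500 ms, −195 pA step reproduces the published 7 mV
  rebound of the OR-LM model (longer steps recruit a rebound spike).
- Propagation rate R: simultaneous activation of 200 excitatory synapses at
  a dendritic compartment; R = spikes at the soma-adjacent compartment per
  source spike. A compartment that cannot fire from the barrage alone is
  retried with an escalating supplementary current step (default 1200 pA).

## Features and classification

Features per (model, stimulus): first-spike latency (fsl), post-spike
silence (pss), burst segmentation (clusters split at ISIs exceeding
gap_factor × median ISI, default 3; counts nbs/nspikes, widths bw, gaps
pbi), rebound amplitude, instantaneous frequencies, and spike-frequency
adaptation quantified by (piecewise) linear regression of log10(ISI in ms)
against the latency of the pair-closing spike. The log transform is the
default because the published intercepts (≈ 1.0–1.2) are consistent with
log10 of ms-scale first ISIs and not with raw ms values; the transform is
recorded in every fit and never compared across conventions. Two-piece fits
use an O(n) prefix-sum breakpoint scan and are preferred over a single line
only when an F-test on the residual reduction fires at α = 0.05.

Classification assigns transient elements (D delayed, ASP. adapting, TSTUT
transient stuttering, TSWB with a slow wave) and at most one steady-state
element (NASP, SLN, PSTUT, PSWB); records ending mid-transient carry only
the transient (e.g. "ASP.", "D.ASP."). The published protocol's numeric
thresholds are not available, so the shipped defaults are explicitly
calibration-backed: every packaged reference model must reproduce its
published label at some step current in [50, 800] pA, and the acceptance
suite enforces exactly that. Calibrated defaults: D iff
fsl > max(70 ms, 2 × first post-delay ISI) — the first ISI, not a mean,
because late ISIs of strong adapters would inflate the reference; SLN iff
pss > max(50 ms, 2 × max ISI); ASP iff the first-piece slope is positive and
statistically so; slow wave iff inter-cluster voltage dips ≥ 10 mV below the
post-reset baseline (measured dips on the fixtures: ≈ 0, 6 and 14 mV for
the transient-stutter, persistent-stutter and slow-wave-burst models — 10 mV
is the separating value; the 2 mV starting point did not separate them).
A stutter record whose final uninterrupted run outlasts the longest gap is
transient (TSTUT/TSWB), otherwise persistent.

## Objective

For each target trace the error is Σ_{f∈S} W_f · log(1 + |exp_f − model_f|)
with S = {fsl, pss, m, c, nisi} for continuous firing and
S = {fsl, pss, nbs, bw, pbi, nspikes} for interrupted firing, features in
native units (the log compresses the scales). List features are compared
sorted, truncated to the shorter length, plus a length-mismatch term of the
same form; a target feature absent in the candidate contributes a fixed
large deviation (100) so degenerate candidates never win. Weights are
dynamic: all 1 when the candidate's class matches the target class; outside
it, each feature violating the target-class criteria gets
1 + 9 × clip(boundary distance, 1), concentrating pressure on exactly the
class-violating features (the published weight-calculation pseudocode is not
in the available text; this reconstruction realizes its described
fast-exploitation / slow-exploration behavior and is fully configurable).
Multi-compartment candidates add, per dendrite: log-penalties when the
decoupled dendrite is more excitable than the soma, when its deflection is
smaller, when forward propagation R < 1, and when the unitary somatic EPSP
leaves [0.1, 0.9] mV. Fast-spiking targets add
log(1 + max(0, f_floor − f_min)) with f_floor = 25 Hz.

## Evolutionary search

Non-overlapping generational EA with elitism: ceil(10%) lowest-error
individuals survive; the rest are produced by binary tournament (two
distinct contestants, ties uniform), two-point crossover on gene boundaries,
and mixed mutation at per-gene rate 0.2 (midpoint of the stated 0.1–0.3
range): ±1 integer random walk for d, C, G and the current genes, uniform
reset within bounds for everything else. Elites remain eligible as parents.
Default bounds bracket all packaged optima generously (a 0.0005–0.15,
b −35–95, d −20–120, C 20–2000, k 0.2–6.5, Vr −80–−50, Vt −65–−5, Vpeak
0–90, Vmin −70–−35, G 0–200); current genes search ±10 pA around a known
stimulation current, else 50–800 pA. Candidates violating the parameter
ordering invariants (e.g. Vt < Vr) score the maximal error rather than being
repaired. A run is fully determined by (seed, config, target); trials derive
child seeds from one seed sequence.

Because the search integrates with Euler at dt = 0.1 while targets and
reported features use RK4 at dt = 0.05, each trial ends with a re-selection
pass: the final population is re-scored under the accurate integrator and
the accurate-error winner is the trial's best. Without this, silence/latency
features that drift ~10 ms between integrators near sensitive operating
points make fast-integrator optima mis-score under the accurate protocol.

## Problem sizes used in the shipped checks

Reference reproductions use 1 s steps (100 ms onset) at RK4 dt = 0.05. The
parameter-recovery check runs the EA at population 40 for 200 generations,
5 seeded trials, against a zero-noise synthetic non-adapting target
generated from the packaged OR-LM set at its discovered working current —
a reduced-scale counterpart of the thousand-trial campaigns behind the
published per-class acceptance rates, which are out of desk scale; the
check asserts class-matching recovery with every compared feature within
10% (0.05 absolute for near-zero slopes).

## Synthetic targets: what they do and do not emulate

`make_synthetic_target` produces feature-level targets from known parameter
sets, optionally jittering scalar features within class-preserving bounds
(re-verified via boundary distances, redrawn on violation). These stand in
for digitized experimental traces: they share the feature schema and class
labels but have none of the measurement noise structure, sweep-to-sweep
variability, or electrode artifacts of real recordings — recovery results
on them demonstrate the machinery (landscape, weighting, search), not
performance on experimental data.

## Known limitations

- The classification thresholds are fixture-calibrated stand-ins for an
  unavailable statistical protocol; labels near a boundary are
  threshold-sensitive.
- The fast-spiking minimum frequency sits on the steeply diverging first-ISI
  branch just above a hard two-spike threshold; its value is set by the
  1 pA scan grid and moves by a few Hz under third-decimal parameter
  rounding. The shipped reproduction measures 23.3 Hz against the published
  21 Hz.
- An isolated spike of the most distal compartment of the packaged
  four-compartment set does not forward-propagate under the default synapse
  reconstruction (its conductance synapse cannot push V above that
  compartment's 2.4 mV spike cutoff without a supplementary current, and the
  single reset transient injects too little charge downstream); propagation
  at rate 1 holds for the two proximal dendrites, as published.
- Branching morphologies, conductance-based membrane channels, spike-shape
  features and network simulation are out of scope.
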