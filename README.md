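# izhifit

Automated fitting of single- and multi-compartment Izhikevich
spiking-neuron models to the quantitative *features* of recorded spike
patterns — rather than to raw voltage traces — with an evolutionary
algorithm whose error landscape embeds qualitative firing-pattern class
definitions (delayed, adapting, stuttering, bursting, ...). It is aimed at
computational neuroscientists who need compact, behaviorally faithful
neuron models for large-scale circuit simulation, and who have sparse
experimental data: a handful of printed feature values per neuron type
instead of clean voltage recordings.

## The model and the objective

Each compartment is a nine-parameter Izhikevich model,

    C dV/dt = k (V − Vr)(V − Vt) − U + I
      dU/dt = a (b (V − Vr) − U)
    if V ≥ Vpeak:  V ← Vmin,  U ← U + d

(units ms, mV, pA, pF, nS). Chains of compartments are joined by
asymmetric resistive links: a link (G, P) injects G·P·(V_prox − V_dist)
outward at its soma-ward end and G·(1−P)·(V_dist − V_prox) at the distal
end, giving direction-dependent attenuation.

A candidate model is scored against per-trace feature targets by

    error = Σ_{f ∈ S} W_f · log(1 + |exp_f − model_f|)

with S = {fsl, pss, m, c, nisi} for continuous firing (first-spike
latency, post-spike silence, adaptation-fit slope/intercept/ISI count) and
S = {fsl, pss, nbs, bw, pbi, nspikes} for interrupted firing (burst
counts, widths, gaps). The weights W_f are dynamic: a candidate whose
qualitative class differs from the target class has exactly its
class-violating features up-weighted in proportion to their distance from
the class boundary, which steers the population into the target class
quickly and then explores slowly within it. Multi-compartment candidates
additionally pay penalties unless their decoupled dendrites are less
excitable than the soma, have higher input resistance, forward-propagate
synaptically initiated spikes, and evoke unitary somatic EPSPs inside
0.1–0.9 mV. The search itself is a non-overlapping generational EA with
10% elitism, binary tournament, two-point crossover, and mixed mutation
(integer random walk for d, C, G and the stimulation currents; uniform
reset within bounds otherwise).

The package ships ten published reference parameter sets (nine
single-behavior hippocampal neuron-type models covering NASP, D.NASP,
ASP., ASP.SLN, ASP.NASP, D.ASP., TSTUT.NASP, TSWB.SLN and PSTUT, plus a
four-compartment CA2 pyramidal chain) as machine-readable fixtures, a
spike-pattern classifier with calibrated default thresholds, and a
synthetic-target generator for recovery experiments.

## Worked example

Simulate the packaged CA1 OR-LM interneuron model under a 156 pA step and
classify its pattern:

    $ izhifit classify "CA1 OR-LM" -I 156
    {
     "class": "ASP.",
     "n_spikes": 23,
     "features": {
      "fsl_ms": 58.6824269156665,
      "pss_ms": 15.411101385665233,
      ...
      "sfa": {
       "transform": "log10",
       "pieces": [
        {"m": 0.00016358227560267226, "c": 1.5456850438079934, "n_isi": 11},
        ...

The first spike arrives 58.7 ms after step onset — the published model
latency for this current is 58.9 ms — and the inter-spike intervals climb
slowly (positive adaptation slope in log10(ISI) per ms), so at this
current the pattern reads as adapting spiking; at higher currents
(≳ 430 pA) the same model fires without detectable adaptation and
classifies NASP, its published label. The same library calls are available
programmatically:

    from izhifit.workbench import fixture, characterize
    trace, train, feats, label = characterize(fixture("CA1 OR-LM").model, 156.0)

A complete fitting loop — generate a synthetic target from a fixture, then
recover a model for it — is two commands:

    izhifit synth "CA3 Giant" -I 200 --seed 3 -o target.yaml
    izhifit fit target.yaml --population 120 --generations 500 --trials 5 -o fit_out

`fit_out/summary.json` reports how many trials produced class-accepted
models and the best model's parameters and currents.

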