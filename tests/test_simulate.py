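import numpy as np
import pytest

from izhifit.model import (CompartmentParams, CouplingLink, MCModel, SimConfig,
                           Stimulus, SynapseConfig)
from izhifit.simulate import (MeasurementInvalid, rheobase_by_ramp, simulate,
                              subthreshold_fixed_point, synaptic_current,
                              voltage_deflection, default_ramp)

P = dict(k=0.5, a=0.01, b=5.0, d=10.0, C=100.0, Vr=-60.0, Vt=-40.0,
         Vpeak=30.0, Vmin=-50.0)


def _single(**kw):
    return MCModel.single(CompartmentParams(**{**P, **kw}))


def _pair(G, P_share=0.5, **kw):
    p = CompartmentParams(**{**P, **kw})
    return MCModel(compartments=(("c1", p), ("c2", p)),
                   links=(CouplingLink("c1", "c2", G, P_share),), soma="c1")


class TestRestState:
    def test_zero_input_stays_at_rest(self, orlm, accurate_sim):
        """(Vr, 0) is an exact fixed point at I = 0."""
        tr = simulate(orlm.model, Stimulus.step(0.0, 100.0, 1100.0), accurate_sim)
        vr = orlm.model.params("soma").Vr
        assert np.max(np.abs(tr.V["soma"] - vr)) < 1e-12
        assert len(tr.spikes["soma"]) == 0

    def test_spike_times_strictly_increasing_and_v_clamped(self, orlm,
                                                           orlm_trace_156):
        sp = orlm_trace_156.spikes["soma"]
        assert len(sp) > 2
        assert np.all(np.diff(sp) > 0)
        # recorded samples never exceed the spike cutoff
        assert np.max(orlm_trace_156.V["soma"]) <= orlm.model.params("soma").Vpeak + 1e-9


class TestFixedPoint:
    def test_zero_current_root_is_vr(self):
        p = CompartmentParams(**P)
        assert subthreshold_fixed_point(p, 0.0) == pytest.approx(p.Vr)

    def test_suprathreshold_has_no_root(self):
        p = CompartmentParams(**P)
        assert subthreshold_fixed_point(p, 1e6) is None

    @pytest.mark.parametrize("I", [-500.0, -100.0, 20.0])
    def test_long_simulation_converges_to_analytic_root(self, I):
        """The quadratic steady state (U = b (V - Vr)) is reached by a
        long simulation within integrator tolerance."""
        p = CompartmentParams(k=1.029, a=0.002, b=11.054, d=40.0, C=1164.0,
                              Vr=-74.633, Vt=-62.009, Vpeak=18.314, Vmin=-65.184)
        v_star = subthreshold_fixed_point(p, I)
        assert v_star is not None
        cfg = SimConfig(dt=0.05, duration=6000.0, method="rk4")
        tr = simulate(MCModel.single(p), Stimulus.step(I, 0.0, 6001.0), cfg)
        assert tr.V["soma"][-1] == pytest.approx(v_star, abs=5e-3)

    def test_deflection_matches_analytic_root(self):
        p = CompartmentParams(**{**P, "a": 0.05})
        v_star = subthreshold_fixed_point(p, -200.0)
        cfg = SimConfig(dt=0.05, duration=2000.0)
        d = voltage_deflection(MCModel.single(p), -200.0, cfg)
        assert d == pytest.approx(p.Vr - v_star, abs=1e-3)
        assert d > 0


class TestCoupling:
    def test_zero_conductance_decouples(self, accurate_sim):
        """With G = 0 the pair is samplewise equal to independent
        single-compartment simulations."""
        pair = _pair(G=0.0)
        stim = Stimulus.step(150.0, 100.0, 1100.0, target="c1")
        tr_pair = simulate(pair, stim, accurate_sim)
        tr_single = simulate(_single(), Stimulus.step(150.0, 100.0, 1100.0),
                             accurate_sim)
        np.testing.assert_array_equal(tr_pair.V["c1"], tr_single.V["soma"])
        np.testing.assert_array_equal(tr_pair.spikes["c1"], tr_single.spikes["soma"])
        assert np.max(np.abs(tr_pair.V["c2"] - P["Vr"])) < 1e-12

    def test_symmetric_coupling_currents_antisymmetric(self):
        """At P = 0.5 the coupling currents at the two link ends are equal
        and opposite at every instant, so the pair's total coupling drive
        vanishes and two identical compartments stay identical."""
        pair = _pair(G=25.0, P_share=0.5)
        stim = [Stimulus.step(180.0, 50.0, 900.0, target="c1"),
                Stimulus.step(180.0, 50.0, 900.0, target="c2")]
        tr = simulate(pair, stim, SimConfig(dt=0.05, duration=1000.0))
        # identical drive + antisymmetric coupling => identical trajectories
        np.testing.assert_allclose(tr.V["c1"], tr.V["c2"], atol=1e-12)

    def test_asymmetric_share_moves_current_prox_vs_dist(self):
        """P > 0.5 loads the proximal end more: with c1 stimulated, a
        larger proximal share drains c1 harder and depolarizes c2 less."""
        cfg = SimConfig(dt=0.05, duration=400.0)
        stim = Stimulus.step(80.0, 50.0, 400.0, target="c1")
        v2 = {}
        for share in (0.2, 0.8):
            tr = simulate(_pair(G=30.0, P_share=share, b=2.0), stim, cfg)
            v2[share] = np.max(tr.V["c2"])
        # distal share (1 - P) drives c2; smaller P -> more drive at c2
        assert v2[0.2] > v2[0.8]


class TestRheobase:
    def test_deterministic(self, orlm):
        r1 = rheobase_by_ramp(orlm.model.params("soma"))
        r2 = rheobase_by_ramp(orlm.model.params("soma"))
        assert r1 == r2

    def test_halving_capacitance_does_not_increase_rheobase(self):
        p = CompartmentParams(**P)
        ramp = default_ramp(i_max=600.0)
        r_full = rheobase_by_ramp(p, ramp)
        r_half = rheobase_by_ramp(p.replace(C=P["C"] / 2), ramp)
        assert r_half <= r_full

    def test_no_spike_signals_error(self):
        p = CompartmentParams(**P)
        ramp = default_ramp(i_max=5.0)  # far below rheobase
        with pytest.raises(MeasurementInvalid, match="no rheobase"):
            rheobase_by_ramp(p, ramp)


class TestSpikeCountMonotonicity:
    def test_nasp_fixture_spike_count_nondecreasing(self, orlm, criteria):
        """Integrator-regime models recruit spikes monotonically with step
        amplitude over the scanned range."""
        cfg = SimConfig(dt=0.1, duration=600.0, method="euler")
        counts = []
        for I in np.arange(100.0, 260.0, 20.0):
            tr = simulate(orlm.model, Stimulus.step(I, 100.0, 600.0), cfg)
            counts.append(len(tr.spikes["soma"]))
        assert all(b >= a for a, b in zip(counts, counts[1:]))


class TestConvergence:
    def test_halving_dt_keeps_latency(self, orlm):
        """rk4 latencies are converged at dt = 0.05 ms."""
        lat = {}
        for dt in (0.05, 0.025):
            cfg = SimConfig(dt=dt, duration=400.0, method="rk4")
            tr = simulate(orlm.model, Stimulus.step(156.0, 100.0, 400.0), cfg)
            lat[dt] = tr.spikes["soma"][0] - 100.0
        assert lat[0.05] == pytest.approx(lat[0.025], rel=1e-3)


class TestSynapticDrive:
    def test_zero_events_zero_drive(self):
        t = np.linspace(0.0, 100.0, 11)
        np.testing.assert_array_equal(synaptic_current([], t), 0.0)

    def test_doubling_count_doubles_drive(self):
        t = np.linspace(0.0, 100.0, 201)
        one = synaptic_current([(10.0, 100, 10.0)], t)
        two = synaptic_current([(10.0, 200, 10.0)], t)
        np.testing.assert_allclose(two, 2.0 * one)

    def test_cuba_epsp_scales_linearly_at_small_drive(self):
        syn = SynapseConfig(mode="cuba")
        model = _single()
        cfg = SimConfig(dt=0.05, duration=200.0)
        amps = []
        for n in (1, 2):
            tr = simulate(model, Stimulus.synaptic([(50.0, n, 1.0)]), cfg, syn=syn)
            amps.append(np.max(tr.V["soma"]) - P["Vr"])
        assert amps[1] == pytest.approx(2.0 * amps[0], rel=1e-3)

    def test_unknown_target_rejected(self, orlm, accurate_sim):
        with pytest.raises(ValueError, match="unknown compartment"):
            simulate(orlm.model, Stimulus.step(100.0, 0.0, 500.0, target="dend"),
                     accurate_sim)
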