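import numpy as np
import pytest
from hypothesis import given, strategies as st

from izhifit.features import (FeatureSet, SpikeTrain, fit_sfa,
                              first_spike_latency, instantaneous_frequencies,
                              isi_latency_pairs, post_spike_silence,
                              rebound_amplitude, segment_bursts)
from izhifit.model import CompartmentParams, MCModel, SimConfig, Stimulus
from izhifit.simulate import simulate


def train(times, onset=0.0, offset=1000.0):
    return SpikeTrain(np.asarray(times, dtype=float), onset, offset)


class TestIsiLatencyPairs:
    def test_pair_end_convention(self):
        """The latency of each ISI is referenced to the second spike of
        the pair."""
        pairs = isi_latency_pairs(train([100.0, 150.0, 200.0]))
        np.testing.assert_allclose(pairs, [[150.0, 50.0], [200.0, 50.0]])

    def test_constant_rate_constant_isis(self):
        pairs = isi_latency_pairs(train(np.arange(50.0, 550.0, 25.0)))
        assert np.ptp(pairs[:, 1]) == 0.0

    def test_needs_two_spikes(self):
        with pytest.raises(ValueError, match="no ISIs"):
            isi_latency_pairs(train([100.0]))


class TestLatencySilence:
    def test_basic_values(self):
        t = train([40.1, 90.0], onset=0.0, offset=200.0)
        assert first_spike_latency(t) == pytest.approx(40.1)
        assert post_spike_silence(t) == pytest.approx(110.0)

    def test_single_spike_at_offset_zero_silence(self):
        t = train([500.0], offset=500.0)
        assert post_spike_silence(t) == 0.0

    @given(st.floats(-1e4, 1e4))
    def test_translation_invariance(self, delta):
        t0 = train([40.0, 90.0, 160.0], onset=10.0, offset=400.0)
        t1 = t0.shifted(delta)
        assert first_spike_latency(t1) == pytest.approx(first_spike_latency(t0))
        assert post_spike_silence(t1) == pytest.approx(post_spike_silence(t0))

    def test_conservation_single_cluster(self):
        """fsl + sum(ISIs) + pss spans the whole stimulus window."""
        t = train([37.0, 81.0, 144.0, 222.0], onset=12.0, offset=512.0)
        total = (first_spike_latency(t) + np.sum(t.isis) + post_spike_silence(t))
        assert total == pytest.approx(500.0)


class TestFitSfa:
    def test_exact_line_identity_transform(self):
        x = np.arange(10.0, 110.0, 10.0)
        pairs = np.column_stack([x, 0.1 * x + 20.0])
        fit = fit_sfa(pairs, transform="identity")
        assert fit.n_pieces == 1
        assert fit.slope == pytest.approx(0.1)
        assert fit.intercept == pytest.approx(20.0)
        assert fit.pieces[0].sse == pytest.approx(0.0, abs=1e-18)

    def test_exact_log_line(self):
        x = np.arange(10.0, 110.0, 10.0)
        pairs = np.column_stack([x, 10.0 ** (0.002 * x + 1.0)])
        fit = fit_sfa(pairs, transform="log10")
        assert fit.slope == pytest.approx(0.002)
        assert fit.intercept == pytest.approx(1.0)

    def test_two_segment_recovery(self):
        """An exact rise-then-flat profile is recovered piecewise: both
        slopes, and a breakpoint between the constructed segments."""
        x1 = np.arange(10.0, 60.0, 10.0)
        x2 = np.arange(60.0, 160.0, 10.0)
        y = np.concatenate([0.5 * x1, np.full(x2.size, 30.0)])
        pairs = np.column_stack([np.concatenate([x1, x2]), y])
        fit = fit_sfa(pairs, transform="identity", alpha=0.05)
        assert fit.n_pieces == 2
        assert fit.pieces[0].m == pytest.approx(0.5, abs=1e-9)
        assert fit.pieces[1].m == pytest.approx(0.0, abs=1e-9)
        assert 50.0 < fit.breakpoint < 70.0
        assert fit.pieces[0].n_isi + fit.pieces[1].n_isi == pairs.shape[0]

    def test_insufficient_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_sfa(np.array([[1.0, 2.0], [2.0, 3.0]]))

    def test_adapting_fixture_isis_nondecreasing(self, fixtures_by_name):
        """The adapting reference model's ISIs grow monotonically under a
        sustained step."""
        giant = fixtures_by_name["CA3 Giant"]
        cfg = SimConfig(dt=0.05, duration=1100.0)
        tr = simulate(giant.model, Stimulus.step(200.0, 100.0, 1100.0), cfg)
        isis = np.diff(tr.spikes["soma"])
        assert len(isis) >= 5
        # non-decreasing up to spike-time interpolation jitter
        assert np.all(np.diff(isis) >= -0.02)


class TestSegmentBursts:
    def test_constant_rate_single_cluster(self):
        _, gaps, nbs, bw, pbi, ns = segment_bursts(train(np.arange(0.0, 400.0, 20.0)))
        assert nbs == 1 and not gaps and pbi == ()

    def test_two_cluster_arithmetic(self):
        _, gaps, nbs, bw, pbi, ns = segment_bursts(
            train([10.0, 20.0, 30.0, 200.0, 210.0, 220.0]))
        assert nbs == 2
        assert pbi == (170.0,)
        assert bw == (20.0, 20.0)
        assert ns == (3, 3)

    def test_gap_rule_scale_invariant(self):
        """gap_factor is dimensionless: scaling all times leaves the
        partition unchanged."""
        t = np.array([10.0, 20.0, 30.0, 200.0, 210.0, 220.0, 500.0, 510.0])
        for scale in (0.1, 1.0, 40.0):
            _, _, nbs, _, _, ns = segment_bursts(train(t * scale, offset=1e6))
            assert nbs == 3
            assert ns == (3, 3, 2)

    def test_stutter_fixture_produces_clusters(self, fixtures_by_name, criteria):
        """The two-compartment stuttering construction fires in clusters."""
        ob = fixtures_by_name["CA1 Oriens-Bistratified"]
        assert ob.model.n_compartments == 2
        cfg = SimConfig(dt=0.05, duration=1100.0)
        tr = simulate(ob.model, Stimulus.step(500.0, 100.0, 1100.0, target="c1"), cfg)
        sp = tr.spikes["c1"]
        t = SpikeTrain(sp[(sp >= 100.0)], 100.0, 1100.0)
        _, _, nbs, _, _, _ = segment_bursts(t, criteria.gap_factor)
        assert nbs >= 2


class TestRebound:
    def test_monotonic_return_zero_rebound(self):
        # b = 0 decouples V from U: release from hyperpolarization
        # relaxes back to rest monotonically, with no sag or rebound
        p = CompartmentParams(k=0.5, a=0.05, b=0.0, d=10.0, C=100.0, Vr=-60.0,
                              Vt=-40.0, Vpeak=30.0, Vmin=-50.0)
        cfg = SimConfig(dt=0.05, duration=1500.0)
        tr = simulate(MCModel.single(p), Stimulus.step(-100.0, 100.0, 800.0), cfg)
        rbv, spike = rebound_amplitude(tr, 800.0)
        assert not spike
        assert rbv == pytest.approx(0.0, abs=0.05)

    def test_orlm_rebound_amplitude(self, orlm):
        """The OR-LM model released from a 500 ms, -195 pA step rebounds
        by about 7 mV (no rebound spike)."""
        cfg = SimConfig(dt=0.05, duration=1100.0)
        tr = simulate(orlm.model, Stimulus.step(-195.0, 100.0, 600.0), cfg)
        rbv, spike = rebound_amplitude(tr, 600.0)
        assert not spike
        assert rbv == pytest.approx(7.0, abs=1.0)

    def test_rebound_nondecreasing_in_duration(self, orlm):
        """Longer hyperpolarization recruits more recovery-variable
        relief, so the rebound does not shrink."""
        amps = []
        for dur in (150.0, 350.0, 600.0):
            cfg = SimConfig(dt=0.05, duration=dur + 700.0)
            tr = simulate(orlm.model, Stimulus.step(-195.0, 100.0, 100.0 + dur), cfg)
            rbv, _ = rebound_amplitude(tr, 100.0 + dur)
            amps.append(rbv)
        assert all(b >= a - 1e-6 for a, b in zip(amps, amps[1:]))


class TestInstantaneousFrequencies:
    def test_constant_isis(self):
        freqs, first, mean = instantaneous_frequencies(
            train(np.arange(0.0, 400.0, 40.0)))
        np.testing.assert_allclose(freqs, 25.0)
        assert first == pytest.approx(25.0)
        assert mean == pytest.approx(25.0)

    def test_first_isi_frequency(self):
        _, first, _ = instantaneous_frequencies(train([0.0, 47.6, 100.0]))
        assert first == pytest.approx(1000.0 / 47.6)
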