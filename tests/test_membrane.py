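import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinephys import synthetic as syn
from spinephys.core import ProtocolEpoch, ProtocolError, Sweep, UnitError
from spinephys.membrane import (DVDT_THRESHOLD, ap_waveform_features,
                                classify_spontaneous, detect_spikes,
                                discharge_metrics, find_rheobase,
                                measure_passive, measure_rmp)


def flat_sweep(level=-70.0, n=5000, **kw):
    return Sweep(np.full(n, level), **kw)


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        assert len(detect_spikes(flat_sweep())) == 0

    def test_subcriterion_ramp_has_no_spikes(self):
        """A 10 mV/ms ramp never reaches the 15 mV/ms criterion."""
        t = np.arange(0, 10, 0.1)
        assert len(detect_spikes(Sweep(-70.0 + 10.0 * t))) == 0

    def test_voltage_clamp_sweep_rejected(self):
        with pytest.raises(UnitError):
            detect_spikes(flat_sweep(units="pA"))

    def test_thresholds_match_direct_derivative_scan(self):
        """Detected thresholds agree with a brute-force scan of the
        centred-difference derivative array to within one sample."""
        sweeps = []
        for off in (20.0, 60.0, 110.0):
            sweeps.append(syn.synthesize_ap_waveform().samples)
        v = np.concatenate(sweeps)
        sw = Sweep(v)
        train = detect_spikes(sw)
        dv = np.gradient(v, sw.dt)
        brute = []
        above = dv >= DVDT_THRESHOLD
        for i in np.flatnonzero(above):
            if not brute or i - brute[-1] > 50:
                brute.append(i)
        assert len(train) == 3 == len(brute)
        np.testing.assert_allclose(train.threshold_times, np.array(brute) * sw.dt,
                                   atol=sw.dt)

    def test_counts_match_generator_ground_truth(self):
        """Spike counts equal the model's own threshold-crossing count on
        every phenotype at 1 mV noise."""
        for name in syn.DISCHARGE_CLASSES:
            sweeps, truth = syn.simulate_current_clamp(
                syn.preset(name, noise_sd=1.0), seed=11)
            for sw, st_true in zip(sweeps, truth.spike_times):
                assert len(detect_spikes(sw)) == st_true.size


class TestMeasurePassive:
    def test_ideal_resistor_gives_exact_rin(self):
        """A pure 300 MOhm resistor: -5 mV -> -16.667 pA steady state."""
        n = 1500
        i = np.zeros(n)
        i[200:1200] = -5.0 / 300.0 * 1e3
        sw = Sweep(i, units="pA",
                   epochs=[ProtocolEpoch(0, 20, 0, "holding"),
                           ProtocolEpoch(20, 100, -5.0, "step"),
                           ProtocolEpoch(120, 30, 0, "holding")])
        rin, _ = measure_passive([sw])
        assert rin == pytest.approx(300.0, rel=1e-9)

    @pytest.mark.parametrize("rin,cm", [(100.0, 5.0), (295.0, 13.0), (600.0, 25.0)])
    def test_rc_cell_recovered_within_5_percent(self, rin, cm):
        sweeps = syn.simulate_seal_test(cm_pf=cm, rin_mohm=rin, seed=5)
        r_est, c_est = measure_passive(sweeps)
        assert r_est == pytest.approx(rin, rel=0.05)
        assert c_est == pytest.approx(cm, rel=0.05)

    def test_zero_length_step_is_protocol_error(self):
        with pytest.raises(Exception):
            ProtocolEpoch(20, 0.0, -5.0, "step")

    def test_no_step_epoch_is_protocol_error(self):
        with pytest.raises(ProtocolError):
            measure_passive([flat_sweep(units="pA")])


class TestMeasureRmp:
    def test_constant_trace(self):
        sw = flat_sweep(-56.0, n=350_000)
        assert measure_rmp(sw) == pytest.approx(-56.0)

    def test_spikes_masked_from_mean(self):
        """Three APs on a -60 mV baseline shift the masked mean < 0.5 mV."""
        base = np.full(320_000, -60.0)
        spike = np.concatenate([np.linspace(-60, 20, 15, endpoint=False),
                                np.linspace(20, -65, 15, endpoint=False),
                                np.linspace(-65, -60, 20, endpoint=False)])
        for k in range(3):
            i0 = 50_000 + 100_000 * k
            base[i0:i0 + spike.size] = spike
        sw = Sweep(base)
        assert measure_rmp(sw) == pytest.approx(-60.0, abs=0.5)

    def test_short_recording_warns(self):
        sw = flat_sweep(-60.0, n=100_000)  # 10 s
        with pytest.warns(UserWarning):
            measure_rmp(sw)


class TestClassifySpontaneous:
    def test_no_spikes_is_none(self):
        assert classify_spontaneous(np.array([]), 60_000.0) == "none"

    def test_periodic_train_is_tonic(self):
        t = np.arange(0, 60_000, 500.0)
        assert classify_spontaneous(t, 60_000.0) == "tonic"

    def test_poisson_train_is_irregular(self, rng):
        """CV of a Poisson train is ~1, far above the 0.5 tonic bound."""
        isis = rng.exponential(500.0, 120)
        assert classify_spontaneous(np.cumsum(isis), 60_000.0) == "irregular"

    def test_clustered_spikes_are_bursting(self):
        bursts = [np.array([0, 30, 60, 90]) + k * 3000.0 for k in range(4)]
        assert classify_spontaneous(np.concatenate(bursts), 12_000.0) == "bursting"


class TestFindRheobase:
    @staticmethod
    def family(counts, amps):
        sweeps = []
        for amp in amps:
            sw = syn.synthesize_ap_waveform()
            sweeps.append(Sweep(sw.samples, epochs=[
                ProtocolEpoch(0, sw.duration_ms, amp, "step")]))
        return sweeps

    def test_first_spiking_step_is_rheobase(self, tf_family):
        sweeps, trains, truth = tf_family
        res = find_rheobase(sweeps, trains)
        counts = [t.size for t in truth.spike_times]
        first = next(i for i, c in enumerate(counts) if c > 0)
        assert res.index == first
        assert res.rheobase_pa == truth.extras["amplitudes_pa"][first]

    def test_never_spiking_flags_reluctant_candidate(self):
        sweeps = [flat_sweep(epochs=[ProtocolEpoch(0, 400, a, "step")])
                  for a in (20.0, 40.0)]
        res = find_rheobase(sweeps)
        assert res.reluctant_candidate and res.rheobase_pa is None

    def test_spiking_at_smallest_step_sets_boundary_warning(self):
        sw = syn.synthesize_ap_waveform()
        sweeps = [Sweep(sw.samples, epochs=[ProtocolEpoch(0, sw.duration_ms, a, "step")])
                  for a in (20.0, 40.0)]
        res = find_rheobase(sweeps)
        assert res.index == 0 and res.boundary_warning


class TestDischargeMetrics:
    @staticmethod
    def train_from(peaks_ms, amps_mv, start=0.0):
        from spinephys.membrane import SpikeTrain
        peaks_ms = np.asarray(peaks_ms, float)
        return SpikeTrain(threshold_times=peaks_ms - 1.0,
                          threshold_voltages=np.full(peaks_ms.size, -40.0),
                          peak_times=peaks_ms,
                          peak_voltages=np.asarray(amps_mv, float) - 40.0)

    def test_adaptation_from_isi_ratio(self):
        """ISIs 50, 50, 100 ms: first rate 20 Hz, last 10 Hz, adaptation 0.5."""
        tr = self.train_from([100, 150, 200, 300], [60, 60, 60, 60])
        m = discharge_metrics(tr, ProtocolEpoch(0, 1000, 100, "step"))
        assert m.instantaneous_freqs_hz[0] == pytest.approx(20.0)
        assert m.instantaneous_freqs_hz[-1] == pytest.approx(10.0)
        assert m.adaptation == pytest.approx(0.5)

    def test_attenuation_percentage(self):
        """Peak amplitudes 60, 55, 45 mV: attenuation 75 %."""
        tr = self.train_from([100, 200, 300], [60, 55, 45])
        m = discharge_metrics(tr, ProtocolEpoch(0, 1000, 100, "step"))
        assert m.attenuation_pct == pytest.approx(75.0)

    def test_latency_and_duration(self):
        tr = self.train_from([121, 901], [60, 60])
        m = discharge_metrics(tr, ProtocolEpoch(0, 1000, 100, "step"))
        assert m.first_spike_latency_ms == pytest.approx(120.0)
        assert m.discharge_duration_ms == pytest.approx(780.0)

    def test_single_spike_flags_undefined(self):
        tr = self.train_from([100], [60])
        m = discharge_metrics(tr, ProtocolEpoch(0, 1000, 100, "step"))
        assert np.isnan(m.adaptation) and m.flags

    @given(shift=st.floats(0.0, 500.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_to_time_axis_shift(self, shift):
        """All metrics are unchanged when the step and spikes shift together."""
        base = discharge_metrics(self.train_from([100, 150, 260], [60, 58, 55]),
                                 ProtocolEpoch(0, 1000, 100, "step"))
        moved = discharge_metrics(
            self.train_from(np.array([100, 150, 260]) + shift, [60, 58, 55]),
            ProtocolEpoch(shift, 1000, 100, "step"))
        assert moved.first_spike_latency_ms == pytest.approx(base.first_spike_latency_ms)
        assert moved.adaptation == pytest.approx(base.adaptation)
        assert moved.discharge_duration_ms == pytest.approx(base.discharge_duration_ms)

    def test_constant_trains_have_unit_adaptation_and_full_attenuation(self):
        tr = self.train_from([100, 200, 300, 400], [55, 55, 55, 55])
        m = discharge_metrics(tr, ProtocolEpoch(0, 1000, 100, "step"))
        assert m.adaptation == pytest.approx(1.0)
        assert m.attenuation_pct == pytest.approx(100.0)


class TestApWaveformFeatures:
    def test_triangular_ap_width_is_twice_half_rise(self):
        """A symmetric triangular AP with 2 ms half-rise has 4 ms base width."""
        dt = 0.1
        pre = np.full(200, -60.0)
        approach = np.linspace(-60.0, -40.0, 40, endpoint=False)  # 5 mV/ms
        up = np.linspace(-40.0, 20.0, 20, endpoint=False)
        down = np.linspace(20.0, -40.0, 20, endpoint=False)
        tail = np.linspace(-40.0, -45.0, 100)
        after = np.full(400, -45.0)
        sw = Sweep(np.concatenate([pre, approach, up, down, tail, after]), dt=dt)
        f = ap_waveform_features(sw)
        assert f.base_width_ms == pytest.approx(4.0, abs=0.15)

    def test_simulated_tonic_cell_matches_noise_free_reference(self):
        """Features on a noisy tonic sweep lie within 5 % of those measured
        on the same model integrated without noise."""
        ref_sweeps, _ = syn.simulate_current_clamp(
            syn.preset("TF", noise_sd=0.0), amplitudes_pa=np.array([120.0]))
        noisy_sweeps, _ = syn.simulate_current_clamp(
            syn.preset("TF", noise_sd=0.5), amplitudes_pa=np.array([120.0]), seed=4)
        ref = ap_waveform_features(ref_sweeps[0])
        noisy = ap_waveform_features(noisy_sweeps[0])
        assert noisy.peak_amplitude_mv == pytest.approx(ref.peak_amplitude_mv, rel=0.05)
        assert noisy.ahp_amplitude_mv == pytest.approx(ref.ahp_amplitude_mv, rel=0.05)
        assert noisy.base_width_ms == pytest.approx(ref.base_width_ms, rel=0.05)
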