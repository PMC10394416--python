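"""Simulator oracles: STDP arithmetic, noise scaling, LIF closed form,
conservation, and the Kesten geometric-Brownian limit."""

import math

import numpy as np
import pytest

from spinedyn import simulator as sim
from spinedyn.errors import ConfigurationError

DT = 1e-4


class TestSTDPRules:
    def test_potentiation_arithmetic(self):
        p = sim.STDPParams()
        assert sim.stdp_potentiate(1.0, -0.5, p) == pytest.approx(1 + 0.007 * math.exp(-1))
        assert sim.stdp_potentiate(1.0, 0.0, p) == pytest.approx(1.007)
        assert sim.stdp_potentiate(1.0, -1e6, p) == pytest.approx(1.0)

    def test_depression_arithmetic(self):
        p = sim.STDPParams()
        assert sim.stdp_depress(1.0, 0.5, p) == pytest.approx(1 - 0.003 * math.exp(-1))
        assert sim.stdp_depress(0.0, 0.5, p) == 0.0  # multiplicative rule fixes zero
        assert sim.stdp_depress(2.0, 1e6, p) == pytest.approx(2.0)

    def test_sign_contracts(self):
        p = sim.STDPParams()
        with pytest.raises(ConfigurationError):
            sim.stdp_potentiate(1.0, 0.5, p)
        with pytest.raises(ConfigurationError):
            sim.stdp_depress(1.0, -0.5, p)

    def test_event_kernel_matches_sequential_pairing_oracle(self):
        """Hand-written 3-spike scenario: the vectorized kernel must equal
        the sequential application of the scalar STDP rules."""
        p = sim.STDPParams()
        tau_steps = (p.tau_stdp * 1e-3) / DT  # = 5 steps
        w = np.array([[1.0, 0.2]])
        v = np.zeros(1)
        last_update = np.zeros(1, dtype=np.int64)
        last_pre = np.full((1, 2), -1, dtype=np.int64)
        last_post = np.full(1, -1, dtype=np.int64)
        posts = np.zeros(1, dtype=np.int64)
        gain, theta = 20.0, 10.0  # input 0 supra-, input 1 sub-threshold
        ev_step = np.array([10, 13, 20], dtype=np.int64)
        ev_neuron = np.zeros(3, dtype=np.int64)
        ev_input = np.array([0, 1, 0], dtype=np.int64)
        decay = math.exp(-DT / (10.0 * 1e-3))
        sim._event_kernel(
            ev_step, ev_neuron, ev_input, w, v, last_update, last_pre, last_post,
            decay, gain, theta, p.c_p, p.c_d, tau_steps, posts, True,
        )
        ms = DT * 1e3  # step -> milliseconds
        w0 = sim.stdp_potentiate(1.0, -0.0, p)  # post at step 10
        w0 = sim.stdp_depress(w0, 10 * ms, p)  # pre at 20, last post at 10
        w0 = sim.stdp_potentiate(w0, -0.0, p)  # post at step 20
        w1 = sim.stdp_depress(0.2, 3 * ms, p)  # pre at 13, last post at 10
        w1 = sim.stdp_potentiate(w1, -7 * ms, p)  # post at 20, last pre at 13
        assert posts[0] == 2
        assert w[0, 0] == pytest.approx(w0, rel=1e-12)
        assert w[0, 1] == pytest.approx(w1, rel=1e-12)


class TestIntrinsicNoise:
    def test_zero_noise_is_identity(self, rng):
        w = rng.uniform(0, 1, 100)
        out = sim.apply_intrinsic_noise(w, 0.01, sim.NoiseParams(0.0, 0.0), rng)
        assert np.array_equal(out, w)

    def test_multiplicative_spread_scale(self):
        rng = np.random.default_rng(21)
        w = np.ones(100_000)
        out = sim.apply_intrinsic_noise(w, 0.01, sim.NoiseParams(0.2, 0.0), rng)
        assert out.std() == pytest.approx(0.2 * math.sqrt(0.01), rel=0.02)

    def test_additive_noise_clipped_at_zero(self):
        rng = np.random.default_rng(22)
        w = np.zeros(100_000)
        out = sim.apply_intrinsic_noise(w, 0.01, sim.NoiseParams(0.0, 0.5), rng)
        assert (out >= 0).all()
        # clipped half-normal: mean = sigma * sqrt(1/(2 pi))
        sig = 0.5 * math.sqrt(0.01)
        assert out.mean() == pytest.approx(sig / math.sqrt(2 * math.pi), rel=0.05)


class TestHeterosynapticScale:
    def test_proportional_example(self):
        assert np.allclose(sim.heterosynaptic_scale([1.0, 3.0], 8.0), [2.0, 6.0])

    def test_identity_when_already_on_target(self):
        w = np.array([0.5, 1.5, 2.0])
        assert np.allclose(sim.heterosynaptic_scale(w, 4.0), w)

    def test_ratios_preserved(self, rng):
        w = rng.uniform(0.1, 2.0, 50)
        out = sim.heterosynaptic_scale(w, 17.0)
        assert out.sum() == pytest.approx(17.0, rel=1e-12)
        assert np.allclose(out / out[0], w / w[0])

    def test_zero_rows_skipped(self):
        w = np.array([[0.0, 0.0], [1.0, 1.0]])
        out = sim.heterosynaptic_scale(w, np.array([5.0, 5.0]))
        assert np.array_equal(out[0], [0.0, 0.0])
        assert out[1].sum() == pytest.approx(5.0)


class TestInputSpikes:
    def test_silent_protocol_empty(self, rng):
        trains = sim.generate_input_spikes(sim.SILENT, 1.0, 10, rng)
        assert all(t.size == 0 for t in trains)

    def test_poisson_count(self):
        rng = np.random.default_rng(23)
        proto = sim.StimulusProtocol("poisson", 10.0, stim_proportion=1.0)
        (train,) = sim.generate_input_spikes(proto, 100.0, 1, rng)
        assert abs(train.size - 1000) < 3 * math.sqrt(1000)

    def test_periodic_200hz_count(self):
        rng = np.random.default_rng(24)
        proto = sim.StimulusProtocol("periodic", 200.0, stim_proportion=1.0)
        trains = sim.generate_input_spikes(proto, 1.0, 5, rng)
        assert all(t.size == 200 for t in trains)

    def test_unstimulated_inputs_silent(self):
        rng = np.random.default_rng(25)
        proto = sim.StimulusProtocol("poisson", 10.0, stim_proportion=0.5)
        trains = sim.generate_input_spikes(proto, 10.0, 10, rng)
        assert all(t.size > 0 for t in trains[:5])
        assert all(t.size == 0 for t in trains[5:])

    def test_unresolvable_rate_rejected(self, rng):
        proto = sim.StimulusProtocol("poisson", 20_000.0)
        with pytest.raises(ConfigurationError):
            sim.generate_input_spikes(proto, 1.0, 1, rng, dt=1e-4)


class TestLIF:
    def test_no_input_no_output(self):
        neuron = sim.NeuronParams(n_inputs=2, n_neurons=1)
        out = sim.simulate_lif(neuron, [1.0, 1.0], [np.empty(0), np.empty(0)],
                               duration=0.1)
        assert out.size == 0

    @pytest.mark.parametrize("drive", [15.0, 20.0, 40.0])
    def test_constant_drive_isi_closed_form(self, drive):
        neuron = sim.NeuronParams(n_inputs=1, n_neurons=1)
        out = sim.simulate_lif(
            neuron, [0.0], [np.empty(0)], dt=DT, const_drive=drive, duration=0.5
        )
        isi = np.diff(out)
        theory = (neuron.tau_m * 1e-3) * math.log(drive / (drive - neuron.threshold))
        assert np.all(np.abs(isi - theory) <= DT + 1e-12)

    def test_suprathreshold_input_relays_every_spike(self):
        neuron = sim.NeuronParams(n_inputs=1, n_neurons=1)
        pre = np.array([0.01, 0.05, 0.2])
        out = sim.simulate_lif(neuron, [1.0], [pre], coupling_gain=15.0, duration=0.3)
        assert out.size == pre.size


class TestRunSimulation:
    @staticmethod
    def _small(**kw):
        defaults = dict(
            neuron=sim.NeuronParams(n_neurons=20, n_inputs=20),
            duration=1.0,
            seed=42,
        )
        defaults.update(kw)
        return sim.SimulationConfig(**defaults)

    def test_all_dynamics_off_weights_frozen(self):
        w0 = np.random.default_rng(0).uniform(0, 1, (20, 20))
        cfg = self._small(noise=sim.NoiseParams(0.0, 0.0), stdp_enabled=False)
        res = sim.run_simulation(cfg, initial_weights=w0)
        assert np.array_equal(res.final_weights, w0)

    def test_deterministic_given_seed(self):
        cfg = self._small(protocol=sim.CONTROL_10HZ)
        a = sim.run_simulation(cfg)
        b = sim.run_simulation(cfg)
        assert np.array_equal(a.final_weights, b.final_weights)
        assert np.array_equal(a.post_spike_counts, b.post_spike_counts)

    def test_weights_never_negative_and_conserved(self):
        cfg = self._small(protocol=sim.HFS_200HZ, noise=sim.NoiseParams(0.3, 0.05))
        res = sim.run_simulation(cfg)
        assert (res.final_weights >= 0).all()
        assert res.scaling_max_rel_dev <= 1e-9

    def test_zero_stim_proportion_equals_silent(self):
        import dataclasses

        hfs0 = dataclasses.replace(sim.HFS_200HZ, stim_proportion=0.0)
        a = sim.run_simulation(self._small(protocol=hfs0))
        b = sim.run_simulation(self._small(protocol=sim.SILENT))
        assert np.array_equal(a.final_weights, b.final_weights)

    def test_kesten_limit_variance(self):
        """Scaling and STDP off, additive off: Var[ln w] ~ m^2 T (GBM limit)."""
        cfg = sim.SimulationConfig(
            neuron=sim.NeuronParams(n_neurons=100, n_inputs=100),
            noise=sim.NoiseParams(0.15, 0.0),
            duration=5.0, scaling_enabled=False, stdp_enabled=False, seed=77,
        )
        res = sim.run_simulation(cfg, initial_weights=np.full((100, 100), 0.5))
        var = np.log(res.final_weights.ravel()).var()
        assert var == pytest.approx(0.15**2 * 5.0, rel=0.10)

    def test_protocol_suite_shares_initial_weights(self):
        suite = sim.run_protocol_suite(self._small(), 42)
        assert set(suite) == {"silent", "control", "hfs"}
        assert suite["silent"].final_weights.shape == (20, 20)
        for res in suite.values():
            assert (res.final_weights >= 0).all()
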