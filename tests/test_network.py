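"""Network construction, stimulation and simulation invariants."""

import numpy as np
import pytest

from updownnet.network import (
    Connectivity,
    NetworkConfig,
    StimulationProtocol,
    Stimulus,
    build_network,
    make_stimulus,
    run_deterministic_trials,
    simulate,
)
from updownnet.synapses import ConductancePair, SynapseParams, conductance_step


class TestBuildNetwork:
    def test_mean_in_degree_matches_p(self):
        degs = []
        for seed in range(5):
            conn = build_network(NetworkConfig(seed=seed))
            degs.append(conn.in_degree().mean())
        expected = 0.01 * (2**10 - 1)
        se = np.sqrt(expected / (2**10 * len(degs)))  # binomial s.e. of the mean
        assert abs(np.mean(degs) - expected) < 3 * se

    def test_near_zero_p_gives_empty_edge_set(self):
        conn = build_network(NetworkConfig(N=100, p=1e-9, seed=0))
        assert conn.n_edges == 0

    def test_deterministic_under_seed(self):
        a = build_network(NetworkConfig(N=100, p=0.05, seed=3))
        b = build_network(NetworkConfig(N=100, p=0.05, seed=3))
        assert a.n_edges == b.n_edges
        np.testing.assert_array_equal(a.targets, b.targets)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_no_self_loops(self):
        conn = build_network(NetworkConfig(N=200, p=0.1, seed=1))
        for i in range(conn.N):
            assert i not in conn.targets[conn.indptr[i] : conn.indptr[i + 1]]

    def test_composition_counts(self, mixed_connectivity):
        labels = mixed_connectivity.labels
        n = len(labels)
        assert np.sum(labels == "CH") == round(0.16 * n)
        assert np.sum(labels == "RS") == round(0.64 * n)
        assert np.sum(labels == "LTS") == round(0.20 * n)

    def test_in_degree_split_consistent(self, small_connectivity):
        conn = small_connectivity
        np.testing.assert_array_equal(
            conn.n_ex + conn.n_in, np.bincount(conn.targets, minlength=conn.N)
        )

    def test_invalid_composition_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            NetworkConfig(exc_composition={"RS": 0.5, "CH": 0.2})


class TestStimulus:
    def test_full_fraction_targets_everyone(self, small_connectivity):
        stim = make_stimulus(StimulationProtocol(fraction=1.0), small_connectivity)
        assert np.all(stim.amplitude > 0)

    def test_sixteenth_fraction_count(self, mixed_connectivity):
        stim = make_stimulus(
            StimulationProtocol(fraction=1 / 16, I_stim=10), mixed_connectivity
        )
        assert np.sum(stim.amplitude > 0) == 64  # floor(1024/16)

    def test_current_zero_after_stimulus(self, small_connectivity):
        stim = make_stimulus(
            StimulationProtocol(t_stim=50.0, fraction=0.5), small_connectivity
        )
        assert np.all(stim.current(51.0) == 0)
        assert np.any(stim.current(49.0) > 0)

    def test_disallowed_fraction(self):
        with pytest.raises(ValueError, match="fraction"):
            StimulationProtocol(fraction=0.3)


class TestSimulate:
    def test_rest_is_absorbing_without_noise(self, small_connectivity):
        sim = simulate(small_connectivity, SynapseParams(D=0.0), 300.0, seed=0)
        assert sim.raster.n_spikes == 0
        assert np.ptp(sim.mean_v) == pytest.approx(0.0, abs=1e-9)

    def test_reset_accounting(self, weak_noise_sim):
        assert weak_noise_sim.n_resets == weak_noise_sim.raster.n_spikes
        assert weak_noise_sim.raster.n_spikes > 0

    def test_spike_times_strictly_increasing_per_neuron(self, weak_noise_sim):
        ids = np.unique(weak_noise_sim.raster.ids)[:20]
        for j in ids:
            t = weak_noise_sim.spike_times(j)
            assert np.all(np.diff(t) > 0)

    def test_conductances_nonnegative(self, intermittent_sim):
        assert intermittent_sim.mean_Gex.min() >= 0
        assert intermittent_sim.mean_Gin.min() >= 0

    def test_zero_in_degree_neuron_has_zero_conductance(self):
        # two disconnected neurons, D>0: noise amplitude sqrt(2 D n) = 0
        conn = Connectivity(
            indptr=np.zeros(3, dtype=np.int64),
            targets=np.empty(0, dtype=np.int64),
            labels=np.array(["RS", "LTS"], dtype=object),
            is_exc=np.array([True, False]),
            n_ex=np.zeros(2, dtype=np.int64),
            n_in=np.zeros(2, dtype=np.int64),
        )
        sim = simulate(
            conn, SynapseParams(D=1e-4), 200.0, seed=4, record_neurons=[0, 1]
        )
        assert np.all(sim.Gex == 0)
        assert np.all(sim.Gin == 0)
        assert sim.raster.n_spikes == 0

    def test_disconnected_rs_with_constant_current_adapts(self):
        """Tonic spiking with increasing inter-spike intervals at I = 6."""
        conn = Connectivity(
            indptr=np.zeros(2, dtype=np.int64),
            targets=np.empty(0, dtype=np.int64),
            labels=np.array(["RS"], dtype=object),
            is_exc=np.array([True]),
            n_ex=np.zeros(1, dtype=np.int64),
            n_in=np.zeros(1, dtype=np.int64),
        )
        stim = Stimulus(amplitude=np.array([6.0]), t_stim=1000.0)
        sim = simulate(conn, SynapseParams(D=0.0), 1000.0, stimulus=stim, seed=0)
        t = sim.spike_times(0)
        assert len(t) >= 3
        isi = np.diff(t)
        assert isi[-1] > isi[0]  # spike-frequency adaptation

    def test_kernel_matches_python_conductance_step(self):
        """Deterministic conductance decay agrees with the reference stepper."""
        conn = Connectivity(  # disconnected neuron: no jump arrivals
            indptr=np.zeros(2, dtype=np.int64),
            targets=np.empty(0, dtype=np.int64),
            labels=np.array(["RS"], dtype=object),
            is_exc=np.array([True]),
            n_ex=np.zeros(1, dtype=np.int64),
            n_in=np.zeros(1, dtype=np.int64),
        )
        rng = np.random.default_rng(0)
        sim = simulate(
            conn,
            SynapseParams(D=0.0),
            50.0,
            seed=0,
            record_neurons=[0],
            initial_state=(
                np.array([-70.0]), np.array([-14.0]),
                np.array([0.3]), np.array([0.1]),
            ),
        )
        params = SynapseParams(D=0.0)
        G = ConductancePair(0.3, 0.1)
        for _ in range(int(round(50.0 / 0.05))):
            G = conductance_step(G, 0.05, 0, 0, 0, 0, params, rng)
        assert sim.Gex[-1, 0] == pytest.approx(G.G_ex, rel=1e-9)
        assert sim.Gin[-1, 0] == pytest.approx(G.G_in, rel=1e-9)

    def test_step_size_convergence(self, small_connectivity):
        """Halving dt changes the time-averaged rate of a noisy run by <5%."""
        rates = []
        for dt in (0.05, 0.025):
            sim = simulate(
                small_connectivity, SynapseParams(D=2e-4), 2000.0, dt=dt, seed=5
            )
            rates.append(sim.raster.n_spikes / sim.t_end)
        assert abs(rates[1] - rates[0]) / rates[0] < 0.05

    def test_blowup_detected(self):
        conn = Connectivity(
            indptr=np.zeros(2, dtype=np.int64),
            targets=np.empty(0, dtype=np.int64),
            labels=np.array(["RS"], dtype=object),
            is_exc=np.array([True]),
            n_ex=np.zeros(1, dtype=np.int64),
            n_in=np.zeros(1, dtype=np.int64),
        )
        with pytest.raises(RuntimeError, match="blow-up"):
            simulate(
                conn,
                SynapseParams(D=0.0),
                10.0,
                seed=0,
                initial_state=(
                    np.array([np.nan]),
                    np.array([0.0]),
                    np.array([0.0]),
                    np.array([0.0]),
                ),
            )


class TestDeterministicTrials:
    def test_short_trials_discarded(self, mixed_connectivity):
        config = NetworkConfig(
            seed=101,
            exc_composition={"RS": 0.8, "CH": 0.2},
            inh_composition={"LTS": 1.0},
        )
        protocols = [
            StimulationProtocol(I_stim=20, t_stim=50, fraction=1.0, target_seed=2),
            StimulationProtocol(I_stim=10, t_stim=100, fraction=1.0, target_seed=0),
        ]
        kept = run_deterministic_trials(
            config,
            SynapseParams(D=0.0),
            protocols,
            t_end=2500.0,
            min_duration=400.0,
            seed=3,
        )
        for trial in kept:
            assert trial.free_activity_ms >= 400.0

    def test_noise_rejected(self):
        with pytest.raises(ValueError, match="D = 0"):
            run_deterministic_trials(
                NetworkConfig(N=64, p=0.05), SynapseParams(D=1e-6), []
            )
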