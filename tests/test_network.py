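"""Hierarchical competitive network: connectivity, dynamics, learning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from visnetscenes import network
from visnetscenes.config import LayerConfig, default_layers


def tiny_configs(grid=8, fan_in=12, sigma=3.0):
    layers = []
    for k in range(4):
        layers.append(LayerConfig(grid_size=grid, fan_in=fan_in,
                                  conn_sigma=sigma, inhib_sigma=1.0,
                                  inhib_contrast=1.5,
                                  sparseness_percentile=0.9,
                                  sigmoid_slope=40.0, learning_rate=0.05))
    return layers


@pytest.fixture()
def tiny_net():
    return network.init_network(tiny_configs(), retina_size=8, n_channels=4,
                                seed=3, check_coverage=False)


class TestInit:
    def test_seed_determinism(self):
        a = network.init_network(tiny_configs(), 8, 4, seed=5, check_coverage=False)
        b = network.init_network(tiny_configs(), 8, 4, seed=5, check_coverage=False)
        for la, lb in zip(a.layers, b.layers):
            assert np.array_equal(la.src_idx, lb.src_idx)
            assert np.array_equal(la.weights, lb.weights)

    def test_unit_weight_norms(self, tiny_net):
        for layer in tiny_net.layers:
            assert np.allclose(np.linalg.norm(layer.weights, axis=1), 1.0,
                               atol=1e-9)

    def test_coverage_by_chain_union(self):
        """Graph-reachability oracle: a central layer-4 neuron sees >=95% of
        the retina through composed afferent chains."""
        net = network.init_network(default_layers(32, 32), 32, 24, seed=0)
        assert network.receptive_coverage(net) >= 0.95

    def test_narrow_connectivity_rejected(self):
        with pytest.raises(ValueError, match="coverage"):
            network.init_network(tiny_configs(sigma=0.05), 8, 4, seed=0)

    def test_sources_in_range(self, tiny_net):
        assert tiny_net.layers[0].src_idx.max() < 8 * 8 * 4
        for layer in tiny_net.layers[1:]:
            assert layer.src_idx.max() < 64


class TestPropagate:
    def test_zero_input(self, tiny_net):
        assert np.allclose(network.propagate(np.zeros(8 * 8 * 4),
                                             tiny_net.layers[0]), 0.0)

    def test_dense_matrix_oracle(self, tiny_net):
        """Sparse gather-product equals a dense matrix-vector product with
        zeros at absent synapses (duplicates accumulated)."""
        rng = np.random.default_rng(0)
        layer = tiny_net.layers[1]
        x = rng.uniform(0, 1, 64)
        dense = np.zeros((layer.n, 64))
        for i in range(layer.n):
            for j, w in zip(layer.src_idx[i], layer.weights[i]):
                dense[i, j] += w
        assert np.allclose(network.propagate(x, layer), dense @ x, atol=1e-9)

    def test_single_source(self):
        layer = network.Layer(
            cfg=tiny_configs()[0],
            src_idx=np.array([[2, 5]]), weights=np.array([[0.6, 0.8]]),
            trace=np.zeros(1))
        x = np.zeros(8)
        x[2] = 0.5
        assert network.propagate(x, layer) == pytest.approx(0.3)


class TestLateralInhibition:
    def test_zero_in_zero_out(self):
        assert np.allclose(network.lateral_inhibit(np.zeros(64), 1.0, 1.5), 0.0)

    def test_isolated_peak_stays_max(self):
        h = np.zeros(64)
        h[27] = 1.0
        out = network.lateral_inhibit(h, 1.0, 1.5)
        assert np.argmax(out) == 27

    def test_uniform_field_suppressed(self):
        """Equal neighbours suppress each other; an isolated neuron of the
        same amplitude survives."""
        uniform = network.lateral_inhibit(np.full(64, 1.0), 1.0, 1.5)
        single = np.zeros(64)
        single[27] = 1.0
        isolated = network.lateral_inhibit(single, 1.0, 1.5)
        assert uniform.max() < isolated[27]


class TestSigmoidSparseness:
    def test_percentile_sets_active_fraction(self):
        rng = np.random.default_rng(0)
        h = rng.uniform(0, 1, 400)
        y = network.apply_sigmoid_sparseness(h, 0.95, 100.0)
        assert abs(int((y > 0.5).sum()) - 20) <= 1

    def test_hard_limit_is_top_k_mask(self):
        rng = np.random.default_rng(1)
        h = rng.uniform(0, 1, 100)
        y = network.apply_sigmoid_sparseness(h, 0.9, 1e8)
        assert set(np.round(y[np.argsort(h)[-9:]], 6)) == {1.0}
        assert y[np.argsort(h)[0]] == pytest.approx(0.0, abs=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        h = rng.uniform(0, 1, 50)
        y = network.apply_sigmoid_sparseness(h, 0.8, 30.0)
        order = np.argsort(h)
        assert np.all(np.diff(y[order]) >= -1e-12)

    def test_degenerate_uniform(self):
        y = network.apply_sigmoid_sparseness(np.full(16, 0.3), 0.9, 50.0)
        assert np.allclose(y, 0.5)


class TestTrace:
    def test_eta_zero_is_instantaneous(self):
        y = np.array([0.2, 0.7])
        assert np.array_equal(network.update_trace(y, np.array([1.0, 1.0]), 0.0), y)

    def test_geometric_convergence(self):
        y = np.array([1.0])
        trace = np.array([0.0])
        eta = 0.6
        for t in range(1, 8):
            trace = network.update_trace(y, trace, eta)
            assert abs(trace[0] - 1.0) == pytest.approx(eta ** t, abs=1e-12)

    def test_two_step_hand_recursion(self):
        """eta=0.8, y sequence {1, 0} -> trace 0.16."""
        trace = np.zeros(1)
        trace = network.update_trace(np.array([1.0]), trace, 0.8)
        trace = network.update_trace(np.array([0.0]), trace, 0.8)
        assert trace[0] == pytest.approx(0.16, abs=1e-12)

    def test_loop_oracle(self):
        rng = np.random.default_rng(0)
        ys = rng.uniform(0, 1, (20, 5))
        eta = 0.73
        trace = np.zeros(5)
        for y in ys:
            trace = network.update_trace(y, trace, eta)
        expected = np.zeros(5)
        for y in ys:  # explicit recursion oracle
            expected = (1 - eta) * y + eta * expected
        assert np.allclose(trace, expected, atol=1e-12)


class TestLearnStep:
    def _one_neuron_layer(self, w, lr=0.05):
        cfg = LayerConfig(grid_size=1, fan_in=len(w), conn_sigma=1.0,
                          inhib_sigma=1.0, inhib_contrast=1.5,
                          sparseness_percentile=0.5, sigmoid_slope=1.0,
                          learning_rate=lr)
        return network.Layer(cfg=cfg, src_idx=np.arange(len(w))[None, :],
                             weights=np.array([w], dtype=float),
                             trace=np.ones(1))

    def test_hand_arithmetic_oracle(self):
        """w=(0.6,0.8), alpha=0.05, trace=1, x=(1,0) -> normalize(0.65, 0.8)."""
        layer = self._one_neuron_layer([0.6, 0.8])
        network.learn_step(layer, np.array([1.0, 0.0]))
        expected = np.array([0.65, 0.8]) / np.linalg.norm([0.65, 0.8])
        assert np.allclose(layer.weights[0], expected, atol=1e-12)

    def test_zero_rate_leaves_weights(self):
        layer = self._one_neuron_layer([0.6, 0.8])
        layer.trace = np.zeros(1)
        network.learn_step(layer, np.array([1.0, 1.0]))
        assert np.allclose(layer.weights[0], [0.6, 0.8])

    def test_zero_alpha_noop(self):
        layer = self._one_neuron_layer([0.6, 0.8], lr=0.0)
        network.learn_step(layer, np.array([1.0, 1.0]))
        assert np.array_equal(layer.weights[0], [0.6, 0.8])

    def test_weights_stay_nonnegative_unit_norm(self, tiny_net):
        rng = np.random.default_rng(0)
        for layer in tiny_net.layers:
            layer.trace = rng.uniform(0, 1, layer.n)
            network.learn_step(layer, rng.uniform(0, 1, 300))
            assert np.all(layer.weights >= 0)
            assert np.allclose(np.linalg.norm(layer.weights, axis=1), 1.0,
                               atol=1e-9)


class TestPresentAndTraining:
    def test_inference_is_deterministic(self, tiny_net):
        rng = np.random.default_rng(0)
        v1 = rng.uniform(0, 1, 8 * 8 * 4)
        a = network.present(tiny_net, v1, learn=False)
        b = network.present(tiny_net, v1, learn=False)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_blank_input_degenerates_to_uniform(self, tiny_net):
        ys = network.present(tiny_net, np.zeros(8 * 8 * 4), learn=False)
        assert np.allclose(ys[3], 0.5)

    def test_sequence_resets_trace_and_counts(self, tiny_net):
        rng = np.random.default_rng(0)
        transforms = [rng.uniform(0, 1, 8 * 8 * 4) for _ in range(7)]
        tiny_net.layers[0].trace += 1.0
        before = tiny_net.presentations
        network.train_object_sequence(tiny_net, transforms)
        assert tiny_net.presentations - before == 7

    def test_eta_zero_reduces_to_plain_hebb(self):
        """With eta=0 the trace equals the instantaneous rate, so one
        presentation must match a hand-computed Hebb update bit for bit."""
        net = network.init_network(tiny_configs(), 8, 4, seed=9,
                                   check_coverage=False)
        net.eta = 0.0
        rng = np.random.default_rng(4)
        v1 = rng.uniform(0, 1, 8 * 8 * 4)
        x = v1 / np.linalg.norm(v1)
        layer = net.layers[0]
        h = network.propagate(x, layer)
        hp = network.lateral_inhibit(h, layer.cfg.inhib_sigma,
                                     layer.cfg.inhib_contrast)
        y = network.apply_sigmoid_sparseness(hp, layer.cfg.sparseness_percentile,
                                             layer.cfg.sigmoid_slope)
        w = layer.weights + layer.cfg.learning_rate * y[:, None] * x[layer.src_idx]
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        network.present(net, v1, learn=True)
        assert np.array_equal(net.layers[0].weights, w)

    def test_zero_epochs_is_identity(self, tiny_net):
        w0 = [layer.weights.copy() for layer in tiny_net.layers]
        network.train_all(tiny_net, [[np.ones(8 * 8 * 4)]], epochs=0)
        for layer, w in zip(tiny_net.layers, w0):
            assert np.array_equal(layer.weights, w)

    def test_weight_change_shrinks_with_training(self, tiny_net):
        rng = np.random.default_rng(1)
        dataset = [[rng.uniform(0, 1, 8 * 8 * 4) for _ in range(5)]
                   for _ in range(2)]
        hist = network.train_all(tiny_net, dataset, epochs=10)
        dws = [sum(row) for row in hist["mean_abs_dw"]]
        assert dws[-1] < dws[0]

    def test_empty_dataset_rejected(self, tiny_net):
        with pytest.raises(ValueError):
            network.train_all(tiny_net, [], epochs=1)


class TestCheckpoint:
    def test_round_trip_bit_exact(self, tiny_net, tmp_path):
        rng = np.random.default_rng(0)
        network.present(tiny_net, rng.uniform(0, 1, 8 * 8 * 4), learn=True)
        path = tmp_path / "net.npz"
        network.save_network(tiny_net, path)
        loaded = network.load_network(path)
        for la, lb in zip(tiny_net.layers, loaded.layers):
            assert np.array_equal(la.weights, lb.weights)
            assert np.array_equal(la.src_idx, lb.src_idx)
            assert np.array_equal(la.trace, lb.trace)
        # RNG stream continues identically
        assert np.array_equal(tiny_net.perm_rng.permutation(10),
                              loaded.perm_rng.permutation(10))
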