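import numpy as np
import pytest

from srmd.config import StudyConfig
from _oracles import PlainANN, numerical_gradient

from srmd.gwann import (
    backprop_deltas,
    evaluate_accuracy,
    forward,
    geo_weights,
    gradients_from_deltas,
    init_model,
    load_model,
    predict,
    save_model,
    train,
    train_network,
    update_weights,
    weighted_error,
)


def make_model(layer_sizes=(5, 4, 3), seed=0, bandwidth_m=500.0):
    anchors = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0]])[: layer_sizes[-1]]
    return init_model(list(layer_sizes), anchors, seed=seed, bandwidth_m=bandwidth_m)


class TestInit:
    def test_same_seed_identical_weights(self):
        a, b = make_model(seed=5), make_model(seed=5)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_different_seeds_differ(self):
        a, b = make_model(seed=5), make_model(seed=6)
        assert any(not np.array_equal(wa, wb) for wa, wb in zip(a.weights, b.weights))

    def test_input_width_must_match_factor_count(self):
        with pytest.raises(ValueError, match="5 neurons"):
            make_model(layer_sizes=(4, 4, 3))

    def test_empty_anchors_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            init_model([5, 4, 1], np.empty((0, 2)), seed=0)


class TestGeoWeights:
    def test_kernel_values(self):
        anchors = np.array([[0.0, 0.0]])
        samples = np.array([[0.0, 0.0], [500.0, 0.0], [0.0, -500.0]])
        gw = geo_weights(samples, anchors, bandwidth_m=500.0)
        assert gw.matrix[0, 0] == pytest.approx(1.0)           # zero distance
        assert gw.matrix[1, 0] == pytest.approx(np.exp(-0.5))  # one bandwidth
        assert gw.matrix[2, 0] == gw.matrix[1, 0]              # equidistant

    def test_weights_in_unit_interval_and_decreasing(self):
        rng = np.random.default_rng(0)
        gw = geo_weights(rng.uniform(0, 5000, (50, 2)), rng.uniform(0, 5000, (7, 2)),
                         bandwidth_m=800.0)
        assert np.all((gw.matrix > 0) & (gw.matrix <= 1))

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            geo_weights(np.zeros((1, 2)), np.zeros((1, 2)), bandwidth_m=0.0)


class TestForward:
    def test_zero_network_outputs_zero(self):
        m = make_model()
        for w in m.weights:
            w[:] = 0.0
        for b in m.biases:
            b[:] = 0.0
        out = forward(m, np.full(5, 0.5))[-1]
        np.testing.assert_array_equal(out, np.zeros((1, 3)))

    def test_single_path_matches_hand_evaluation(self):
        # 5-1-1 net with only the first input connected: tanh(w2 tanh(w1 x))
        m = make_model(layer_sizes=(5, 1, 1))
        m.anchors_xy = m.anchors_xy[:1]
        w1, w2 = 0.7, -1.3
        m.weights[0][:] = 0.0
        m.weights[0][0, 0] = w1
        m.weights[1][:] = w2
        m.biases[0][:] = 0.0
        m.biases[1][:] = 0.0
        x = np.array([0.4, 0.0, 0.0, 0.0, 0.0])
        expected = np.tanh(w2 * np.tanh(w1 * 0.4))
        assert forward(m, x)[-1][0, 0] == pytest.approx(expected, rel=1e-12)

    def test_outputs_bounded_by_activation(self):
        m = make_model(seed=3)
        out = forward(m, np.random.default_rng(1).uniform(0, 1, (40, 5)))[-1]
        assert np.all((out > -1) & (out < 1))

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            forward(make_model(), np.array([np.nan, 0, 0, 0, 0]))


class TestWeightedError:
    def test_perfect_predictions_give_zero(self):
        assert weighted_error([0.3, 0.4], [0.3, 0.4], [1.0, 0.5]) == 0.0

    def test_unit_weights_reduce_to_half_sse(self):
        p, r = np.array([0.1, 0.5]), np.array([0.2, 0.3])
        assert weighted_error(p, r, np.ones(2)) == pytest.approx(0.5 * np.sum((p - r) ** 2))

    def test_hand_computed_two_element_case(self):
        # 1/2 (1*0.04 + 0.5*0.04) = 0.03
        e = weighted_error([0.2, 0.6], [0.4, 0.8], [1.0, 0.5])
        assert e == pytest.approx(0.03)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            weighted_error([0.1], [0.1, 0.2], [1.0, 1.0])


class TestBackprop:
    def test_perfect_predictions_zero_output_deltas(self):
        m = make_model()
        x = np.random.default_rng(2).uniform(0, 1, (4, 5))
        cache = forward(m, x)
        targets_equal_outputs = cache[-1]
        d = np.ones_like(targets_equal_outputs)
        # feed each sample its own outputs as targets, one output at a time
        deltas = backprop_deltas(m, cache, np.zeros(4), d * 0.0)
        np.testing.assert_array_equal(deltas[-1], np.zeros_like(cache[-1]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_analytic_gradient_matches_central_difference(self, seed):
        rng = np.random.default_rng(seed)
        m = make_model(seed=seed)
        x = rng.uniform(0, 1, (6, 5))
        r = rng.uniform(0, 1, 6)
        d = geo_weights(rng.uniform(0, 2000, (6, 2)), m.anchors_xy,
                        bandwidth_m=700.0).matrix
        cache = forward(m, x)
        deltas = backprop_deltas(m, cache, r, d)
        g_w, g_b = gradients_from_deltas(cache, deltas)
        n_w, n_b = numerical_gradient(m, x, r, d)
        for ga, gn in zip(g_w + g_b, n_w + n_b):
            np.testing.assert_allclose(ga, gn, rtol=1e-6, atol=1e-9)

    def test_zero_geo_weight_silences_output_neuron(self):
        m = make_model()
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, (3, 5))
        r = rng.uniform(0, 1, 3)
        d = np.ones((3, 3))
        d[:, 1] = 0.0
        cache = forward(m, x)
        deltas = backprop_deltas(m, cache, r, d)
        np.testing.assert_array_equal(deltas[-1][:, 1], np.zeros(3))

    def test_missing_cache_rejected(self):
        with pytest.raises(ValueError, match="cache"):
            backprop_deltas(make_model(), None, np.zeros(1), np.ones((1, 3)))


class TestUpdate:
    def test_zero_learning_rate_keeps_weights(self):
        m = make_model()
        before = [w.copy() for w in m.weights]
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, (2, 5))
        cache = forward(m, x)
        deltas = backprop_deltas(m, cache, rng.uniform(0, 1, 2), np.ones((2, 3)))
        update_weights(m, deltas, cache, 0.0)
        for w, w0 in zip(m.weights, before):
            np.testing.assert_array_equal(w, w0)

    def test_single_step_matches_hand_computed_deltas(self):
        # 5-1-2 net, one sample: check dw = -eta * delta_j * p_i explicitly
        anchors = np.array([[0.0, 0.0], [1000.0, 0.0]])
        m = init_model([5, 1, 2], anchors, seed=9)
        x = np.array([[0.3, 0.1, 0.9, 0.2, 0.5]])
        r = np.array([0.4])
        d = np.array([[1.0, 0.5]])
        cache = forward(m, x)
        h = cache[1][0, 0]
        out = cache[2][0]
        delta_out = (1 - out**2) * d[0] * (out - r[0])
        delta_hid = (1 - h**2) * (delta_out * m.weights[1][0]).sum()
        w1_before = m.weights[0].copy()
        w2_before = m.weights[1].copy()
        eta = 0.1
        deltas = backprop_deltas(m, cache, r, d)
        update_weights(m, deltas, cache, eta)
        np.testing.assert_allclose(m.weights[1][0], w2_before[0] - eta * delta_out * h)
        np.testing.assert_allclose(m.weights[0][:, 0], w1_before[:, 0] - eta * delta_hid * x[0])

    def test_descent_on_noiseless_target(self):
        rng = np.random.default_rng(8)
        m = make_model(seed=8)
        x = rng.uniform(0, 1, (60, 5))
        r = np.clip(0.3 + 0.4 * x[:, 0] - 0.2 * x[:, 3], 0, 1)
        d = np.ones((60, 3))
        errs = []
        for _ in range(40):
            cache = forward(m, x)
            errs.append(float(0.5 * np.sum(d * (r[:, None] - cache[-1]) ** 2)))
            deltas = backprop_deltas(m, cache, r, d)
            update_weights(m, deltas, cache, 0.01 / 60)
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))
        assert errs[-1] < errs[0]


class TestTraining:
    def test_same_seed_reproduces_final_weights(self, small_scene, fast_config):
        year = small_scene.mining_years[0]
        args = ({year: small_scene.stacks[year]}, {year: small_scene.fvc[year]}, fast_config)
        m1, _ = train(*args)[year]
        m2, _ = train(*args)[year]
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)

    def test_unit_geo_weights_reproduce_standard_backprop(self):
        """With all geographic weights 1 the trainer IS plain backprop."""
        rng = np.random.default_rng(12)
        n, epochs, eta = 50, 25, 0.3
        x = rng.uniform(0, 1, (n, 5))
        r = rng.uniform(0, 1, n)
        xy = rng.uniform(0, 3000, (n, 2))
        m = init_model([5, 4, 6], rng.uniform(0, 3000, (6, 2)), seed=3)
        oracle = PlainANN(m.weights, m.biases)
        ones = geo_weights(xy, m.anchors_xy, bandwidth_m=1.0)
        ones.matrix = np.ones_like(ones.matrix)
        m, state = train_network(
            x, r, xy, m, learning_rate=eta, max_epochs=epochs, tolerance=0.0, geo=ones
        )
        oracle_errs = [oracle.epoch(x, r, eta) for _ in range(epochs)]
        assert state.errors == oracle_errs
        for w_gw, w_pl in zip(m.weights, oracle.w):
            np.testing.assert_array_equal(w_gw, w_pl)
        for b_gw, b_pl in zip(m.biases, oracle.b):
            np.testing.assert_array_equal(b_gw, b_pl)

    def test_noiseless_linear_scene_fits_below_rmse_floor(self):
        from srmd.scene import SceneConfig, generate_scene

        scene = generate_scene(
            SceneConfig(seed=21, shape=(30, 30), noise_sd=0.0,
                        no_mining_years=[1992, 1993], mining_years=[2020])
        )
        cfg = StudyConfig(seed=21, max_epochs=200)
        year = 2020
        model, _ = train({year: scene.stacks[year]}, {year: scene.fvc[year]}, cfg)[year]
        pred = predict(model, scene.stacks[year])
        rmse = np.sqrt(np.mean((pred.values - scene.fvc[year].values) ** 2))
        assert rmse < 0.02

    def test_online_mode_reduces_error(self):
        rng = np.random.default_rng(5)
        n = 30
        x = rng.uniform(0, 1, (n, 5))
        r = np.clip(0.4 + 0.3 * x[:, 0], 0, 1)
        xy = rng.uniform(0, 1000, (n, 2))
        m = init_model([5, 4, 4], rng.uniform(0, 1000, (4, 2)), seed=1,
                       bandwidth_m=800.0)
        m, state = train_network(
            x, r, xy, m, learning_rate=0.05, max_epochs=15, tolerance=0.0,
            update_mode="online",
        )
        assert state.errors[-1] < state.errors[0]


class TestPrediction:
    def test_prediction_grid_aligned_and_clipped(self, small_scene, trained_mining_model):
        year = small_scene.mining_years[0]
        pred = predict(trained_mining_model, small_scene.stacks[year])
        assert pred.same_geometry(small_scene.grid)
        vals = pred.valid_values()
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_noiseless_prediction_correlates_with_truth(self):
        from srmd.scene import SceneConfig, generate_scene

        scene = generate_scene(
            SceneConfig(seed=22, shape=(30, 30), noise_sd=0.0,
                        no_mining_years=[1992, 1993], mining_years=[2020])
        )
        cfg = StudyConfig(seed=22, max_epochs=200)
        model, _ = train({2020: scene.stacks[2020]}, {2020: scene.fvc[2020]}, cfg)[2020]
        pred = predict(model, scene.stacks[2020])
        r = np.corrcoef(pred.values.ravel(), scene.fvc[2020].values.ravel())[0, 1]
        assert r > 0.99

    def test_untrained_model_rejected(self, small_scene):
        year = small_scene.mining_years[0]
        m = make_model()
        with pytest.raises(ValueError, match="trained"):
            predict(m, small_scene.stacks[year])

    def test_geometry_mismatch_rejected(self, small_scene, trained_mining_model):
        other = trained_mining_model.copy()
        other.anchors_xy = other.anchors_xy + 1e8   # anchors far off-grid
        year = small_scene.mining_years[0]
        with pytest.raises(ValueError, match="geometry"):
            predict(other, small_scene.stacks[year])


class TestAccuracy:
    def test_perfect_predictions_zero_errors(self, grid10):
        obs = {2000: grid10.with_values(np.full((10, 10), 0.5))}
        rep = evaluate_accuracy(obs, obs)
        assert rep.mean_rmse == 0.0 and rep.mean_mre == 0.0

    def test_means_are_arithmetic_over_years(self, grid10):
        obs, pred = {}, {}
        offsets = {2000: 0.02, 2001: 0.06, 2002: 0.01}
        for year, off in offsets.items():
            obs[year] = grid10.with_values(np.full((10, 10), 0.5))
            pred[year] = grid10.with_values(np.full((10, 10), 0.5 + off))
        rep = evaluate_accuracy(pred, obs)
        assert rep.mean_rmse == pytest.approx(np.mean(list(offsets.values())))
        per_year = dict(zip(rep.table.year, rep.table.rmse))
        assert per_year[2001] == pytest.approx(0.06)

    def test_mre_excludes_near_zero_observations(self, grid10):
        obs_vals = np.full((10, 10), 0.001)      # below the relative-error floor
        obs_vals[0, 0] = 0.5
        obs = {2000: grid10.with_values(obs_vals)}
        pred = {2000: grid10.with_values(obs_vals + 0.05)}
        rep = evaluate_accuracy(pred, obs, mre_floor=0.01)
        assert rep.mean_mre == pytest.approx(0.05 / 0.5)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, trained_mining_model):
        path = save_model(trained_mining_model, tmp_path / "m.npz")
        back = load_model(path)
        assert back.layer_sizes == trained_mining_model.layer_sizes
        assert back.trained
        for w1, w2 in zip(back.weights, trained_mining_model.weights):
            np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(back.anchors_xy, trained_mining_model.anchors_xy)
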