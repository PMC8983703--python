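"""Pair scoring: descriptor distance score and the siamese network."""

import numpy as np
import pytest

from conftest import sample_cluster_pairs
from zernsurf.similarity import (
    NetworkConfig,
    NetworkParams,
    PairScore,
    build_pair_features,
    encode,
    nn_score,
    pair_feature_length,
    pair_metrics,
    score_pairs,
    train_network,
    zdzd_score,
)
from zernsurf.similarity import _backward, _bce, _descriptor_matrix, _forward_scores
from zernsurf.zernike import ZernikeDescriptor, descriptor_length


def desc(values, order=None, nv=100, nf=196):
    values = np.asarray(values, dtype=float)
    if order is None:
        order = {121: 20, 30: 9, 12: 5, 4: 2}[len(values)]
    return ZernikeDescriptor(
        order=order, values=values, mesh_vertices=nv, mesh_faces=nf
    )


class TestZdzdScore:
    def test_identical_descriptors_score_one(self):
        a = desc(np.linspace(0, 1, 121))
        assert zdzd_score(a, a).value == 1.0

    def test_unit_distance_scores_half(self):
        a = desc(np.zeros(121))
        v = np.zeros(121)
        v[17] = 1.0
        assert zdzd_score(a, desc(v)).value == pytest.approx(0.5)

    def test_distance_nine_hits_default_threshold(self):
        a = desc(np.zeros(121))
        v = np.zeros(121)
        v[0] = 9.0
        s = zdzd_score(a, desc(v))
        assert s.value == pytest.approx(0.1)
        assert s.threshold == 0.1
        assert s.same_fold  # >= threshold

    def test_order_mismatch_raises(self):
        with pytest.raises(ValueError):
            zdzd_score(desc(np.zeros(121)), desc(np.zeros(12)))

    def test_strictly_decreasing_in_distance(self):
        a = desc(np.zeros(121))
        scores = []
        for dist in [0.5, 1.0, 2.0, 5.0]:
            v = np.zeros(121)
            v[0] = dist
            scores.append(zdzd_score(a, desc(v)).value)
        assert all(x > y for x, y in zip(scores, scores[1:]))

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = desc(rng.random(121)), desc(rng.random(121))
        assert zdzd_score(a, b).value == zdzd_score(b, a).value


class TestEncoderAndFeatures:
    def test_default_feature_length_is_1452(self):
        assert pair_feature_length(121, (250, 200, 150)) == 1452

    def test_toy_feature_length(self):
        assert pair_feature_length(3, (2, 2, 2)) == 28

    @pytest.mark.parametrize(
        "d,widths",
        [(121, (250, 200, 150)), (12, (8, 6, 4)), (4, (2, 2, 2)), (30, (10, 20, 30)),
         (121, (100, 100, 100))],
    )
    def test_built_features_obey_closed_formula(self, d, widths):
        order = {121: 20, 12: 5, 4: 2, 30: 9}[d]
        cfg = NetworkConfig(descriptor_length=d, encoder_widths=widths, seed=0)
        params = NetworkParams(cfg)
        rng = np.random.default_rng(1)
        a, b = desc(rng.random(d), order), desc(rng.random(d), order)
        feats = build_pair_features(a, b, encode(a, params), encode(b, params))
        assert len(feats) == pair_feature_length(d, widths)

    def test_encoder_output_widths(self):
        params = NetworkParams(NetworkConfig(seed=0))
        acts = encode(desc(np.random.default_rng(2).random(121)), params)
        assert [len(h) for h in acts] == [250, 200, 150]

    def test_zero_weights_give_zero_activations(self):
        params = NetworkParams(NetworkConfig(seed=0))
        for k in ("W1", "W2", "W3"):
            params.weights[k] = np.zeros_like(params.weights[k])
        acts = encode(desc(np.ones(121)), params)
        assert all(np.all(h == 0) for h in acts)

    def test_encoder_deterministic(self):
        params = NetworkParams(NetworkConfig(seed=0))
        x = desc(np.random.default_rng(3).random(121))
        a1, a2 = encode(x, params), encode(x, params)
        for h1, h2 in zip(a1, a2):
            np.testing.assert_array_equal(h1, h2)

    def test_identity_pair_metric_slots(self):
        params = NetworkParams(NetworkConfig(seed=0))
        a = desc(np.random.default_rng(4).random(121), nv=500, nf=996)
        feats = build_pair_features(a, a, encode(a, params), encode(a, params))
        m_raw = feats[2 * 121 + 2 * 600 : 2 * 121 + 2 * 600 + 4]
        m_enc = feats[2 * 121 + 2 * 600 + 4 : 2 * 121 + 2 * 600 + 8]
        for m in (m_raw, m_enc):
            assert m[0] == pytest.approx(0.0)  # Euclidean distance
            assert m[1] == pytest.approx(0.0, abs=1e-12)  # cosine distance
            assert m[2] == pytest.approx(0.0)  # Manhattan distance
        assert feats[-2] == 0.0 and feats[-1] == 0.0  # mesh count deltas

    def test_metric_values_on_known_vectors(self):
        u = np.array([[1.0, 0.0]])
        v = np.array([[0.0, 1.0]])
        m = pair_metrics(u, v)[0]
        np.testing.assert_allclose(m, [np.sqrt(2), 1.0, 2.0, 0.0])


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        cfg = NetworkConfig(
            descriptor_length=12, encoder_widths=(5, 4, 3), comparator_width=6, seed=3
        )
        params = NetworkParams(cfg)
        rng = np.random.default_rng(0)
        pairs = [
            (
                desc(np.abs(rng.normal(size=12)), 5, int(rng.integers(10, 99)), 30),
                desc(np.abs(rng.normal(size=12)), 5, int(rng.integers(10, 99)), 40),
                int(rng.integers(0, 2)),
            )
            for _ in range(7)
        ]
        xa, xb, meta, y = _descriptor_matrix(pairs)
        p, cache = _forward_scores(xa, xb, meta, params)
        grads = _backward(y, cache, params)
        h = 1e-6
        for key in ("W1", "W2", "Wc1", "Wc2"):
            W = params.weights[key]
            flat = np.argsort(-np.abs(grads[key]).ravel())[:10]  # largest entries
            for pos in flat:
                ix = np.unravel_index(pos, W.shape)
                W[ix] += h
                l1 = _bce(_forward_scores(xa, xb, meta, params)[0], y)
                W[ix] -= 2 * h
                l2 = _bce(_forward_scores(xa, xb, meta, params)[0], y)
                W[ix] += h
                num = (l1 - l2) / (2 * h)
                assert grads[key][ix] == pytest.approx(num, rel=1e-3, abs=1e-8)


class TestTraining:
    def test_loss_decreases(self, cluster_pairs):
        mixed = cluster_pairs["train"][:200] + cluster_pairs["train"][-200:]
        params, log = train_network(mixed, NetworkConfig(epochs=8, seed=1))
        assert log.train_loss[-1] < log.train_loss[0]

    def test_same_seed_is_bit_identical(self, cluster_pairs):
        cfg = NetworkConfig(epochs=3, seed=9)
        mixed = cluster_pairs["train"][:100] + cluster_pairs["train"][-100:]
        _, log1 = train_network(mixed, cfg)
        _, log2 = train_network(mixed, cfg)
        assert log1.train_loss == log2.train_loss
        assert log1.val_loss == log2.val_loss

    def test_single_class_input_raises(self, cluster_pairs):
        positives = [p for p in cluster_pairs["train"] if p[2] == 1][:50]
        with pytest.raises(ValueError):
            train_network(positives, NetworkConfig(epochs=1, seed=0))

    def test_label_shuffle_trains_to_chance(self, cluster_data):
        descs, labels = cluster_data
        rng = np.random.default_rng(21)
        pairs = sample_cluster_pairs(descs, labels, 600, rng)
        shuffled_labels = rng.permutation([p[2] for p in pairs])
        shuffled = [(a, b, int(y)) for (a, b, _), y in zip(pairs, shuffled_labels)]
        params, _ = train_network(shuffled, NetworkConfig(epochs=8, seed=4))
        test = sample_cluster_pairs(descs, labels, 400, rng)
        y = np.array([p[2] for p in test])
        acc = np.mean((score_pairs(test, params) >= 0.5) == y)
        assert 0.35 <= acc <= 0.65

    def test_held_out_accuracy_on_separable_clusters(self, trained_network, cluster_pairs):
        params, _ = trained_network
        y = np.array([p[2] for p in cluster_pairs["test"]])
        acc = np.mean((score_pairs(cluster_pairs["test"], params) >= 0.5) == y)
        assert acc > 0.9


class TestNNScore:
    def test_untrained_params_raise(self, cluster_pairs):
        params = NetworkParams(NetworkConfig(seed=0))
        a, b, _ = cluster_pairs["test"][0]
        with pytest.raises(ValueError):
            nn_score(a, b, params)

    def test_score_in_unit_interval_and_symmetric(self, trained_network, cluster_pairs):
        params, _ = trained_network
        for a, b, _ in cluster_pairs["test"][:20]:
            s_ab = nn_score(a, b, params)
            s_ba = nn_score(b, a, params)
            assert 0.0 <= s_ab.value <= 1.0
            assert s_ab.value == pytest.approx(s_ba.value, abs=1e-12)

    def test_zero_final_layer_scores_half(self, trained_network, cluster_pairs):
        params, _ = trained_network
        params = params.copy()
        params.weights["Wc2"] = np.zeros_like(params.weights["Wc2"])
        params.weights["bc2"] = np.zeros_like(params.weights["bc2"])
        a, b, _ = cluster_pairs["test"][0]
        assert nn_score(a, b, params).value == pytest.approx(0.5)

    def test_mode_thresholds(self):
        s = PairScore(value=0.55, method="nn", threshold=0.5)
        assert s.same_fold
        s = PairScore(value=0.55, method="nn", threshold=0.6)
        assert not s.same_fold


class TestCheckpointIO:
    def test_save_load_round_trip(self, tmp_path, trained_network, cluster_pairs):
        params, _ = trained_network
        path = tmp_path / "net.npz"
        params.save(path)
        back = NetworkParams.load(path)
        a, b, _ = cluster_pairs["test"][0]
        assert nn_score(a, b, back).value == pytest.approx(
            nn_score(a, b, params).value, abs=1e-12
        )
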