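"""Network construction, the lateral operator, and the training protocol."""

import numpy as np
import pytest

import lgncnn as L
from lgncnn import arch


def _delta_kernel(n, size):
    K = np.zeros((size, size, n, n))
    r = size // 2
    for f in range(n):
        K[r, r, f, f] = 1.0
    return K


class TestBuildNetwork:
    def test_default_shapes_match_reference_architecture(self):
        net = L.build_network(L.ArchitectureConfig(), image_size=32, seed=0)
        assert net.l0_conv.W.value.shape == (1, 1, 11, 11)
        assert net.l1_conv.W.value.shape == (64, 1, 7, 7)
        assert net.lateral.K.value.shape == (13, 13, 64, 64)

    def test_classical_baseline_has_no_prefilter_or_lateral(self):
        cfg = L.ArchitectureConfig(use_l0=False, use_lateral=False)
        net = L.build_network(cfg, image_size=32, seed=0)
        assert net.l0_conv is None
        assert net.lateral is None
        assert net.psi0 is None
        assert net.K1 is None

    def test_unit_fraction_scales_filter_counts(self):
        cfg = L.ArchitectureConfig(unit_fraction=0.25)
        net = L.build_network(cfg, image_size=32, seed=0)
        assert net.l1_conv.W.value.shape[0] == 16

    def test_forward_output_shape(self):
        cfg = L.ArchitectureConfig(unit_fraction=0.125, depth=2)
        net = L.build_network(cfg, image_size=16, seed=0)
        net.set_mode(False)
        out = net.forward(np.zeros((3, 1, 16, 16), dtype=np.float32))
        assert out.shape == (3, 10)

    def test_even_sizes_rejected(self):
        with pytest.raises(ValueError):
            L.ArchitectureConfig(l0_size=10)
        with pytest.raises(ValueError):
            L.ArchitectureConfig(lateral_size=12)


class TestLateralUpdate:
    def test_zero_kernel_halves_activation(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=(4, 8, 8))
        out = L.lateral_update(h, np.zeros((5, 5, 4, 4)))
        assert np.allclose(out, h / 2)

    def test_identity_delta_kernel_is_identity(self):
        rng = np.random.default_rng(1)
        h = rng.normal(size=(4, 8, 8))
        assert np.allclose(L.lateral_update(h, _delta_kernel(4, 5)), h)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        h1, h2 = rng.normal(size=(2, 3, 7, 7))
        K = rng.normal(size=(5, 5, 3, 3))
        lhs = L.lateral_update(2.0 * h1 + 3.0 * h2, K)
        rhs = 2.0 * L.lateral_update(h1, K) + 3.0 * L.lateral_update(h2, K)
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_two_step_identity(self):
        # (h~ + K*h~)/2 == (h + 2 K*h + K*K*h)/4 with the same border rule
        rng = np.random.default_rng(3)
        h = rng.normal(size=(4, 10, 10))
        K = rng.normal(size=(5, 5, 4, 4)) * 0.2
        twice = L.lateral_update(L.lateral_update(h, K), K)
        Kh = arch._kernel_conv(h, K)
        KKh = arch._kernel_conv(Kh, K)
        assert np.abs(twice - 0.25 * (h + 2 * Kh + KKh)).max() < 1e-10

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            L.lateral_update(np.zeros((3, 5, 5)), np.zeros((5, 5, 4, 4)))

    def test_displacement_semantics(self):
        # K(i, j, f, g) moves activation of f by (+i, +j) into channel g
        h = np.zeros((2, 7, 7))
        h[0, 3, 3] = 1.0
        K = np.zeros((5, 5, 2, 2))
        K[2 + 1, 2 + 2, 0, 1] = 1.0  # displacement (i, j) = (1, 2)
        out = L.lateral_update(h, K)
        assert out[1, 4, 5] == pytest.approx(0.5)
        assert out[0, 3, 3] == pytest.approx(0.5)


class TestSelfReplicate:
    def test_zero_kernel(self):
        assert np.all(L.self_replicate(np.zeros((5, 5, 3, 3))) == 0)

    def test_identity_delta_triples(self):
        K = _delta_kernel(3, 5)
        out = L.self_replicate(K)
        expect = np.zeros((9, 9, 3, 3))
        for f in range(3):
            expect[4, 4, f, f] = 3.0
        assert np.abs(out - expect).max() < 1e-12

    def test_enlarged_support_shape(self):
        out = L.self_replicate(np.zeros((13, 13, 2, 2)))
        assert out.shape == (25, 25, 2, 2)

    def test_composed_kernel_matches_two_steps_on_interior(self):
        # away from the zero-padded border, one step with 2K + K*K equals
        # two steps with K (up to the 1/4 scaling)
        rng = np.random.default_rng(4)
        n, S, H = 3, 5, 14
        r = S // 2
        h = rng.normal(size=(n, H, H))
        K = rng.normal(size=(S, S, n, n)) * 0.2
        twice = L.lateral_update(L.lateral_update(h, K), K)
        single = 0.25 * (h + arch._kernel_conv(h, L.self_replicate(K)))
        assert np.abs(twice - single)[:, r : H - r, r : H - r].max() < 1e-10


class TestTraining:
    def _cfg(self, **kw):
        defaults = dict(max_epochs=2, patience=5, lr=0.02, batch_size=32, seed=3)
        defaults.update(kw)
        return L.TrainingConfig(**defaults)

    def _net(self, seed=0):
        cfg = L.ArchitectureConfig(unit_fraction=0.125, depth=1, lateral_size=7)
        return L.build_network(cfg, image_size=16, seed=seed)

    def test_two_phase_smoke(self, tiny_dataset):
        net = self._net()
        hist = L.train(net, (tiny_dataset.images, tiny_dataset.labels), self._cfg())
        phases = set(hist["phase"])
        assert phases == {"pretrain_feedforward", "joint_with_lateral"}
        assert np.all(np.isfinite(net.l1_filters))
        assert np.all(np.isfinite(net.K1))

    def test_feedforward_phase_leaves_kernel_untouched(self, tiny_dataset):
        net = self._net()
        K_before = net.K1.copy()
        L.train(
            net,
            (tiny_dataset.images, tiny_dataset.labels),
            self._cfg(phase="pretrain_feedforward"),
        )
        assert np.array_equal(net.K1, K_before)

    def test_early_stopping_halts_before_max_epochs(self, tiny_dataset):
        # unlearnable labels: validation accuracy stays flat
        rng = np.random.default_rng(0)
        X = tiny_dataset.images
        y = rng.integers(0, 10, len(X))
        net = self._net()
        hist = L.train(net, (X, y), self._cfg(max_epochs=30, patience=2))
        n_phase1 = sum(p == "pretrain_feedforward" for p in hist["phase"])
        assert n_phase1 < 30

    def test_reproducible_given_seed(self, tiny_dataset):
        data = (tiny_dataset.images, tiny_dataset.labels)
        h1 = L.train(self._net(seed=1), data, self._cfg())
        h2 = L.train(self._net(seed=1), data, self._cfg())
        assert h1["val_acc"] == h2["val_acc"]
        assert h1["train_acc"] == h2["train_acc"]

    def test_empty_dataset_rejected(self):
        net = self._net()
        with pytest.raises(ValueError):
            L.train(net, (np.zeros((0, 1, 16, 16)), np.zeros(0, int)), self._cfg())


class TestEvaluate:
    def test_constant_network_on_balanced_labels(self):
        cfg = L.ArchitectureConfig(unit_fraction=0.125, depth=1, use_lateral=False)
        net = L.build_network(cfg, image_size=16, seed=0)
        # zero the final layer: constant logits -> constant prediction
        net.layers[-1].W.value[...] = 0.0
        net.layers[-1].b.value[...] = 0.0
        rng = np.random.default_rng(0)
        X = rng.random((200, 1, 16, 16)).astype(np.float32)
        y = np.repeat(np.arange(10), 20)
        assert L.evaluate(net, (X, y)) == pytest.approx(0.1)

    def test_empty_dataset_rejected(self):
        cfg = L.ArchitectureConfig(unit_fraction=0.125, depth=1)
        net = L.build_network(cfg, image_size=16, seed=0)
        with pytest.raises(ValueError):
            L.evaluate(net, (np.zeros((0, 1, 16, 16)), np.zeros(0, int)))


class TestBundles:
    def test_save_load_roundtrip(self, tmp_path):
        cfg = L.ArchitectureConfig(unit_fraction=0.125, depth=1, lateral_size=7)
        net = L.build_network(cfg, image_size=16, seed=0)
        net.lateral.init_random(np.random.default_rng(1))
        path = tmp_path / "weights.npz"
        L.save_bundle(path, net, meta={"note": "test"})
        bundle = L.load_bundle(path)
        assert np.allclose(bundle["psi0"], net.psi0)
        assert np.allclose(bundle["l1_filters"], net.l1_filters)
        assert np.allclose(bundle["K1"], net.K1)
        assert bundle["meta"]["note"] == "test"
        assert bundle["meta"]["config"]["lateral_size"] == 7
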