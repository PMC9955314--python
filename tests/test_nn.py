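import numpy as np
import pytest

import tabraster as tr
from tabraster.nn import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    ResNet,
    SGDMomentum,
    softmax_cross_entropy,
)

RNG = np.random.default_rng(12345)


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        old = x[idx]
        x[idx] = old + eps
        hi = f()
        x[idx] = old - eps
        lo = f()
        x[idx] = old
        g[idx] = (hi - lo) / (2 * eps)
    return g


def check_layer_gradients(layer, x, atol=1e-7):
    """Central finite differences vs analytic backward, float64."""
    def loss():
        return float((layer.forward(x, train=True) ** 2).sum() / 2)

    out = layer.forward(x, train=True)
    for p in layer.params():
        p.zero_grad()
    dx = layer.backward(out)  # d/dx of sum(out^2)/2 is out
    gx = numeric_grad(loss, x)
    assert np.max(np.abs(dx - gx)) < atol, "input gradient"
    for p in layer.params():
        analytic = p.grad.copy()
        gp = numeric_grad(loss, p.data)
        # re-run backward not needed: grads were accumulated once above
        assert np.max(np.abs(analytic - gp)) < atol, p.name


class TestLayerGradients:
    def test_conv_stride_pad(self):
        layer = Conv2d(2, 3, 3, stride=2, pad=1, bias=True,
                       rng=np.random.default_rng(0), dtype=np.float64)
        x = RNG.normal(size=(2, 2, 7, 7))
        check_layer_gradients(layer, x)

    def test_conv_1x1(self):
        layer = Conv2d(3, 2, 1, rng=np.random.default_rng(1), dtype=np.float64)
        check_layer_gradients(layer, RNG.normal(size=(2, 3, 4, 4)))

    def test_batchnorm(self):
        layer = BatchNorm2d(3, dtype=np.float64)
        layer.gamma.data = RNG.normal(1.0, 0.2, 3)
        layer.beta.data = RNG.normal(0.0, 0.2, 3)
        check_layer_gradients(layer, RNG.normal(size=(3, 3, 4, 4)), atol=1e-6)

    def test_maxpool(self):
        layer = MaxPool2d(3, 2, 1)
        check_layer_gradients(layer, RNG.normal(size=(2, 2, 6, 6)))

    def test_linear(self):
        layer = Linear(5, 3, rng=np.random.default_rng(2), dtype=np.float64)
        check_layer_gradients(layer, RNG.normal(size=(4, 5)))

    def test_global_avg_pool(self):
        check_layer_gradients(GlobalAvgPool(), RNG.normal(size=(2, 3, 5, 5)))

    def test_softmax_cross_entropy_gradient(self):
        logits = RNG.normal(size=(6, 3))
        y = np.array([0, 1, 2, 1, 0, 2])
        _, d = softmax_cross_entropy(logits, y)
        g = numeric_grad(lambda: softmax_cross_entropy(logits, y)[0], logits)
        assert np.max(np.abs(d - g)) < 1e-7

    def test_full_network_gradient_spot_check(self):
        """End-to-end backprop through a depth-18 net vs finite differences."""
        model = ResNet(18, seed=0, dtype=np.float64)
        x = np.random.default_rng(3).normal(size=(2, 3, 32, 32))
        y = np.array([0, 1])

        def loss():
            return softmax_cross_entropy(model.forward(x, train=True), y)[0]

        logits = model.forward(x, train=True)
        _, dl = softmax_cross_entropy(logits, y)
        for p in model.params():
            p.zero_grad()
        model.backward(dl)
        ps = model.params()
        rng = np.random.default_rng(4)
        for p in [ps[0], ps[7], ps[-1]]:
            idx = tuple(int(rng.integers(0, s)) for s in p.data.shape)
            analytic = p.grad[idx]
            old = p.data[idx]
            eps = 1e-6
            p.data[idx] = old + eps
            hi = loss()
            p.data[idx] = old - eps
            lo = loss()
            p.data[idx] = old
            fd = (hi - lo) / (2 * eps)
            assert analytic == pytest.approx(fd, rel=1e-3, abs=1e-7)


class TestBackboneContract:
    def test_feature_dimensions(self):
        assert tr.adapt_backbone(18).feature_dim == 512
        assert tr.adapt_backbone(50).feature_dim == 2048

    def test_unsupported_depth(self):
        with pytest.raises(ValueError, match="depth"):
            tr.adapt_backbone(34)

    def test_pretrained_without_weights_file_fails_offline(self):
        with pytest.raises(ValueError, match="weights_path"):
            tr.adapt_backbone(18, pretrained=True)

    def test_pretrained_roundtrip_via_npz(self, tmp_path):
        m = tr.adapt_backbone(18, seed=5)
        path = tmp_path / "w.npz"
        np.savez(path, **m.state_dict())
        m2 = tr.adapt_backbone(18, pretrained=True, weights_path=path, seed=9)
        x = np.random.default_rng(0).normal(size=(1, 3, 32, 32)).astype(np.float32)
        assert np.allclose(m.forward_features(x), m2.forward_features(x))

    def test_extract_shapes_and_purity(self, image_batch_32):
        x, _ = image_batch_32
        m = tr.adapt_backbone(18, seed=0)
        f = tr.extract_features(m, x[:10])
        assert f.shape == (10, 512)
        assert tr.extract_features(m, x[:0]).shape == (0, 512)
        dup = tr.extract_features(m, np.stack([x[0], x[0]]))
        assert np.allclose(dup[0], dup[1])
        again = tr.extract_features(m, x[:10])
        assert np.array_equal(f, again)  # deterministic given fixed weights


class TestPreprocess:
    def test_resize_to_224_three_channels(self):
        img = tr.GrayImage(np.zeros((120, 120), dtype=np.uint8))
        out = tr.preprocess(img)
        assert out.shape == (3, 224, 224)

    def test_constant_image_stays_constant(self):
        img = tr.GrayImage(np.full((120, 120), 102, dtype=np.uint8))
        out = tr.preprocess(img)
        assert np.allclose(out, 102 / 255.0, atol=1e-6)

    def test_all_zero_maps_to_all_zero(self):
        out = tr.preprocess(tr.GrayImage(np.zeros((120, 120), np.uint8)))
        assert np.all(out == 0.0)

    def test_wrong_rank_rejected(self):
        with pytest.raises(ValueError, match="2-D"):
            tr.preprocess(np.zeros((3, 120, 120)))


class TestTraining:
    def test_lr_schedule_never_drops_within_five_epochs(self):
        opt = SGDMomentum([], lr=0.001, drop_factor=0.1, drop_period=20)
        assert [opt.lr_at(e) for e in range(5)] == [0.001] * 5
        assert opt.lr_at(20) == pytest.approx(0.0001)

    def test_single_class_training_rejected(self, image_batch_32):
        x, _ = image_batch_32
        m = tr.adapt_backbone(18, seed=0)
        with pytest.raises(ValueError, match="single class"):
            tr.train(m, x[:4], np.zeros(4, int))

    def test_curves_have_one_entry_per_epoch(self, image_batch_32):
        x, y = image_batch_32
        m = tr.adapt_backbone(18, seed=0)
        cfg = tr.TrainConfig(max_epochs=2, batch_size=8, seed=0)
        h = tr.train(m, x, y, cfg, x_val=x[:4], y_val=y[:4])
        assert len(h["train_loss"]) == len(h["train_acc"]) == 2
        assert len(h["val_acc"]) == 2
        assert h["lr"] == [0.001, 0.001]

    def test_seeded_runs_reproduce_identical_weights(self, image_batch_32):
        x, y = image_batch_32
        states = []
        for _ in range(2):
            m = tr.adapt_backbone(18, seed=1)
            tr.train(m, x, y, tr.TrainConfig(max_epochs=1, batch_size=8, seed=1))
            states.append(m.state_dict())
        for k in states[0]:
            assert np.array_equal(states[0][k], states[1][k]), k

    def test_capacity_overfits_sixteen_images(self, image_batch_32):
        """50 epochs reach 100% training accuracy on 16 distinct images."""
        x, y = image_batch_32
        m = tr.adapt_backbone(18, seed=0)
        cfg = tr.TrainConfig(max_epochs=50, batch_size=8, initial_lr=0.01,
                             seed=0)
        h = tr.train(m, x, y, cfg)
        assert h["train_acc"][-1] == 1.0
        assert h["train_acc"][-1] >= h["train_acc"][0]
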