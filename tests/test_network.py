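import numpy as np
import pytest

from uresnet.network import (
    Conv2d,
    ConvTranspose2d,
    MaxPool2x2,
    Network,
    NetworkSpec,
    ResEle,
    ShapeError,
    build_uresnet,
    count_parameters,
    forward,
    load_network,
    save_network,
    softmax,
    softmax_backward,
)

SMALL = NetworkSpec(channel_widths=(4, 6, 8, 10))


class TestArchitecture:
    def test_default_layer_census(self):
        """8 residual elements, 3 deconvolutions, 1 final convolution."""
        net = build_uresnet(NetworkSpec())
        assert net.n_residual_elements() == 8
        assert net.n_deconv_layers() == 3
        assert isinstance(net.final, Conv2d) and net.final.k == 1

    def test_default_parameter_count_about_one_million(self):
        n = count_parameters(build_uresnet(NetworkSpec()))
        assert 0.8e6 <= n <= 1.2e6

    def test_small_layer_parameter_counts(self):
        rng = np.random.default_rng(0)
        assert Conv2d(1, 32, 3, rng).n_params() == 9 * 32 + 32  # 320
        assert Conv2d(32, 64, 1, rng).n_params() == 32 * 64 + 64  # 2112

    def test_channel_widths_must_increase(self):
        with pytest.raises(ValueError):
            NetworkSpec(channel_widths=(32, 32, 64, 128))

    def test_wrong_scale_count_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(channel_widths=(8, 16, 32))

    def test_patch_in_probability_map_out(self):
        net = build_uresnet(SMALL, seed=1)
        p = forward(net, np.random.default_rng(0).normal(size=(2, 1, 64, 64)))
        assert p.shape == (2, 3, 64, 64)


class TestForwardContracts:
    def test_probabilities_normalized(self):
        net = build_uresnet(SMALL, seed=2)
        p = forward(net, np.random.default_rng(1).normal(size=(3, 1, 32, 32)))
        assert p.min() >= 0 and p.max() <= 1
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zeroed_final_layer_gives_uniform_probabilities(self):
        net = build_uresnet(SMALL, seed=3)
        net.final.params["w"][:] = 0
        net.final.params["b"][:] = 0
        p = forward(net, np.random.default_rng(2).normal(size=(1, 1, 16, 16)))
        np.testing.assert_allclose(p, 1.0 / 3.0, atol=1e-6)

    def test_batch_duplication_gives_identical_outputs(self):
        # per-sample independence; tolerance covers BLAS summation-order
        # differences between row blocks of the batched GEMM
        net = build_uresnet(SMALL, seed=4)
        x = np.random.default_rng(3).normal(size=(1, 1, 24, 24)).astype(np.float32)
        p = net.forward(np.concatenate([x, x]))
        np.testing.assert_allclose(p[0], p[1], atol=1e-6)

    def test_indivisible_shape_raises(self):
        net = build_uresnet(SMALL)
        with pytest.raises(ShapeError, match="pad"):
            net.forward(np.zeros((1, 1, 30, 30), dtype=np.float32))

    def test_residual_identity_with_zeroed_branch(self):
        rng = np.random.default_rng(5)
        block = ResEle(6, 6, 3, rng, dtype=np.float64)
        block.conv.params["w"][:] = 0
        block.conv.params["b"][:] = 0
        x = rng.normal(size=(1, 6, 8, 8))  # includes negative values
        np.testing.assert_array_equal(block.forward(x), x)

    def test_activations_nonnegative_after_every_relu(self, monkeypatch):
        """Post-activation feature maps are >= 0 throughout the network."""
        from uresnet.network import ReLU

        minima = []
        orig = ReLU.forward

        def recording(self, x):
            out = orig(self, x)
            minima.append(float(out.min()))
            return out

        monkeypatch.setattr(ReLU, "forward", recording)
        net = build_uresnet(SMALL, seed=6)
        x = np.random.default_rng(4).normal(size=(1, 1, 16, 16)).astype(np.float32)
        net.forward(x)
        assert len(minima) == 8 + 3  # one per ResEle branch + per junction
        assert all(m >= 0 for m in minima)


class TestGradients:
    """Finite-difference checks of every hand-written backward pass."""

    @pytest.mark.parametrize(
        "make_layer,in_shape",
        [
            (lambda rng: Conv2d(2, 3, 3, rng, np.float64), (2, 2, 6, 6)),
            (lambda rng: Conv2d(3, 2, 1, rng, np.float64), (1, 3, 5, 5)),
            (lambda rng: ConvTranspose2d(3, 2, rng, np.float64), (2, 3, 4, 4)),
            (lambda rng: ResEle(2, 4, 3, rng, np.float64), (1, 2, 6, 6)),
            (lambda rng: ResEle(3, 3, 3, rng, np.float64), (1, 3, 6, 6)),
        ],
        ids=["conv3", "conv1", "deconv", "resele_proj", "resele_id"],
    )
    def test_layer_backward_matches_finite_differences(self, make_layer, in_shape):
        rng = np.random.default_rng(11)
        layer = make_layer(rng)
        x = rng.normal(size=in_shape)
        cot = rng.normal(size=layer.forward(x).shape)  # random cotangent

        def value(xx):
            return float((layer.forward(xx) * cot).sum())

        layer.forward(x)
        layer.zero_grad() if hasattr(layer, "params") and layer.params else None
        dx = layer.backward(cot.copy())
        eps = 1e-6
        flat = x.ravel()
        for i in np.random.default_rng(0).choice(flat.size, 6, replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            vp = value(x)
            flat[i] = orig - eps
            vm = value(x)
            flat[i] = orig
            layer.forward(x)  # restore caches
            assert dx.ravel()[i] == pytest.approx((vp - vm) / (2 * eps), rel=1e-5, abs=1e-8)

    def test_maxpool_routes_gradient_to_argmax(self):
        pool = MaxPool2x2()
        x = np.arange(16, dtype=np.float64).reshape(1, 1, 4, 4)
        out = pool.forward(x)
        np.testing.assert_array_equal(out[0, 0], [[5, 7], [13, 15]])
        dx = pool.backward(np.ones_like(out))
        assert dx.sum() == 4
        assert dx[0, 0, 1, 1] == 1 and dx[0, 0, 0, 0] == 0

    def test_whole_network_input_gradient(self):
        net = build_uresnet(NetworkSpec(channel_widths=(3, 4, 5, 6)), seed=8,
                            dtype=np.float64)
        rng = np.random.default_rng(9)
        x = rng.normal(size=(1, 1, 16, 16))
        cot = rng.normal(size=(1, 3, 16, 16))
        net.forward(x)
        net.zero_grad()
        dx = net.backward(cot.copy())
        eps = 1e-6
        for idx in [(0, 0, 3, 3), (0, 0, 8, 12)]:
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            num = ((net.forward(xp) * cot).sum() - (net.forward(xm) * cot).sum()) / (
                2 * eps
            )
            assert dx[idx] == pytest.approx(num, rel=1e-5)

    def test_softmax_backward_reproduces_ce_shortcut(self):
        """Chaining dCE/dprobs through the softmax must give probs - onehot."""
        rng = np.random.default_rng(10)
        logits = rng.normal(size=(2, 3, 4, 4))
        p = softmax(logits, axis=1)
        y = np.eye(3)[rng.integers(0, 3, size=(2, 4, 4))].transpose(0, 3, 1, 2)
        dprobs = -y / p
        np.testing.assert_allclose(softmax_backward(p, dprobs, axis=1), p - y,
                                   atol=1e-12)


class TestFullyConvolutional:
    def test_downsampling_factor_is_eight(self):
        net = build_uresnet(SMALL, seed=12)
        x = np.zeros((1, 1, 64, 64), dtype=np.float32)
        h = x
        for s, blocks in enumerate(net.scales):
            for b in blocks:
                h = b.forward(h)
            if s < 3:
                h = net.pools[s].forward(h)
        assert h.shape[-2:] == (8, 8)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        net = build_uresnet(SMALL, seed=13)
        x = np.random.default_rng(6).normal(size=(1, 1, 16, 16)).astype(np.float32)
        ref = net.forward(x)
        path = tmp_path / "ck.npz"
        save_network(net, path)
        back = load_network(path, SMALL)
        np.testing.assert_allclose(back.forward(x), ref, atol=1e-6)

    def test_spec_mismatch_rejected(self, tmp_path):
        net = build_uresnet(SMALL, seed=14)
        path = tmp_path / "ck.npz"
        save_network(net, path)
        with pytest.raises(ValueError, match="spec"):
            load_network(path, NetworkSpec(channel_widths=(8, 16, 24, 32)))
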