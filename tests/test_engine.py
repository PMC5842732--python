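import numpy as np
import pytest

from uresnet.engine import (
    DivergenceError,
    TrainConfig,
    lr_at,
    pad_to_multiple,
    segment_volume,
    split_cohort_two_fold,
    train,
)
from uresnet.losses import LossConfig
from uresnet.network import NetworkSpec, build_uresnet, softmax
from uresnet.phantom import PhantomConfig, generate_cohort
from uresnet.sampling import SamplerConfig, sample_cohort
from uresnet.volume_io import compute_brain_mask, normalize_intensity

TINY_SPEC = NetworkSpec(channel_widths=(4, 6, 8, 10))


@pytest.fixture(scope="module")
def tiny_setup():
    """A 2-case normalized cohort plus its pooled patch set (16x16 patches)."""
    cases = []
    for vol, lab in generate_cohort(
        2, PhantomConfig(grid_shape=(64, 64, 6)), stroke_fraction=0.5, seed=31
    ):
        vol.brain_mask = compute_brain_mask(vol)
        cases.append((normalize_intensity(vol), lab))
    cfg = SamplerConfig(patch_size=16, wmh_fraction=0.05, stroke_fraction=0.2,
                        seed=32)
    patches = sample_cohort(cases, cfg)
    return cases, patches


class TestSchedule:
    def test_default_protocol_values(self):
        cfg = TrainConfig()
        assert lr_at(0, cfg) == pytest.approx(0.0005)
        assert lr_at(24, cfg) == pytest.approx(0.0005)
        assert lr_at(25, cfg) == pytest.approx(0.00005)
        assert lr_at(100, cfg) == pytest.approx(0.00005)

    def test_unit_decay_factor_is_constant(self):
        cfg = TrainConfig(lr_decay_factor=1.0)
        assert lr_at(40, cfg) == cfg.base_lr

    def test_negative_epoch_rejected(self):
        with pytest.raises(ValueError):
            lr_at(-1, TrainConfig())


class TestTrain:
    def test_zero_epochs_is_identity(self, tiny_setup):
        _, patches = tiny_setup
        net = build_uresnet(TINY_SPEC, seed=1)
        before = [p.copy() for l in net.trainable_layers() for p in l.params.values()]
        net, hist = train(net, patches, None, TrainConfig(n_epochs=0))
        after = [p for l in net.trainable_layers() for p in l.params.values()]
        for b, a in zip(before, after):
            np.testing.assert_array_equal(b, a)
        assert hist.epoch_loss == []

    def test_loss_decreases_on_seeded_run(self, tiny_setup):
        _, patches = tiny_setup
        net = build_uresnet(TINY_SPEC, seed=2)
        _, hist = train(net, patches, None,
                        TrainConfig(n_epochs=5, batch_size=32, seed=3))
        assert len(hist.epoch_loss) == 5
        assert hist.epoch_loss[-1] < hist.epoch_loss[0]

    def test_same_seed_reproduces_weights(self, tiny_setup):
        _, patches = tiny_setup
        results = []
        for _ in range(2):
            net = build_uresnet(TINY_SPEC, seed=4)
            net, _ = train(net, patches, None,
                           TrainConfig(n_epochs=2, batch_size=32, seed=5))
            results.append(
                np.concatenate(
                    [p.ravel() for l in net.trainable_layers() for p in l.params.values()]
                )
            )
        np.testing.assert_array_equal(results[0], results[1])

    def test_step_count_per_epoch(self, tiny_setup):
        _, patches = tiny_setup
        net = build_uresnet(TINY_SPEC, seed=6)
        from uresnet.engine import Adam

        cfg = TrainConfig(n_epochs=1, batch_size=30, seed=7)
        net, _ = train(net, patches, None, cfg)
        # ceil(P / batch) optimizer steps in one epoch
        expected = -(-len(patches) // cfg.batch_size)
        # re-run with an instrumented optimizer to count steps
        calls = []
        orig_step = Adam.step

        def counting(self, lr):
            calls.append(lr)
            orig_step(self, lr)

        Adam.step = counting
        try:
            train(build_uresnet(TINY_SPEC, seed=6), patches, None, cfg)
        finally:
            Adam.step = orig_step
        assert len(calls) == expected

    def test_empty_patchset_rejected(self, tiny_setup):
        cases, patches = tiny_setup
        from uresnet.sampling import PatchSet
        import pandas as pd

        empty = PatchSet(
            patches.images[:0], patches.labels[:0], patches.provenance.iloc[:0]
        )
        with pytest.raises(ValueError, match="empty"):
            train(build_uresnet(TINY_SPEC), empty, None, TrainConfig())

    def test_monitoring_uses_whole_volumes(self, tiny_setup):
        cases, patches = tiny_setup
        net = build_uresnet(TINY_SPEC, seed=8)
        _, hist = train(
            net, patches, cases,
            TrainConfig(n_epochs=2, batch_size=64, seed=9, eval_every=1),
        )
        assert len(hist.checkpoints) == 2
        for ck in hist.checkpoints:
            assert 0.0 <= ck["dice_class1"] <= 1.0
            assert 0.0 <= ck["dice_class2"] <= 1.0


class TestSegmentVolume:
    def test_output_on_input_lattice(self, tiny_setup, rng):
        cases, _ = tiny_setup
        vol, _ = cases[0]
        net = build_uresnet(TINY_SPEC, seed=10)
        labels, probs = segment_volume(net, vol)
        assert labels.labels.shape == vol.grid_shape
        assert set(np.unique(labels.labels)) <= {0, 1, 2}
        assert probs.shape == (3,) + vol.grid_shape
        np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)

    def test_padding_identity_when_divisible(self):
        x = np.zeros((4, 2, 64, 64), dtype=np.float32)
        padded, (h, w) = pad_to_multiple(x)
        assert padded is x and (h, w) == (64, 64)

    def test_pad_then_crop_preserves_odd_shapes(self):
        x = np.random.default_rng(0).normal(size=(1, 1, 30, 44)).astype(np.float32)
        padded, (h, w) = pad_to_multiple(x)
        assert padded.shape[-2:] == (32, 48)
        np.testing.assert_array_equal(padded[..., :h, :w], x)

    def test_channel_mismatch_rejected(self, tiny_setup):
        cases, _ = tiny_setup
        vol, _ = cases[0]
        net = build_uresnet(NetworkSpec(in_channels=2, channel_widths=(4, 6, 8, 10)))
        with pytest.raises(ValueError, match="channels"):
            segment_volume(net, vol)

    def test_stitching_matches_patchwise_inference(self):
        """Fully-convolutional consistency: whole-slice inference equals
        sliding-window patch inference at every voxel whose receptive field
        lies inside both inputs (crop offset aligned to the pooling grid)."""
        net = build_uresnet(TINY_SPEC, seed=11)
        plane = np.random.default_rng(50).normal(size=(1, 1, 160, 160)).astype(
            np.float32
        )
        full = softmax(net.forward(plane), axis=1)
        part = softmax(net.forward(plane[:, :, 32:128, 32:128]), axis=1)
        # 40-voxel margin exceeds the network's receptive-field radius
        np.testing.assert_allclose(
            full[:, :, 72:88, 72:88], part[:, :, 40:56, 40:56], atol=1e-4
        )


class TestCrossValidation:
    def test_two_fold_split_stratifies_stroke(self):
        cases = generate_cohort(
            8, PhantomConfig(grid_shape=(48, 48, 4), n_wmh_lesions=2),
            stroke_fraction=0.5, seed=40,
        )
        fold_a, fold_b = split_cohort_two_fold(cases, seed=41)
        assert sorted(fold_a + fold_b) == list(range(8))
        has_stroke = [int((l.labels == 2).any()) for _, l in cases]
        assert sum(has_stroke[i] for i in fold_a) == 2
        assert sum(has_stroke[i] for i in fold_b) == 2

    def test_split_deterministic(self):
        cases = generate_cohort(
            6, PhantomConfig(grid_shape=(48, 48, 4), n_wmh_lesions=2),
            stroke_fraction=0.5, seed=42,
        )
        assert split_cohort_two_fold(cases, 1) == split_cohort_two_fold(cases, 1)
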