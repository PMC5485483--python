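import numpy as np
import pytest

from lggseg.cnn import (
    NetworkSpec,
    PatchCNN,
    TrainConfig,
    build_network,
    dense_inference,
    load_checkpoint,
    lr_schedule,
    save_checkpoint,
    train,
)
from lggseg.imaging_core import Volume
from lggseg.pipeline import score_volume
from lggseg.sampler import HALF, PATCH_SIZE, PatchSet


def _random_patchset(n=120, channels=1, seed=0, separation=0.0):
    """Labelled random patches; separation > 0 makes classes separable."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n)
    windows = rng.standard_normal((n, channels, PATCH_SIZE, PATCH_SIZE))
    windows += separation * labels[:, None, None, None]
    centers = np.tile([0, HALF, HALF], (n, 1))
    return PatchSet(windows=windows, centers=centers, labels=labels, seed=seed)


class TestNetworkSpec:
    def test_base_line_layer_counts(self):
        spec = NetworkSpec.from_variant("base")
        assert spec.n_conv_layers == 4
        assert spec.n_pool_stages == 2
        assert len(spec.fc_sizes) == 3 and spec.fc_sizes == (256, 256, 2)
        assert spec.conv_blocks == [[64, 64], [128, 128]]

    def test_deeper_has_six_convolutions(self):
        spec = NetworkSpec.from_variant("deeper")
        assert spec.n_conv_layers == 6
        assert spec.conv_blocks == [[64, 64, 64], [128, 128, 128]]

    def test_more_fc_widens_hidden_layers(self):
        assert NetworkSpec.from_variant("more_fc").fc_sizes == (4096, 4096, 2)
        assert NetworkSpec.from_variant("deeper_more_fc").fc_sizes == (4096, 4096, 2)

    def test_inconsistent_depth_rejected(self):
        with pytest.raises(ValueError, match="convolutions per block"):
            NetworkSpec("deeper", "none", [[64, 64], [128, 128]], (256, 256, 2))

    def test_final_fc_must_be_two_way(self):
        with pytest.raises(ValueError, match="ending in 2"):
            NetworkSpec("base", "none", [[8, 8], [16, 16]], (32, 32, 3))

    def test_fusion_channel_contract(self):
        assert NetworkSpec.from_variant("base").in_channels == 1
        assert NetworkSpec.from_variant("base", fusion="early").in_channels == 3
        with pytest.raises(ValueError):
            build_network(NetworkSpec.from_variant("base", fusion="early"), in_channels=1)


class TestLrSchedule:
    def test_paper_endpoints_and_log_midpoint(self):
        cfg = TrainConfig()
        assert lr_schedule(1, cfg) == pytest.approx(3e-3)
        assert lr_schedule(25, cfg) == pytest.approx(3e-5)
        # log-spaced: epoch 13 of 25 sits exactly one decade down
        assert lr_schedule(13, cfg) == pytest.approx(3e-4)

    def test_single_epoch_schedule(self):
        cfg = TrainConfig(epochs=1)
        assert lr_schedule(1, cfg) == pytest.approx(cfg.lr_start)

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            lr_schedule(26, TrainConfig())


class TestTraining:
    def _spec(self):
        return NetworkSpec.from_variant("base", filters=(4, 8), fc_width=16)

    def test_separable_classes_learned_quickly(self):
        """Bright-vs-dark patches: training error < 5% within 5 epochs."""
        ps = _random_patchset(n=160, separation=2.0, seed=1)
        model = build_network(self._spec(), seed=1, dropout_rate=0.0)
        cfg = TrainConfig(epochs=5, batch_size=8, dropout_rate=0.0, seed=1)
        hist = train(model, ps, cfg)
        assert hist.errors[-1] < 0.05

    def test_same_seed_same_final_loss(self):
        ps = _random_patchset(n=80, separation=1.0, seed=2)
        losses = []
        for _ in range(2):
            model = build_network(self._spec(), seed=3, dropout_rate=0.25)
            cfg = TrainConfig(epochs=2, batch_size=16, dropout_rate=0.25, seed=3)
            losses.append(train(model, ps, cfg).losses[-1])
        assert losses[0] == losses[1]

    def test_lr_curve_follows_schedule(self):
        ps = _random_patchset(n=40, separation=1.0)
        model = build_network(self._spec(), seed=0)
        cfg = TrainConfig(epochs=3, batch_size=16, seed=0)
        hist = train(model, ps, cfg)
        assert hist.lrs == [lr_schedule(e, cfg) for e in (1, 2, 3)]
        assert hist.lrs[-1] == pytest.approx(
            cfg.lr_start * (cfg.lr_end / cfg.lr_start) ** (2 / (cfg.epochs - 1))
        )

    def test_single_class_warns(self):
        ps = _random_patchset(n=30)
        ps.labels[:] = 0
        model = build_network(self._spec(), seed=0)
        with pytest.warns(UserWarning, match="single class"):
            train(model, ps, TrainConfig(epochs=1, batch_size=16, seed=0))

    def test_divergent_loss_aborts_with_diagnostics(self):
        ps = _random_patchset(n=60, separation=1.0)
        model = build_network(self._spec(), seed=0)
        cfg = TrainConfig(epochs=3, lr_start=1e6, lr_end=1e5, batch_size=16, seed=0)
        with pytest.raises(RuntimeError, match="loss"), np.errstate(all="ignore"):
            train(model, ps, cfg)


class TestDenseInference:
    def test_stride_four_and_normalized_scores(self, tiny_trained, small_cohort):
        _, test_set = small_cohort
        maps = score_volume(tiny_trained, test_set[0][0])
        assert all(sm.stride == 4 for sm in maps)
        for sm in maps:
            np.testing.assert_allclose(sm.probs.sum(axis=-1), 1.0, atol=1e-9)

    def test_matches_patchwise_forward_pass(self, tiny_trained, small_cohort):
        """Dense scores equal the patch classifier on the matching windows."""
        _, test_set = small_cohort
        from lggseg.preprocess import apply_normalizer

        vol = apply_normalizer(test_set[0][0], tiny_trained.stats)
        model = tiny_trained.model
        maps = dense_inference(model, vol)
        z = 1
        sm = maps[z]
        H, W = vol.shape[1:]
        rng = np.random.default_rng(0)
        h, w, _ = sm.probs.shape
        for _ in range(10):
            i = int(rng.integers(0, min(h, (H - PATCH_SIZE) // 4 + 1)))
            j = int(rng.integers(0, min(w, (W - PATCH_SIZE) // 4 + 1)))
            r, c = HALF + 4 * i, HALF + 4 * j
            win = vol.voxels[z, r - HALF : r + HALF + 1, c - HALF : c + HALF + 1]
            p = model.predict_proba(win[None, None])[0]
            np.testing.assert_allclose(sm.probs[i, j], p, atol=1e-10)

    def test_repeated_runs_identical(self, tiny_trained, small_cohort):
        _, test_set = small_cohort
        a = score_volume(tiny_trained, test_set[0][0])
        b = score_volume(tiny_trained, test_set[0][0])
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.probs, y.probs)

    def test_slice_below_receptive_field_rejected(self):
        model = build_network(NetworkSpec.from_variant("base", filters=(4, 8), fc_width=16))
        with pytest.raises(ValueError, match="receptive"):
            dense_inference(model, Volume(np.ones((2, 20, 20))))


class TestFusion:
    def _tiny(self, fusion):
        return build_network(
            NetworkSpec.from_variant("base", fusion=fusion, filters=(4, 8), fc_width=16),
            seed=4,
        )

    def test_early_fusion_shape_contract(self):
        model = self._tiny("early")
        p = model.predict_proba(np.random.default_rng(0).standard_normal((2, 3, 33, 33)))
        assert p.shape == (2, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_late_fusion_has_three_independent_pathways(self):
        early, late = self._tiny("early"), self._tiny("late")
        assert len(late.pathways) == 3 and len(early.pathways) == 1
        ratio = late.n_conv_parameters / early.n_conv_parameters
        assert 2.5 < ratio < 3.5

    @pytest.mark.parametrize("fusion", ["early", "late"])
    def test_fusion_dense_inference_normalized(self, fusion):
        model = self._tiny(fusion)
        vol = Volume(np.random.default_rng(1).standard_normal((3, 40, 40)))
        maps = dense_inference(model, vol)
        assert len(maps) == 3
        for sm in maps:
            np.testing.assert_allclose(sm.probs.sum(axis=-1), 1.0, atol=1e-9)


def test_checkpoint_round_trip(tmp_path, tiny_trained):
    p = tmp_path / "model.npz"
    save_checkpoint(tiny_trained.model, p, extra={"note": "x"})
    model, extra = load_checkpoint(p)
    assert extra == {"note": "x"}
    rng = np.random.default_rng(0)
    x = rng.standard_normal((3, 1, 33, 33))
    np.testing.assert_array_equal(
        model.predict_proba(x), tiny_trained.model.predict_proba(x)
    )
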