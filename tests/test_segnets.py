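"""Network builders, residual blocks, training loop, checkpointing, estimator."""

import numpy as np
import pytest

from rffseg.segnets import (ModelConfig, RFFSegmenter, build_fcn, build_model,
                            build_resunet, build_unet, load_checkpoint,
                            residual_block, save_checkpoint, train)
from rffseg.synthetic import default_config, generate_dataset


def small_config(arch, **kw):
    base = dict(architecture=arch, input_size=(32, 32), depth=2,
                base_filters=4, use_rff=True, q_factor=16, rff_sigma=1.0,
                optimizer_seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestBuilders:
    @pytest.mark.parametrize("arch", ["fcn", "unet", "resunet"])
    @pytest.mark.parametrize("use_rff", [False, True])
    def test_output_shape_and_range(self, arch, use_rff):
        net = build_model(small_config(arch, use_rff=use_rff))
        x = np.zeros((2, 32, 32), dtype=np.float32)
        out = net.forward(x)
        assert out.shape == (2, 32, 32)
        assert out.min() >= 0 and out.max() <= 1

    @pytest.mark.parametrize("arch", ["fcn", "unet", "resunet"])
    def test_128_input_with_depth_4_gives_8x8_pre_rff_grid(self, arch):
        cfg = ModelConfig(architecture=arch, input_size=(128, 128), depth=4,
                          base_filters=2, use_rff=True, q_factor=8,
                          rff_sigma=1.0)
        net = build_model(cfg)
        x = np.zeros((1, 128, 128), dtype=np.float32)
        _, _, feats = net.forward_full(x)
        assert feats[net._pre_rff_name].shape[1:3] == (8, 8)
        assert feats["rff"].shape[1:] == (8, 8, 8)

    @pytest.mark.parametrize("arch", ["fcn", "unet", "resunet"])
    def test_rff_layer_adds_parameters(self, arch):
        # bottleneck holds 16 channels here, so q_factor 32 widens the head
        plain = build_model(small_config(arch, use_rff=False))
        with_rff = build_model(small_config(arch, use_rff=True, q_factor=32))
        assert with_rff.n_parameters() > plain.n_parameters()

    @pytest.mark.parametrize("arch", ["fcn", "unet", "resunet"])
    def test_disabling_rff_recovers_baseline_topology(self, arch):
        plain = [d["type"] for d in
                 build_model(small_config(arch, use_rff=False)).layer_summary()]
        enhanced = [d["type"] for d in
                    build_model(small_config(arch, use_rff=True)).layer_summary()]
        assert "rff" not in plain
        assert enhanced.count("rff") == 1
        enhanced.remove("rff")
        assert enhanced == plain

    def test_unet_resunet_differ_only_in_block_type(self):
        unet = build_unet(small_config("unet")).layer_summary()
        res = build_resunet(small_config("resunet")).layer_summary()
        skeleton = lambda s: [d["type"] for d in s
                              if d["type"] not in ("conv", "resblock")]
        assert skeleton(unet) == skeleton(res)
        # every 2-conv block becomes one residual block (5 blocks at depth 2)
        assert sum(d["type"] == "conv" for d in unet) == 2 * 5 + 1
        assert sum(d["type"] == "resblock" for d in res) == 5

    def test_decoder_receives_matching_skip_channels(self):
        net = build_unet(small_config("unet"))
        for up, block in net.decoder:
            first = block[0].describe()
            assert first["cin"] == 2 * up.cout

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(architecture="unet", input_size=(50, 50), depth=3)

    def test_invalid_q_factor_rejected(self):
        with pytest.raises(ValueError):
            small_config("unet", q_factor=10)

    def test_identical_seeds_give_identical_weights(self):
        a = build_model(small_config("resunet"))
        b = build_model(small_config("resunet"))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)


class TestResidualBlock:
    def test_zero_transform_is_identity(self):
        F = np.random.default_rng(0).random((4, 4, 3))
        np.testing.assert_array_equal(
            residual_block(F, lambda f: np.zeros_like(f)), F)

    def test_identity_transform_doubles(self):
        F = np.random.default_rng(1).random((4, 4, 2))
        np.testing.assert_allclose(residual_block(F, lambda f: f), 2 * F)

    def test_jacobian_contains_identity_component(self):
        # with a linear transform T, the block's Jacobian is J_T + I
        rng = np.random.default_rng(2)
        A = rng.normal(size=(1, 1)) * 0.3     # 1-channel linear map
        transform = lambda f: f * A[0, 0]
        F = rng.random((2, 2, 1))
        eps = 1e-6
        jac = np.zeros((4, 4))
        for k in range(4):
            dF = np.zeros(4)
            dF[k] = eps
            up = residual_block(F + dF.reshape(2, 2, 1), transform)
            dn = residual_block(F - dF.reshape(2, 2, 1), transform)
            jac[:, k] = ((up - dn) / (2 * eps)).ravel()
        np.testing.assert_allclose(jac - A[0, 0] * np.eye(4), np.eye(4),
                                   atol=1e-6)

    def test_channel_change_requires_projection(self):
        F = np.ones((2, 2, 1))
        widen = lambda f: np.concatenate([f, f], axis=-1)
        with pytest.raises(ValueError):
            residual_block(F, widen)
        out = residual_block(F, widen, proj=widen)
        np.testing.assert_allclose(out, 2 * np.ones((2, 2, 2)))

    def test_layer_with_zero_weights_is_identity_on_nonnegatives(self):
        # equal channel counts: the skip is a pure identity (no projection)
        from rffseg._autodiff import Tensor
        from rffseg.segnets import ResidualBlock

        rng = np.random.default_rng(3)
        block = ResidualBlock("b", 3, 3, rng)
        assert block.proj is None
        for p in block.params():
            p.data[:] = 0
        x = Tensor(rng.random((1, 8, 8, 3)).astype(np.float32))
        np.testing.assert_allclose(block(x).data, x.data)


class TestTraining:
    def test_one_epoch_one_batch_is_one_step(self):
        cfg = default_config(32, seed=1)
        pairs, _ = generate_dataset(40, cfg)
        splits = ["train"] * 32 + ["val"] * 4 + ["test"] * 4
        mc = small_config("unet", epochs=1, batch_size=32)
        _, hist = train(build_model(mc), pairs, splits)
        assert hist["steps"] == 1
        assert len(hist["train_loss"]) == 1
        assert len(hist["val_loss"]) == 2   # pre-training entry + 1 epoch

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_validation_loss_improves(self, seed):
        cfg = default_config(32, seed=seed + 100)
        pairs, splits = generate_dataset(60, cfg)
        mc = small_config("unet", epochs=8, batch_size=16,
                          optimizer_seed=seed, rff_sigma="median")
        _, hist = train(build_model(mc), pairs, splits)
        assert hist["best_val_loss"] < hist["val_loss"][0]

    def test_empty_split_rejected(self):
        pairs, _ = generate_dataset(10, default_config(32))
        with pytest.raises(ValueError):
            train(build_model(small_config("unet")), pairs, ["train"] * 10)

    def test_selectable_learning_rates(self):
        assert small_config("unet", learning_rate=1e-3).learning_rate == 1e-3
        assert small_config("unet", learning_rate=1e-4).learning_rate == 1e-4


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, quick_net):
        net = quick_net["net"]
        x = np.stack([p.image for p in quick_net["pairs"][:3]])
        path = str(tmp_path / "model.ckpt")
        save_checkpoint(net, path)
        clone = load_checkpoint(path)
        np.testing.assert_allclose(clone.forward(x), net.forward(x),
                                   rtol=0, atol=1e-6)
        np.testing.assert_array_equal(clone.rff.rff_params.omega,
                                      net.rff.rff_params.omega)


class TestRFFSegmenterEstimator:
    def test_fit_predict_interface(self):
        cfg = default_config(32, seed=2)
        pairs, _ = generate_dataset(30, cfg)
        X = np.stack([p.image for p in pairs])
        y = np.stack([p.mask for p in pairs])
        est = RFFSegmenter(depth=2, base_filters=4, epochs=2, batch_size=8,
                           q_factor=8, random_state=0)
        est.fit(X, y)
        assert est.net_ is not None
        assert est.predict(X[:2]).shape == (2, 32, 32)
        assert set(np.unique(est.predict(X[:2]))) <= {0, 1}
        proba = est.predict_proba(X[:2])
        assert proba.min() >= 0 and proba.max() <= 1
        assert 0 <= est.score(X[:4], y[:4]) <= 1

    def test_sklearn_clone_and_params(self):
        from sklearn.base import clone

        est = RFFSegmenter(architecture="fcn", q_factor=32)
        c = clone(est)
        assert c.get_params() == est.get_params()
        c.set_params(epochs=5)
        assert c.epochs == 5
        with pytest.raises(ValueError):
            c.set_params(nonsense=1)

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError):
            RFFSegmenter().predict(np.zeros((1, 32, 32)))
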