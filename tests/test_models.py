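import numpy as np
import pytest

from sersdemux.exceptions import ConfigurationError
from sersdemux.models import (
    ConvBlock,
    ModelConfig,
    TransUNetDemultiplexer,
    UNet1d,
    build_model,
    demultiplex,
    load_checkpoint,
    save_checkpoint,
)

SMALL = dict(base_channels=4, embed_dim=16, n_heads=2, n_layers=1)


def small_config(family, **over):
    return ModelConfig(family=family, **{**SMALL, **over})


class TestModelConfig:
    def test_bottleneck_length_is_four_halvings(self):
        cfg = small_config("unet")
        assert cfg.bottleneck_length == 56  # 896 / 2**4

    def test_rejects_indivisible_input_length(self):
        with pytest.raises(ConfigurationError):
            small_config("unet", input_length=900)

    def test_rejects_patch_not_matching_bottleneck(self):
        # 896/8 = 112 patches vs bottleneck 56: fusion impossible
        with pytest.raises(ConfigurationError, match="fusion"):
            small_config("trans_unet", patch_length=8)

    def test_rejects_unknown_family(self):
        with pytest.raises(ConfigurationError):
            small_config("dense_net")


@pytest.mark.parametrize("family", ["unet", "resnet_unet", "trans_unet"])
class TestForwardContract:
    def test_output_shape_and_tanh_range(self, family):
        model = build_model(small_config(family))
        x = np.random.default_rng(0).uniform(-1, 1, (3, 896))
        y = demultiplex(model, x)
        assert y.shape == (3, 896)
        assert np.all(y <= 1.0) and np.all(y >= -1.0)

    def test_seeded_builds_are_bit_identical(self, family):
        a = build_model(small_config(family, seed=42))
        b = build_model(small_config(family, seed=42))
        x = np.random.default_rng(1).uniform(-1, 1, 896)
        np.testing.assert_array_equal(demultiplex(a, x), demultiplex(b, x))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_different_seeds_differ(self, family):
        a = build_model(small_config(family, seed=1))
        b = build_model(small_config(family, seed=2))
        x = np.random.default_rng(1).uniform(-1, 1, 896)
        assert not np.array_equal(demultiplex(a, x), demultiplex(b, x))

    def test_wrong_input_length_rejected(self, family):
        model = build_model(small_config(family))
        with pytest.raises(ValueError):
            demultiplex(model, np.zeros(512))


class TestEncoderTrace:
    def test_length_trace_mirrors(self):
        model = build_model(small_config("unet"))
        x = np.random.default_rng(0).uniform(-1, 1, (1, 896)).astype(np.float32)
        h = np.ascontiguousarray(x[:, None, :].transpose(1, 0, 2))
        lengths = []
        for enc, pool in zip(model.encoders, model.pools):
            h = pool.forward(enc.forward(h))
            lengths.append(h.shape[-1])
        assert lengths == [448, 224, 112, 56]
        b = model.bottleneck.forward(h)
        assert b.shape[-1] == 56
        # the decoder's transposed convolutions double the length back up
        up_lengths = []
        for up in model.upsamples:
            b = up.forward(b)
            up_lengths.append(b.shape[-1])
            b = np.zeros((up.c_out, 1, b.shape[-1]), dtype=b.dtype)
        assert up_lengths == [112, 224, 448, 896]
        # full forward restores the input length
        assert demultiplex(model, x).shape == (1, 896)

    def test_plain_block_nested_in_resnet_block(self):
        """A ResNet block minus its additive shortcut is the plain block."""
        rng = np.random.default_rng(0)
        res = ConvBlock(3, 3, rng, resnet=True, dtype=np.float64)
        x = rng.standard_normal((3, 2, 16))
        with_skip = res.forward(x)
        res.resnet = False
        without_skip = res.forward(x)
        np.testing.assert_allclose(with_skip - x, without_skip, atol=1e-12)
        plain = ConvBlock(3, 3, rng, resnet=False, dtype=np.float64)
        assert plain.shortcut is None


class TestTransformerBranch:
    def test_patch_count(self):
        model = build_model(small_config("trans_unet", patch_length=16))
        assert model.transformer.n_patches == 56

    def test_encode_shape_and_family_guard(self):
        from sersdemux.models import transformer_encode
        model = build_model(small_config("trans_unet"))
        x = np.random.default_rng(0).uniform(-1, 1, (3, 896))
        enc = transformer_encode(model, x)
        assert enc.shape == (3, model.c_bottleneck, 56)
        single = transformer_encode(model, x[0])
        np.testing.assert_array_equal(single, enc[0])
        with pytest.raises(ConfigurationError):
            transformer_encode(build_model(small_config("unet")), x)

    def test_zero_layers_degenerates_to_embeddings(self):
        model = build_model(small_config("trans_unet", n_layers=0))
        x = np.random.default_rng(0).uniform(-1, 1, (2, 896)).astype(np.float32)
        tokens = x.reshape(2, 56, 16)
        z = model.transformer.patch_embed.forward(tokens) + model.transformer.pos_embed.value
        expect = model.transformer.out_proj.forward(z).transpose(2, 0, 1)
        got = model.transformer.forward(x[:, None, :])
        np.testing.assert_allclose(got, expect, rtol=1e-6)

    def test_permutation_equivariance_without_positions(self):
        """With position embeddings zeroed, permuting input patches permutes
        the attention output accordingly (self-attention is set-structured)."""
        model = build_model(small_config("trans_unet", n_layers=1))
        model.transformer.pos_embed.value[...] = 0.0
        rng = np.random.default_rng(3)
        x = rng.uniform(-1, 1, (1, 1, 896)).astype(np.float32)
        out = model.transformer.forward(x)  # (c_b, 1, 56)
        xp = x.reshape(1, 56, 16).copy()
        xp[:, [0, 13]] = xp[:, [13, 0]]  # swap two patches
        out_p = model.transformer.forward(xp.reshape(1, 1, 896))
        expect = out.copy()
        expect[:, :, [0, 13]] = expect[:, :, [13, 0]]
        np.testing.assert_allclose(out_p, expect, atol=1e-5)


class TestCheckpoint:
    def test_round_trip_preserves_outputs(self, tmp_path):
        model = build_model(small_config("trans_unet", seed=9))
        x = np.random.default_rng(0).uniform(-1, 1, 896)
        path = tmp_path / "ck.npz"
        save_checkpoint(path, model)
        back = load_checkpoint(path)
        np.testing.assert_array_equal(demultiplex(model, x), demultiplex(back, x))

    def test_family_mismatch_refused(self, tmp_path):
        model = build_model(small_config("unet"))
        path = tmp_path / "ck.npz"
        save_checkpoint(path, model)
        with pytest.raises(ConfigurationError):
            load_checkpoint(path, family="trans_unet")


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        est = TransUNetDemultiplexer(base_channels=4, epochs=2)
        params = est.get_params()
        assert params["base_channels"] == 4
        clone = TransUNetDemultiplexer(**params)
        assert clone.get_params() == params

    def test_sklearn_clone(self):
        from sklearn.base import clone
        est = TransUNetDemultiplexer(base_channels=4, epochs=1, seed=3)
        c = clone(est)
        assert c.get_params() == est.get_params()

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            TransUNetDemultiplexer().predict(np.zeros((1, 896)))
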