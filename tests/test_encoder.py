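"""Gated-convolution encoder identities: GLU arithmetic, residual wiring,
receptive field, masking and determinism."""

import numpy as np
import pytest

from pascal import EncoderConfig, embed, encode, init_encoder_params
from pascal.encoder import conv1d_same, encoder_forward, glu_forward


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@pytest.fixture()
def tiny_cfg():
    return EncoderConfig(
        vocab_size=10, d_e=4, kernel=3, n_conv_layers=3, filters=(5, 6, 6),
        n_residual_blocks=2, dropout=0.0, dtype="float64",
    )


class TestConfig:
    def test_default_stack_matches_reference_hyperparameters(self):
        cfg = EncoderConfig(vocab_size=100)
        assert cfg.d_e == 200
        assert cfg.filters == (128, 256, 256, 256)
        assert cfg.kernel == 3 and cfg.n_conv_layers == 4 and cfg.n_residual_blocks == 3
        assert cfg.d_h == 256
        assert cfg.dropout == 0.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kernel": 4},
            {"filters": (128, 256)},
            {"n_residual_blocks": 2},
            {"dropout": 1.0},
            {"filters": (128, 256, 512, 256)},
        ],
    )
    def test_inconsistent_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EncoderConfig(vocab_size=10, **kwargs)


class TestEmbed:
    def test_lookup_copies_table_rows_and_pad_is_zero(self, tiny_cfg):
        params = init_encoder_params(tiny_cfg, np.random.default_rng(0))
        table = params["embed.W"]
        idx = np.array([3, 0, 7])
        out = embed(idx, table)
        assert out.shape == (3, tiny_cfg.d_e)
        np.testing.assert_array_equal(out[0], table[3])
        np.testing.assert_array_equal(out[1], 0.0)

    def test_out_of_range_index_rejected(self, tiny_cfg):
        params = init_encoder_params(tiny_cfg, np.random.default_rng(0))
        with pytest.raises(IndexError):
            embed(np.array([tiny_cfg.vocab_size]), params["embed.W"])

    def test_default_embedding_width(self):
        cfg = EncoderConfig(vocab_size=50)
        params = init_encoder_params(cfg, np.random.default_rng(1))
        assert embed(np.arange(8), params["embed.W"]).shape == (8, 200)


class TestGluBlock:
    def test_hand_computed_convolution_and_gate(self):
        # one channel, kernel (1, 2, 1), input [1, 2, 3] under zero padding:
        # conv = [1*0+2*1+1*2, 1*1+2*2+1*3, 1*2+2*3+1*0] = [4, 8, 8]
        params = {
            "c.W": np.array([1.0, 2.0, 1.0]).reshape(3, 1, 1),
            "c.b": np.zeros(1),
            "c.M": np.array([0.5, 0.0, 0.0]).reshape(3, 1, 1),
            "c.g": np.array([1.0]),
        }
        x = np.array([1.0, 2.0, 3.0]).reshape(1, 3, 1)
        h, _ = glu_forward(x, params, "c")
        conv = np.array([4.0, 8.0, 8.0])
        gate = sigmoid(np.array([0.0 * 0.5 + 1, 1 * 0.5 + 1, 2 * 0.5 + 1]))
        np.testing.assert_allclose(h[0, :, 0], conv * gate, rtol=1e-12)

    def test_zero_gate_kernel_halves_the_linear_path(self):
        rng = np.random.default_rng(0)
        params = {
            "c.W": rng.normal(size=(3, 2, 4)),
            "c.b": rng.normal(size=4),
            "c.M": np.zeros((3, 2, 4)),
            "c.g": np.zeros(4),
        }
        x = rng.normal(size=(2, 6, 2))
        h, _ = glu_forward(x, params, "c")
        lin, _ = conv1d_same(x, params["c.W"], params["c.b"])
        np.testing.assert_allclose(h, 0.5 * lin, rtol=1e-12)

    def test_zero_linear_kernel_annihilates_output(self):
        rng = np.random.default_rng(1)
        params = {
            "c.W": np.zeros((3, 2, 4)),
            "c.b": np.zeros(4),
            "c.M": rng.normal(size=(3, 2, 4)),
            "c.g": rng.normal(size=4),
        }
        h, _ = glu_forward(rng.normal(size=(1, 5, 2)), params, "c")
        assert (h == 0).all()

    def test_gate_bound_output_never_exceeds_linear_path(self):
        rng = np.random.default_rng(2)
        params = {
            "c.W": rng.normal(size=(3, 2, 4)),
            "c.b": rng.normal(size=4),
            "c.M": rng.normal(size=(3, 2, 4)),
            "c.g": rng.normal(size=4),
        }
        x = rng.normal(size=(2, 6, 2))
        h, _ = glu_forward(x, params, "c")
        lin, _ = conv1d_same(x, params["c.W"], params["c.b"])
        assert (np.abs(h) <= np.abs(lin) + 1e-12).all()


class TestEncoderStack:
    def test_residual_blocks_are_identity_under_zero_kernels(self, tiny_cfg):
        """With every residual-block kernel and bias zero, blocks 2..n pass
        their input through unchanged, so the output equals the projected
        block-1 output."""
        rng = np.random.default_rng(3)
        params = init_encoder_params(tiny_cfg, rng)
        for layer in (2, 3):
            for name in ("W", "M", "b", "g"):
                params[f"conv{layer}.{name}"][:] = 0.0
        idx = rng.integers(1, 10, size=(1, 7))
        mask = np.ones((1, 7))
        H = encode(idx, mask, params, tiny_cfg)
        x = params["embed.W"][idx]
        h1, _ = glu_forward(x, params, "conv1")
        np.testing.assert_allclose(H, h1 @ params["proj.W"], rtol=1e-12)

    def test_output_shape_and_pad_rows_zero(self, tiny_cfg):
        rng = np.random.default_rng(4)
        params = init_encoder_params(tiny_cfg, rng)
        idx = rng.integers(1, 10, size=(2, 8))
        idx[0, 5:] = 0
        mask = (idx > 0).astype(float)
        H = encode(idx, mask, params, tiny_cfg)
        assert H.shape == (2, 8, tiny_cfg.d_h)
        assert (H[0, 5:] == 0).all()

    def test_default_width_of_context_vectors(self):
        cfg = EncoderConfig(vocab_size=30, dropout=0.0)
        rng = np.random.default_rng(5)
        params = init_encoder_params(cfg, rng)
        idx = rng.integers(1, 30, size=(1, 8))
        H = encode(idx, np.ones((1, 8)), params, cfg)
        assert H.shape == (1, 8, 256)

    def test_receptive_field_radius_matches_analytic_value(self, tiny_cfg):
        """Perturbing a character farther than R = n_layers*(k-1)/2 from
        position i leaves h_i unchanged; perturbing within R changes it."""
        R = tiny_cfg.receptive_radius
        assert R == 3  # 3 layers * (3-1)/2
        rng = np.random.default_rng(6)
        params = init_encoder_params(tiny_cfg, rng)
        N = 12
        idx = rng.integers(1, 10, size=(1, N))
        mask = np.ones((1, N))
        H0 = encode(idx, mask, params, tiny_cfg)
        i = 2
        far = idx.copy()
        far[0, i + R + 1] = (far[0, i + R + 1] % 9) + 1 if far[0, i + R + 1] != 9 else 1
        np.testing.assert_array_equal(encode(far, mask, params, tiny_cfg)[0, i], H0[0, i])
        near = idx.copy()
        near[0, i + R] = (near[0, i + R] % 9) + 1
        assert not np.allclose(encode(near, mask, params, tiny_cfg)[0, i], H0[0, i])

    def test_padded_positions_cannot_leak_into_valid_ones(self, tiny_cfg):
        rng = np.random.default_rng(7)
        params = init_encoder_params(tiny_cfg, rng)
        idx = rng.integers(1, 10, size=(1, 9))
        mask = np.ones((1, 9))
        mask[0, 6:] = 0.0
        H0 = encode(idx, mask, params, tiny_cfg)
        altered = idx.copy()
        altered[0, 6:] = rng.integers(1, 10, size=3)  # junk beyond the mask
        np.testing.assert_array_equal(encode(altered, mask, params, tiny_cfg), H0)

    def test_inference_is_deterministic(self, tiny_cfg):
        rng = np.random.default_rng(8)
        params = init_encoder_params(tiny_cfg, rng)
        idx = rng.integers(1, 10, size=(2, 6))
        mask = np.ones((2, 6))
        a = encode(idx, mask, params, tiny_cfg)
        b = encode(idx, mask, params, tiny_cfg)
        assert (a == b).all()

    def test_dropout_only_active_in_training_mode(self, tiny_cfg):
        cfg = EncoderConfig(**{**tiny_cfg.__dict__, "dropout": 0.5})
        rng = np.random.default_rng(9)
        params = init_encoder_params(cfg, rng)
        idx = rng.integers(1, 10, size=(1, 6))
        mask = np.ones((1, 6))
        t1, _ = encoder_forward(params, cfg, idx, mask, train=True, rng=np.random.default_rng(1))
        t2, _ = encoder_forward(params, cfg, idx, mask, train=True, rng=np.random.default_rng(2))
        assert not np.allclose(t1, t2)
        e1 = encode(idx, mask, params, cfg)
        e2 = encode(idx, mask, params, cfg)
        assert (e1 == e2).all()

    def test_pad_embedding_row_is_zero(self, tiny_cfg):
        params = init_encoder_params(tiny_cfg, np.random.default_rng(10))
        assert (params["embed.W"][0] == 0).all()
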