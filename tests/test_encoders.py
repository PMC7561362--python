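"""Shape contracts, attention normalization and masking of the omics encoders."""

import numpy as np
import pytest

from epifusion.autograd import Tensor, conv1d_full_height
from epifusion.encoders import (
    EncoderConfig,
    HistoneEncoder,
    MethylationEncoder,
    TFEncoder,
    _max_pool1d,
    encode_histone,
    encode_methylation,
    encode_tf,
)
from epifusion.ingest import HistoneMatrix, MethylationTrack, N_TFS, TFMatrix


@pytest.fixture(scope="module")
def cfg():
    return EncoderConfig(seed=5)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(5)


def make_hm(rng):
    return HistoneMatrix(rng.poisson(3.0, size=(7, 40)).astype(float))


class TestHistoneEncoder:
    def test_conv_feature_map_length_34(self, cfg, rng):
        enc = HistoneEncoder(cfg, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(2, 7, 40)))
        fm = conv1d_full_height(x, enc.conv_w, enc.conv_b)
        assert fm.shape == (2, cfg.conv_kernels, 34)
        assert cfg.conv_out_len == 34

    def test_pooled_length_12_matches_sliding_window_oracle(self, cfg, rng):
        x = rng.normal(size=(1, 4, 34))
        pooled = _max_pool1d(Tensor(x), cfg.pool_size, cfg.pool_stride, cfg.pool_pad)
        assert (34 + 2 - 3) // 3 + 1 == 12
        assert pooled.shape == (1, 4, 12)
        padded = np.pad(x, ((0, 0), (0, 0), (1, 1)))
        oracle = np.stack(
            [padded[:, :, s : s + 3].max(axis=2) for s in range(0, 34, 3)], axis=2
        )
        np.testing.assert_array_equal(pooled.data, oracle)

    def test_latent_is_80_and_attention_over_12_steps(self, cfg, rng):
        lat = encode_histone(make_hm(rng), cfg)
        assert lat.h_hm.shape == (80,)
        assert lat.bin_attention.shape == (12,)
        assert lat.bin_attention.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(lat.bin_attention >= 0)

    def test_all_zero_input_gives_uniform_bin_attention(self, cfg):
        lat = encode_histone(HistoneMatrix(np.zeros((7, 40))), cfg)
        np.testing.assert_allclose(lat.bin_attention, np.full(12, 1 / 12), atol=1e-12)

    def test_wrong_shape_rejected(self, cfg):
        enc = HistoneEncoder(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError, match="7, 40"):
            enc(Tensor(np.zeros((1, 7, 39))))

    def test_batched_equals_single(self, cfg, rng):
        enc = HistoneEncoder(cfg, np.random.default_rng(1))
        enc.eval()
        mats = [make_hm(rng) for _ in range(3)]
        h_batch, _ = enc(Tensor(np.stack([m.values for m in mats])))
        for i, m in enumerate(mats):
            h_one, _ = enc(Tensor(m.values[None]))
            np.testing.assert_allclose(h_batch.data[i], h_one.data[0], atol=1e-12)


class TestMethylationEncoder:
    @pytest.mark.parametrize("length", [1, 3, 57])
    def test_fixed_20_dim_output_for_any_length(self, cfg, rng, length):
        track = MethylationTrack(np.arange(length) * 2 - 2000, rng.random(length))
        lat = encode_methylation(track, cfg)
        assert lat.h_me.shape == (20,)
        assert lat.cpg_attention.shape == (length,)
        assert lat.cpg_attention.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_cpg_attention_is_exactly_one(self, cfg):
        lat = encode_methylation(MethylationTrack([0], [0.4]), cfg)
        assert lat.cpg_attention.tolist() == [1.0]

    def test_empty_track_maps_to_zero_vector(self, cfg):
        lat = encode_methylation(MethylationTrack([], []), cfg)
        np.testing.assert_array_equal(lat.h_me, np.zeros(20))
        assert lat.cpg_attention.size == 0

    def test_batched_variable_lengths_equal_single_encodes(self, cfg, rng):
        """Padding plus per-sample reversal must not leak across tracks."""
        enc = MethylationEncoder(cfg, np.random.default_rng(2))
        enc.eval()
        tracks = [rng.random(n) for n in (5, 1, 12, 3)]
        h_batch, w_batch = enc(tracks)
        for i, b in enumerate(tracks):
            h_one, w_one = enc([b])
            np.testing.assert_allclose(h_batch.data[i], h_one.data[0], atol=1e-10)
            np.testing.assert_allclose(
                w_batch.data[i, : len(b)], w_one.data[0, : len(b)], atol=1e-10
            )


class TestTFEncoder:
    def test_latent_is_5(self, cfg, rng):
        values = np.zeros((3, N_TFS))
        mask = np.zeros(N_TFS, dtype=bool)
        cols = rng.choice(N_TFS, 6, replace=False)
        mask[cols] = True
        values[:, cols] = rng.random((3, 6)) * 5
        lat = encode_tf(TFMatrix(values, mask), cfg)
        assert lat.h_tf.shape == (5,)
        assert lat.tf_attention.shape == (N_TFS, N_TFS)
        row_sums = lat.tf_attention[cols][:, cols].sum(axis=1)
        np.testing.assert_allclose(row_sums, 1.0, atol=1e-6)

    def test_masked_columns_cannot_influence_output(self, cfg):
        """100 random perturbations of masked columns leave h_tf bit-identical."""
        rng = np.random.default_rng(9)
        enc = TFEncoder(cfg, np.random.default_rng(3))
        enc.eval()
        mask = np.zeros((1, N_TFS), dtype=bool)
        mask[0, [10, 500, 900]] = True
        base = np.zeros((1, N_TFS, 3))
        base[0, [10, 500, 900], :] = rng.random((3, 3)) * 4
        h_ref, _ = enc(base, mask)
        for _ in range(100):
            perturbed = base.copy()
            perturbed[0, ~mask[0], :] = rng.normal(size=(N_TFS - 3, 3)) * 100
            h, _ = enc(perturbed, mask)
            assert np.array_equal(h.data, h_ref.data)

    def test_two_column_attention_matches_softmax_oracle(self, cfg):
        enc = TFEncoder(cfg, np.random.default_rng(4))
        enc.eval()
        vals = np.array([[[1.0, 2.0, 0.5], [3.0, 1.0, 2.0]]])  # (1, 2, 3)
        mask = np.ones((1, 2), dtype=bool)
        _, attn = enc(vals, mask)
        x = vals[0] / cfg.tf_input_scale
        q = x @ enc.wq.weight.data + enc.wq.bias.data
        k = x @ enc.wk.weight.data + enc.wk.bias.data
        scores = q @ k.T / np.sqrt(cfg.tf_qkv_dim)
        oracle = np.exp(scores) / np.exp(scores).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(attn.data[0], oracle, atol=1e-12)

    def test_all_masked_gene_maps_to_zero_vector(self, cfg):
        tf = TFMatrix(np.zeros((3, N_TFS)), np.zeros(N_TFS, dtype=bool))
        lat = encode_tf(tf, cfg)
        np.testing.assert_array_equal(lat.h_tf, np.zeros(5))


def test_encoders_are_deterministic(cfg, rng):
    """Same seed and input -> bit-identical outputs in inference mode."""
    hm = make_hm(rng)
    track = MethylationTrack(np.arange(4) * 3, rng.random(4))
    a = encode_histone(hm, cfg)
    b = encode_histone(hm, EncoderConfig(seed=5))
    assert np.array_equal(a.h_hm, b.h_hm)
    m1 = encode_methylation(track, cfg)
    m2 = encode_methylation(track, EncoderConfig(seed=5))
    assert np.array_equal(m1.h_me, m2.h_me)
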