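"""Network components: shapes, determinism, chromosome pruning, sampling,
serialization, and gradient correctness."""

import numpy as np
import pytest

import transmodal.nn as nn
from transmodal.containers import ChromosomeIndex
from transmodal.model import (
    Discriminator,
    ModelConfig,
    ModelState,
    Translator,
    make_decoder,
    make_encoder,
)


@pytest.fixture
def chrom_index():
    return ChromosomeIndex(
        groups=[("chr1", np.arange(0, 4)), ("chr2", np.arange(4, 7)),
                ("chr3", np.arange(7, 9))],
        catch_all=np.array([], dtype=np.intp))


@pytest.fixture
def cfg():
    return ModelConfig(latent_dim=8, rna_hidden=6, atac_per_chrom_dim=3,
                       adt_hidden=5)


class TestEncoders:
    def test_rna_encoder_output_shape(self):
        cfg = ModelConfig()
        enc = make_encoder("rna", 3000, cfg, np.random.default_rng(0))
        out = enc(np.zeros((5, 3000)), training=False)
        assert out.shape == (5, 128)

    def test_inference_is_deterministic(self, cfg):
        enc = make_encoder("rna", 10, cfg, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(4, 10))
        a = enc(x, training=False)
        b = enc(x, training=False)
        assert np.array_equal(a, b)

    def test_full_mask_with_zero_bias_gives_zero_preactivations(self, cfg):
        cfg_m = ModelConfig(latent_dim=8, rna_hidden=6, mask_rate_rna=1.0,
                            dropout_rate=0.0)
        enc = make_encoder("rna", 10, cfg_m, np.random.default_rng(0))
        for p in enc.parameters():
            if p.value.ndim == 1:
                p.value[...] = 0.0
        x = np.random.default_rng(1).normal(size=(4, 10))
        out = enc(x, training=True, rng=np.random.default_rng(2))
        assert np.allclose(out, 0.0)

    def test_atac_encoder_concatenated_block_width(self, cfg, chrom_index):
        enc = make_encoder("atac", 9, cfg, np.random.default_rng(0), chrom_index)
        block = enc.net.layers[0]
        y, _ = block.forward(np.random.default_rng(1).random((2, 9)))
        assert y.shape == (2, 3 * 3)  # 3 chromosomes x 3 dims each
        out = enc(np.random.default_rng(1).random((2, 9)), training=False)
        assert out.shape == (2, 8)

    def test_chromosome_blocks_are_independent(self, cfg, chrom_index):
        enc = make_encoder("atac", 9, cfg, np.random.default_rng(0), chrom_index)
        block = enc.net.layers[0]
        x = np.random.default_rng(1).random((3, 9))
        before, _ = block.forward(x)
        block.Ws[0].value[...] += 1.0  # perturb chromosome 1's weights
        after, _ = block.forward(x)
        # chromosome 2 and 3 blocks unchanged
        assert np.array_equal(before[:, 3:], after[:, 3:])
        assert not np.array_equal(before[:, :3], after[:, :3])

    def test_within_group_permutation_invariance(self, cfg, chrom_index):
        enc = make_encoder("atac", 9, cfg, np.random.default_rng(0), chrom_index)
        block = enc.net.layers[0]
        x = np.random.default_rng(1).random((3, 9))
        y0, _ = block.forward(x)
        # permute chr1's features together with the matching weight rows
        perm = np.array([2, 0, 3, 1])
        x2 = x.copy()
        x2[:, :4] = x[:, perm]
        block.Ws[0].value[...] = block.Ws[0].value[perm]
        y1, _ = block.forward(x2)
        assert np.allclose(y0, y1)

    def test_atac_parameter_count_excludes_inter_chromosomal(self, cfg, chrom_index):
        enc = make_encoder("atac", 9, cfg, np.random.default_rng(0), chrom_index)
        d, latent = cfg.atac_per_chrom_dim, cfg.latent_dim
        sizes = [4, 3, 2]
        expected = sum(s * d + d for s in sizes) + (d * 3 * latent + latent)
        total = sum(p.value.size for p in enc.parameters())
        assert total == expected


class TestTranslator:
    def test_sample_false_is_deterministic_mean_path(self, cfg):
        trans = Translator(("r", "a"), 8, 0.01, np.random.default_rng(0))
        emb = np.random.default_rng(1).normal(size=(6, 8))
        lb1 = trans.translate(emb, "r", "a", sample=False)
        lb2 = trans.translate(emb, "r", "a", sample=False)
        assert not lb1.sampled
        assert np.array_equal(lb1.embedding, lb2.embedding)

    def test_degenerate_variance_recovers_mean_path(self, cfg):
        trans = Translator(("r", "a"), 8, 0.01, np.random.default_rng(0))
        emb = np.random.default_rng(1).normal(size=(4, 8))
        mean, logvar, _ = trans.encode_latent(emb, "r")
        out_det, _ = trans.decode_latent(mean, "a")
        # force variance -> 0 by patching logvar block output to -inf limit
        eps = np.random.default_rng(2).standard_normal(mean.shape)
        z = mean + np.exp(-60.0 / 2.0) * eps
        out_smp, _ = trans.decode_latent(z, "a")
        assert np.allclose(out_det, out_smp, atol=1e-10)

    def test_reparameterization_moments(self):
        # identity output block, mean 0, logvar 0: draws are standard normal
        trans = Translator(("r", "a"), 4, 0.01, np.random.default_rng(0))
        out_block = trans.out_blocks["a"].layers[0]
        out_block.W.value[...] = np.eye(4)
        out_block.b.value[...] = 0.0
        rng = np.random.default_rng(3)
        n = 10_000
        mean = np.zeros((n, 4))
        logvar = np.zeros((n, 4))
        eps = rng.standard_normal(mean.shape)
        z = mean + np.exp(logvar / 2.0) * eps
        emb, _ = trans.decode_latent(z, "a")
        # LeakyReLU(identity draws): undo the slope on the negative part
        draws = np.where(emb < 0, emb / 0.01, emb)
        assert np.all(np.abs(draws.mean(axis=0)) < 0.05)
        assert np.all(np.abs(draws.var(axis=0) - 1.0) < 0.1)

    def test_output_block_shared_across_sources(self):
        trans = Translator(("r", "a"), 8, 0.01, np.random.default_rng(0))
        assert trans.out_blocks["r"] is trans.out_blocks["r"]
        # the same object serves r->r and a->r
        z = np.random.default_rng(1).normal(size=(3, 8))
        o1, _ = trans.decode_latent(z, "r")
        o2, _ = trans.decode_latent(z, "r")
        assert np.array_equal(o1, o2)

    def test_missing_block_raises(self):
        trans = Translator(("r", "a"), 8, 0.01, np.random.default_rng(0))
        with pytest.raises(KeyError, match="adt"):
            trans.encode_latent(np.zeros((2, 8)), "adt")


class TestDecodersAndDiscriminator:
    def test_rna_decoder_zero_params_give_zero_output(self, cfg):
        dec = make_decoder("rna", 11, cfg, np.random.default_rng(0))
        for p in dec.parameters():
            p.value[...] = 0.0
        out = dec(np.random.default_rng(1).normal(size=(3, 8)), training=False)
        assert np.allclose(out, 0.0)
        assert out.shape == (3, 11)

    def test_atac_decoder_outputs_in_unit_interval(self, cfg, chrom_index):
        dec = make_decoder("atac", 9, cfg, np.random.default_rng(0), chrom_index)
        out = dec(np.random.default_rng(1).normal(size=(5, 8)), training=False)
        assert out.shape == (5, 9)
        assert np.all((out > 0) & (out < 1))

    def test_atac_decoder_zero_params_give_half(self, cfg, chrom_index):
        dec = make_decoder("atac", 9, cfg, np.random.default_rng(0), chrom_index)
        for p in dec.parameters():
            p.value[...] = 0.0
        out = dec(np.random.default_rng(1).normal(size=(2, 8)), training=False)
        assert np.allclose(out, 0.5)

    def test_discriminator_shape_and_range(self):
        dis = Discriminator(8, 0.01, np.random.default_rng(0))
        p = dis(np.random.default_rng(1).normal(size=(7, 8)))
        assert p.shape == (7, 1)
        assert np.all((p > 0) & (p < 1))

    def test_discriminator_zero_params_give_half(self):
        dis = Discriminator(8, 0.01, np.random.default_rng(0))
        for p in dis.parameters():
            p.value[...] = 0.0
        out = dis(np.random.default_rng(1).normal(size=(3, 8)))
        assert np.allclose(out, 0.5)

    def test_discriminator_matches_hand_forward(self):
        # 1-dim toy: sigmoid(W2 * LeakyReLU(W1*x + b1) + b2)
        dis = Discriminator(1, 0.01, np.random.default_rng(0))
        w1 = dis.net.layers[0].W.value[0, 0]
        b1 = dis.net.layers[0].b.value[0]
        w2 = dis.net.layers[2].W.value[0, 0]
        b2 = dis.net.layers[2].b.value[0]
        x = -0.7
        h = w1 * x + b1
        h = h if h >= 0 else 0.01 * h
        expected = 1.0 / (1.0 + np.exp(-(w2 * h + b2)))
        assert dis(np.array([[x]]))[0, 0] == pytest.approx(expected, abs=1e-12)


class TestModelState:
    def test_full_translation_path_deterministic(self, chrom_index):
        cfg = ModelConfig(latent_dim=8, rna_hidden=6, atac_per_chrom_dim=3)
        state = ModelState(cfg, {"r": "rna", "a": "atac"}, {"r": 12, "a": 9},
                           seed=0, chrom_index=chrom_index)
        x = np.random.default_rng(1).normal(size=(4, 12))
        def run():
            h = state.encoders["r"](x, training=False)
            lb = state.translator.translate(h, "r", "a", sample=False)
            return state.decoders["a"](lb.embedding, training=False)
        assert np.array_equal(run(), run())

    def test_serialization_bit_exact_roundtrip(self, tmp_path, chrom_index):
        cfg = ModelConfig(latent_dim=8, rna_hidden=6, atac_per_chrom_dim=3)
        state = ModelState(cfg, {"r": "rna", "a": "atac"}, {"r": 12, "a": 9},
                           seed=3, chrom_index=chrom_index)
        path = tmp_path / "model.npz"
        state.save(path)
        back = ModelState.load(path)
        for (n1, p1), (n2, p2) in zip(state._named_params(), back._named_params()):
            assert n1 == n2
            assert np.array_equal(p1.value, p2.value)
        assert back.fingerprint() == state.fingerprint()
        assert back.side_kinds == state.side_kinds

    def test_adt_side_has_no_masking(self):
        cfg = ModelConfig(latent_dim=8, adt_hidden=5)
        state = ModelState(cfg, {"r": "rna", "a": "adt"}, {"r": 12, "a": 6}, seed=0)
        assert state.encoders["a"].mask.rate == 0.0
        assert state.encoders["r"].mask.rate == 0.5


class TestGradients:
    def test_dense_stack_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        net = nn.Sequential(nn.Dense(5, 4, rng), nn.LeakyReLU(0.01),
                            nn.Dense(4, 3, rng), nn.Sigmoid())
        x = rng.normal(size=(6, 5))
        t = rng.random((6, 3))
        def loss():
            y, _ = net.forward(x)
            return float(((y - t) ** 2).sum())
        y, caches = net.forward(x)
        net.backward(caches, 2.0 * (y - t))
        h = 1e-6
        for p in net.parameters():
            idx = np.unravel_index(p.value.size // 2, p.value.shape)
            orig = p.value[idx]
            p.value[idx] = orig + h
            lp = loss()
            p.value[idx] = orig - h
            lm = loss()
            p.value[idx] = orig
            num = (lp - lm) / (2 * h)
            assert p.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_block_dense_gradients(self):
        rng = np.random.default_rng(0)
        groups = [np.array([0, 2]), np.array([1, 3, 4])]
        layer = nn.BlockDense(groups, 2, rng)
        x = rng.normal(size=(4, 5))
        y, cache = layer.forward(x)
        g = rng.normal(size=y.shape)
        gx = layer.backward(cache, g)
        h = 1e-6
        def obj():
            y2, _ = layer.forward(x)
            return float((y2 * g).sum())
        for p in layer.parameters():
            idx = np.unravel_index(0, p.value.shape)
            orig = p.value[idx]
            p.value[idx] = orig + h
            lp = obj()
            p.value[idx] = orig - h
            lm = obj()
            p.value[idx] = orig
            assert p.grad[idx] == pytest.approx((lp - lm) / (2 * h), rel=1e-5, abs=1e-8)
        # input gradient
        i, j = 1, 3
        xo = x[i, j]
        x[i, j] = xo + h
        lp = obj()
        x[i, j] = xo - h
        lm = obj()
        x[i, j] = xo
        assert gx[i, j] == pytest.approx((lp - lm) / (2 * h), rel=1e-5, abs=1e-8)
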