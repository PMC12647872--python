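"""Network architecture, parameter accounting and the loss functions."""

import numpy as np
import pytest

from pdprog.model import (
    LossConfig,
    ModelError,
    PDualNetConfig,
    build_model,
    joint_loss,
    mds_mse,
    parameter_count_table,
    reconstruction_loss_total,
    weighted_cross_entropy,
)
from pdprog.nn import Tensor, softmax

rng = np.random.default_rng(7)


@pytest.fixture(scope="module")
def model():
    m = build_model(seed=0)
    m.eval()
    return m


def _closed_form_count(cfg: PDualNetConfig) -> int:
    """Independent layer-wise bookkeeping of the deployed parameter count."""
    def affine(a, b):
        return a * b + b

    d = cfg.d_model
    sive = sum(affine(a, b) for a, b in zip(cfg.sive_dims, cfg.sive_dims[1:]))
    attn = affine(d, 3 * d) + affine(d, d)
    ff = affine(d, cfg.ff_dim) + affine(cfg.ff_dim, d)
    enc_layer = attn + ff + 2 * (2 * d)
    dec_ff = affine(d, cfg.dec_ff_dim) + affine(cfg.dec_ff_dim, d)
    dec_layer = 2 * attn + dec_ff + 3 * (2 * d)
    subtype = sum(affine(a, b) for a, b in zip(cfg.subtype_dims, cfg.subtype_dims[1:]))
    head = sum(affine(a, b)
               for a, b in zip(cfg.score_head_dims, cfg.score_head_dims[1:]))
    embeddings = 3 * cfg.vocab_size * cfg.score_embed_dim
    proj = affine(3 * cfg.score_embed_dim, d)
    positional = (cfg.enc_max_len + cfg.dec_max_len) * d
    cls = d
    return sive + cls + positional + enc_layer + dec_layer + subtype + head \
        + embeddings + proj


class TestParameterCount:
    def test_default_configuration_deploys_34703_parameters(self, model):
        table = parameter_count_table(model)
        assert table["deployed_total"] == 34703

    def test_affine_layer_closed_form(self):
        from pdprog.nn import Linear
        lin = Linear(89, 128, rng)
        assert sum(p.data.size for p in lin.parameters()) == 89 * 128 + 128

    @pytest.mark.parametrize("seed", range(5))
    def test_enumerated_count_matches_closed_form_for_random_configs(self, seed):
        r = np.random.default_rng(seed)
        d = int(r.integers(8, 24))
        cfg = PDualNetConfig(
            sive_dims=(int(r.integers(40, 120)), int(r.integers(32, 96)), d),
            d_model=d, ff_dim=int(r.integers(16, 64)),
            subtype_dims=(d, int(r.integers(4, 16)), 4),
            dec_ff_dim=int(r.integers(16, 64)),
            score_head_dims=(d, int(r.integers(8, 24)), 3),
            score_embed_dim=d,
            enc_max_len=int(r.integers(6, 20)), dec_max_len=int(r.integers(6, 30)),
        )
        m = build_model(cfg, seed=seed)
        assert parameter_count_table(m)["deployed_total"] == _closed_form_count(cfg)

    def test_inconsistent_widths_rejected(self):
        with pytest.raises(ModelError):
            build_model(PDualNetConfig(sive_dims=(89, 128, 32)), seed=0)


class TestForwardShapes:
    def test_sive_embedding_width_16(self, model):
        z = model.sive_encode(rng.random((4, 89)))
        assert z.shape == (4, 16)
        assert model.sive_reconstruct(z).shape == (4, 89)

    def test_sive_rejects_wrong_width(self, model):
        with pytest.raises(ModelError):
            model.sive_encode(rng.random((4, 88)))

    def test_batch_of_one_equals_single_sample(self, model):
        x = rng.random((1, 89))
        z1 = model.sive_encode(x).data
        z2 = model.sive_encode(np.concatenate([x, rng.random((3, 89))]))
        assert np.allclose(z1[0], z2.data[0])

    def test_identical_inputs_identical_embeddings_in_eval(self, model):
        x = rng.random((2, 3, 89))
        x[1] = x[0]
        z = model.sive_encode(x)
        d = model.dise_encode(z)
        assert np.array_equal(d.data[0], d.data[1])

    def test_dise_width_16_and_order_sensitivity(self, model):
        z = model.sive_encode(rng.random((1, 4, 89)))
        d = model.dise_encode(z)
        assert d.shape == (1, 16)
        z_rev = Tensor(z.data[:, ::-1].copy())
        d_rev = model.dise_encode(z_rev)
        assert not np.allclose(d.data, d_rev.data)  # positional encoding active

    def test_dise_padding_invariance(self, model):
        z = rng.random((1, 5, 16))
        pad = np.array([[False, False, False, True, True]])
        d1 = model.dise_encode(Tensor(z), padding_mask=pad).data.copy()
        z2 = z.copy()
        z2[0, 3:] = 99.0
        d2 = model.dise_encode(Tensor(z2), padding_mask=pad).data
        assert np.allclose(d1, d2)

    def test_dise_rejects_empty_sequence(self, model):
        with pytest.raises(ModelError):
            model.dise_encode(Tensor(np.zeros((1, 0, 16))))

    def test_classify_emits_4_logits_and_softmax_behaves(self, model):
        d = model.dise_encode(model.sive_encode(rng.random((3, 2, 89))))
        s = model.classify(d)
        assert s.shape == (3, 4)
        p = softmax(s).data
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.array_equal(np.argmax(p, axis=1), np.argmax(s.data, axis=1))


@pytest.fixture(scope="module")
def d_p(model):
    return model.dise_encode(model.sive_encode(rng.random((3, 2, 89))))


class TestScoreDecoder:

    @pytest.mark.parametrize("horizon", [1, 2, 3, 4, 5])
    def test_output_length_equals_horizon(self, model, d_p, horizon):
        ctx = rng.random((3, 3)) * 30
        tt = rng.random((3, horizon, 3)) * 30
        tf = model.decode_scores(d_p, ctx, horizon, "teacher_forced",
                                 teacher_targets=tt)
        ar = model.decode_scores(d_p, ctx, horizon, "autoregressive")
        assert tf.shape == (3, horizon, 3)
        assert ar.shape == (3, horizon, 3)

    def test_modes_coincide_at_horizon_one(self, model, d_p):
        ctx = rng.random((3, 3)) * 30
        tf = model.decode_scores(d_p, ctx, 1, "teacher_forced").data
        ar = model.decode_scores(d_p, ctx, 1, "autoregressive").data
        assert np.array_equal(tf, ar)

    def test_teacher_forcing_is_causal(self, model, d_p):
        ctx = rng.random((3, 3)) * 30
        tt = rng.random((3, 4, 3)) * 30
        base = model.decode_scores(d_p, ctx, 4, "teacher_forced",
                                   teacher_targets=tt).data.copy()
        tt2 = tt.copy()
        tt2[:, 2, :] += 25  # input for step 4 only
        pert = model.decode_scores(d_p, ctx, 4, "teacher_forced",
                                   teacher_targets=tt2).data
        assert np.allclose(base[:, :3], pert[:, :3])
        assert not np.allclose(base[:, 3], pert[:, 3])

    def test_autoregressive_decoding_is_deterministic(self, model, d_p):
        ctx = rng.random((3, 3)) * 30
        a = model.decode_scores(d_p, ctx, 4, "autoregressive").data
        b = model.decode_scores(d_p, ctx, 4, "autoregressive").data
        assert np.array_equal(a, b)

    def test_out_of_range_scores_never_raise(self, model, d_p):
        ctx = np.array([[500.0, -3.0, 1e6]] * 3)  # far outside the vocabulary
        out = model.decode_scores(d_p, ctx, 2, "autoregressive")
        assert np.all(np.isfinite(out.data))

    def test_quantization_clips_to_vocab_levels(self, model):
        q = model.quantize_scores(np.array([[-5.0, 42.4, 250.0]]))
        assert q.tolist() == [[0, 42, 99]]


class TestLosses:
    def test_reconstruction_perfect_is_zero(self):
        x = rng.random((4, 89))
        assert reconstruction_loss_total(x, Tensor(x)).item() == 0.0

    def test_reconstruction_single_residual_hand_value(self):
        x = np.zeros((1, 5))
        x_hat = np.array([[1.0, 2.0, 0.0, 0.0, 0.0]])
        assert reconstruction_loss_total(x, Tensor(x_hat)).item() == pytest.approx(5.0)

    def test_reconstruction_matches_double_sum_oracle(self):
        x = rng.random((6, 13))
        x_hat = rng.random((6, 13))
        expected = sum((x[i, j] - x_hat[i, j]) ** 2
                       for i in range(6) for j in range(13))
        assert reconstruction_loss_total(x, Tensor(x_hat)).item() == \
            pytest.approx(expected)

    def test_cross_entropy_uniform_logits_is_log4(self):
        logits = Tensor(np.zeros((1, 4)))
        loss = weighted_cross_entropy(logits, [2], np.ones(4))
        assert loss.item() == pytest.approx(np.log(4.0), abs=1e-12)

    def test_cross_entropy_invariant_to_weight_rescaling(self):
        logits = Tensor(rng.normal(size=(8, 4)))
        y = rng.integers(0, 4, 8)
        w = np.array([1.0, 2.5, 0.5, 4.0])
        a = weighted_cross_entropy(logits, y, w).item()
        b = weighted_cross_entropy(logits, y, 17.3 * w).item()
        assert a == pytest.approx(b, abs=1e-12)

    def test_cross_entropy_hand_calculation_b2(self):
        logits = Tensor(np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 2.0, 0.0, 0.0]]))
        y = [0, 1]
        w = np.array([1.0, 3.0, 1.0, 1.0])
        l1 = -np.log(np.exp(1) / (np.exp(1) + 3))
        l2 = -np.log(np.exp(2) / (np.exp(2) + 3))
        expected = (1 * l1 + 3 * l2) / 4
        got = weighted_cross_entropy(logits, y, w).item()
        assert got == pytest.approx(expected, abs=1e-9)

    def test_equal_weights_reduce_to_unweighted_mean(self):
        logits = Tensor(rng.normal(size=(10, 4)))
        y = rng.integers(0, 4, 10)
        weighted = weighted_cross_entropy(logits, y, np.full(4, 2.0)).item()
        from pdprog.nn import log_softmax
        plain = float(np.mean(-log_softmax(logits).data[np.arange(10), y]))
        assert weighted == pytest.approx(plain, abs=1e-12)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ModelError):
            weighted_cross_entropy(Tensor(np.zeros((1, 4))), [0],
                                   np.array([1.0, 0.0, 1.0, 1.0]))

    def test_mds_mse_perfect_prediction_is_zero(self):
        u = rng.random((4, 2, 3))
        assert mds_mse(u, Tensor(u)).item() == 0.0

    def test_mds_mse_alpha_masks_other_parts(self):
        u = rng.random((4, 2, 3))
        u_hat = u.copy()
        u_hat[:, :, 1:] += 100
        loss = mds_mse(u, Tensor(u_hat), alphas=(1.0, 0.0, 0.0))
        assert loss.item() == pytest.approx(0.0)

    def test_mds_mse_matches_hand_arithmetic(self):
        u = np.zeros((2, 1, 3))
        u_hat = np.array([[[1.0, 2.0, 3.0]], [[1.0, 0.0, 1.0]]])
        # per-part MSE: (1+1)/2, (4+0)/2, (9+1)/2 with alphas (1, 2, 0.5)
        expected = 1.0 * 1.0 + 2.0 * 2.0 + 0.5 * 5.0
        assert mds_mse(u, Tensor(u_hat), alphas=(1.0, 2.0, 0.5)).item() == \
            pytest.approx(expected)

    def test_joint_loss_warmup_returns_mse_exactly(self):
        cfg = LossConfig(e_thres=10)
        mse = Tensor(np.array(3.7))
        assert joint_loss(mse, Tensor(np.array(9.9)), 10, cfg) is mse

    def test_joint_loss_zero_weights_average_the_terms(self):
        cfg = LossConfig(e_thres=0, trainable_balance=False)
        out = joint_loss(Tensor(np.array(2.0)), Tensor(np.array(4.0)), 1, cfg)
        assert out.item() == pytest.approx(3.0)

    def test_joint_loss_log2_weight_quarters_the_mse(self):
        cfg = LossConfig(w1_init=np.log(2.0), w2_init=0.0, e_thres=0,
                         trainable_balance=False)
        out = joint_loss(Tensor(np.array(8.0)), Tensor(np.array(6.0)), 1, cfg)
        assert out.item() == pytest.approx(8.0 / 4 + 6.0 / 2)

    def test_joint_loss_monotone_in_both_terms(self):
        cfg = LossConfig(e_thres=0, trainable_balance=False)
        base = joint_loss(Tensor(np.array(1.0)), Tensor(np.array(1.0)), 1, cfg).item()
        assert joint_loss(Tensor(np.array(2.0)), Tensor(np.array(1.0)), 1, cfg).item() > base
        assert joint_loss(Tensor(np.array(1.0)), Tensor(np.array(2.0)), 1, cfg).item() > base

    def test_trainable_balance_terms_receive_gradients(self):
        cfg = LossConfig(e_thres=0, trainable_balance=True)
        out = joint_loss(Tensor(np.array(2.0)), Tensor(np.array(3.0)), 1, cfg)
        out.backward()
        # d/dw1 [e^{-w1}/2 * mse] at w1=0 = -mse/2
        assert cfg.w1.grad == pytest.approx(-1.0)
        assert cfg.w2.grad == pytest.approx(-1.5)
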