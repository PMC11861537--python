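"""Layer semantics and architecture invariants of SWCTNet."""

import numpy as np
import pytest

from swctnet.autodiff import Tensor
from swctnet.model import (ABLATION_VARIANTS, ModelConfig, SWCTNet,
                           build_variant, load_checkpoint, mix_pool,
                           save_checkpoint, sliding_window_partition)
from swctnet.nn import (Adam, Dropout, WindowNorm, log_softmax,
                        max_norm_constraint, softmax)

RNG = np.random.default_rng(21)


class TestSlidingWindowPartition:
    def test_full_length_window_is_identity(self):
        X = RNG.normal(size=(3, 20))
        wins = sliding_window_partition(X, 20, 5)
        assert wins.shape == (1, 3, 20)
        assert np.array_equal(wins[0], X)

    def test_index_arithmetic(self):
        X = RNG.normal(size=(2, 100))
        wins = sliding_window_partition(X, 40, 10)
        assert wins.shape == (7, 2, 40)
        assert np.array_equal(wins[2], X[:, 20:60])

    def test_overlapping_windows_share_columns(self):
        X = RNG.normal(size=(1, 30))
        wins = sliding_window_partition(X, 20, 10)
        assert np.array_equal(wins[0][:, 10:], wins[1][:, :10])

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_partition(np.zeros((1, 5)), 10, 2)

    def test_tensor_and_numpy_paths_agree(self):
        X = RNG.normal(size=(2, 4, 24))
        a = sliding_window_partition(X, 8, 4)
        b = sliding_window_partition(Tensor(X), 8, 4).data
        assert np.allclose(a, b)


class TestMixPool:
    def test_ratio_one_is_max_pooling(self):
        x = np.array([[1.0, 3.0, -2.0, 5.0]])
        assert np.allclose(mix_pool(x, 1.0), [[3.0, 5.0]])

    def test_ratio_zero_is_average_pooling(self):
        x = np.array([[1.0, 3.0, -2.0, 5.0]])
        assert np.allclose(mix_pool(x, 0.0), [[2.0, 1.5]])

    def test_constant_input_invariant_for_any_ratio(self):
        x = np.full((2, 6), 1.7)
        for r in (0.0, 0.3, 1.0):
            assert np.allclose(mix_pool(x, r), 1.7)

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError):
            mix_pool(np.zeros((1, 3)), 0.5, kernel=4, stride=4)


class TestWindowNorm:
    def test_standardizes_along_time(self):
        wn = WindowNorm(3)
        x = Tensor(RNG.normal(size=(5, 3, 16)))
        y = wn(x).data
        assert np.abs(y.mean(axis=-1)).max() < 1e-9
        assert np.abs(y.std(axis=-1) - 1).max() < 1e-4

    def test_gamma_zero_collapses_to_beta(self):
        wn = WindowNorm(2)
        wn.gamma.data[:] = 0.0
        wn.beta.data[:] = 0.7
        y = wn(Tensor(RNG.normal(size=(4, 2, 8)))).data
        assert np.allclose(y, 0.7)

    def test_affine_invariance_of_input(self):
        wn = WindowNorm(2)
        x = RNG.normal(size=(4, 2, 8))
        y1 = wn(Tensor(x)).data
        y2 = wn(Tensor(3.0 * x + 11.0)).data
        assert np.allclose(y1, y2, atol=1e-6)


class TestConfig:
    def test_key_dims_follow_quarter_rule(self):
        cfg = ModelConfig(n_channels=9)
        assert cfg.key_dim_channel == 3   # ceil(9/4)
        assert cfg.key_dim_time == 2      # ceil(8/4)

    def test_indivisible_heads_rejected_at_config_time(self):
        with pytest.raises(ValueError, match="n_heads"):
            ModelConfig(n_heads=3).validate()

    def test_kernel_longer_than_window_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            ModelConfig(conv_kernel=17, window_len=16).validate()

    def test_dict_round_trip(self):
        cfg = ModelConfig(task="regression", n_targets=12, seed=9)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


@pytest.fixture(scope="module")
def model():
    return SWCTNet(ModelConfig(seed=3))


@pytest.fixture(scope="module")
def batch():
    return np.random.default_rng(4).normal(size=(6, 9, 40))


class TestArchitectureInvariants:
    def test_attention_rows_sum_to_one(self, model, batch):
        model.eval()
        _, state = model.encode(batch, collect_state=True)
        for layer_maps in state.A_c + state.A_t:
            for A in layer_maps:
                assert np.allclose(A.sum(axis=-1), 1.0, atol=1e-6)
                assert np.all(A >= 0)

    def test_gate_values_in_open_unit_interval(self, model, batch):
        model.eval()
        _, state = model.encode(batch, collect_state=True)
        for lam in state.lambda_gate:
            assert np.all(lam > 0) and np.all(lam < 1)

    def test_fresh_gate_weights_give_half(self, batch):
        # W_g and b_g initialize to zero -> sigmoid(0) = 1/2
        m = SWCTNet(ModelConfig(seed=8))
        m.eval()
        _, state = m.encode(batch, collect_state=True)
        for lam in state.lambda_gate:
            assert np.allclose(lam, 0.5)

    def test_eval_forward_is_deterministic(self, model, batch):
        model.eval()
        p1 = model.classification_head(model.encode(batch)).data
        p2 = model.classification_head(model.encode(batch)).data
        assert np.array_equal(p1, p2)

    def test_training_dropout_changes_outputs(self, batch):
        m = SWCTNet(ModelConfig(seed=5))
        m.train()
        a = m.classification_head(m.encode(batch)).data
        b = m.classification_head(m.encode(batch)).data
        assert not np.array_equal(a, b)

    def test_residual_contract_output_shape(self, model, batch):
        model.eval()
        fused = model.encode(batch)
        cfg = model.config
        assert fused.shape == (len(batch), cfg.n_tokens, cfg.pooled_len)

    def test_gradient_reaches_every_parameter_group(self, batch):
        m = SWCTNet(ModelConfig(seed=6))
        m.train()
        y = np.random.default_rng(0).integers(0, 3, len(batch))
        logits = m.classification_logits(m.encode(batch))
        loss = (-log_softmax(logits)[np.arange(len(batch)), y]).mean()
        loss.backward()
        dead = [k for k, p in m.parameters().items()
                if p.grad is None or not np.any(p.grad)]
        assert dead == []

    def test_max_norm_holds_after_every_step(self, batch):
        m = SWCTNet(ModelConfig(seed=7))
        m.train()
        opt = Adam(m.parameters(), lr=0.05)
        y = np.random.default_rng(1).integers(0, 3, len(batch))
        for _ in range(5):
            m.zero_grad()
            logits = m.classification_logits(m.encode(batch))
            loss = (-log_softmax(logits)[np.arange(len(batch)), y]).mean()
            loss.backward()
            opt.step()
            max_norm_constraint(m.constrained_parameters(), m.config.max_norm)
            for p in m.constrained_parameters():
                norms = np.linalg.norm(p.data, axis=-1)
                assert norms.max() <= m.config.max_norm + 1e-6


class TestHeads:
    def test_zero_head_weights_give_uniform_probabilities(self, batch):
        m = SWCTNet(ModelConfig(seed=9, n_classes=4))
        m.eval()
        m.head.W.data[:] = 0.0
        m.head.b.data[:] = 0.0
        probs = m.classification_head(m.encode(batch)).data
        assert np.allclose(probs, 0.25)

    def test_probabilities_sum_to_one(self, model, batch):
        model.eval()
        probs = model.classification_head(model.encode(batch)).data
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_softmax_shift_invariance_of_argmax(self):
        z = RNG.normal(size=(5, 4))
        p1 = softmax(Tensor(z)).data
        p2 = softmax(Tensor(z + 100.0)).data
        assert np.array_equal(p1.argmax(1), p2.argmax(1))

    def test_dominant_logit_saturates(self):
        z = np.zeros((1, 5))
        z[0, 2] = 20.0
        p = softmax(Tensor(z)).data
        assert p[0, 2] > 0.999

    def test_regression_head_is_affine(self, batch):
        m = SWCTNet(ModelConfig(seed=10, task="regression", n_targets=7))
        m.eval()
        fused0 = m.encode(np.zeros_like(batch))
        b0 = m.regression_head(fused0).data
        assert np.all(np.isfinite(b0))
        pooled = Tensor(RNG.normal(size=(2, m.config.n_tokens)))
        h = lambda t: (t @ m.head.W + m.head.b).data
        assert np.allclose(h(pooled * 3.0) - h(pooled * 0.0),
                           3.0 * (h(pooled) - h(pooled * 0.0)), atol=1e-9)


@pytest.fixture(scope="module")
def gen_model():
    return SWCTNet(ModelConfig(seed=11, task="generation", gen_dim=5))


class TestGenerationDecoder:
    def test_output_length_equals_horizon(self, gen_model, batch):
        gen_model.eval()
        fused = gen_model.encode(batch)
        for horizon in (1, 4):
            out = gen_model.generation_decoder(fused, horizon=horizon)
            assert out.shape == (len(batch), horizon, 5)

    def test_eval_mode_repeatable(self, gen_model, batch):
        gen_model.eval()
        fused = gen_model.encode(batch)
        a = gen_model.generation_decoder(fused, horizon=3).data
        b = gen_model.generation_decoder(fused, horizon=3).data
        assert np.array_equal(a, b)

    def test_prefix_seeds_first_step(self, gen_model, batch):
        gen_model.eval()
        fused = gen_model.encode(batch)
        prefix = np.ones((len(batch), 5))
        a = gen_model.generation_decoder(fused, horizon=2, y_prefix=prefix).data
        b = gen_model.generation_decoder(fused, horizon=2).data
        assert not np.allclose(a, b)

    def test_invalid_horizon_rejected(self, gen_model, batch):
        gen_model.eval()
        fused = gen_model.encode(batch)
        with pytest.raises(ValueError):
            gen_model.generation_decoder(fused, horizon=0)


class TestAblationVariants:
    def test_all_variants_constructible_and_ordered(self):
        base = ModelConfig(seed=0)
        counts = {v: build_variant(base, v).n_parameters()
                  for v in ABLATION_VARIANTS}
        assert counts["M1"] < counts["M2"]
        assert counts["M1"] < counts["M3"]
        assert counts["M2"] < counts["M4"]
        assert counts["M3"] < counts["M4"]

    def test_variant_flags(self):
        base = ModelConfig()
        m1 = build_variant(base, "M1")
        assert not m1.config.use_swcnn and not m1.config.use_channel_attention
        m4 = build_variant(base, "M4")
        assert m4.config.use_swcnn and m4.config.use_channel_attention

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_variant(ModelConfig(), "M5")


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, model, batch):
        model.eval()
        before = model.classification_head(model.encode(batch)).data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        loaded.eval()
        after = loaded.classification_head(loaded.encode(batch)).data
        assert np.allclose(before, after)
        assert loaded.config == model.config


class TestDropout:
    def test_eval_mode_is_identity(self):
        d = Dropout(0.5)
        d.training = False
        x = Tensor(RNG.normal(size=(4, 4)))
        assert np.array_equal(d(x, np.random.default_rng(0)).data, x.data)

    def test_inverted_scaling_preserves_expectation(self):
        d = Dropout(0.5)
        x = Tensor(np.ones((200, 200)))
        y = d(x, np.random.default_rng(1)).data
        assert y.mean() == pytest.approx(1.0, abs=0.02)

    def test_spatial_dropout_drops_whole_channels(self):
        d = Dropout(0.5, spatial=True)
        x = Tensor(np.ones((8, 6, 10)))
        y = d(x, np.random.default_rng(2)).data
        # each (sample, channel) slice is uniformly zero or scaled
        assert set(np.unique(y)) <= {0.0, 2.0}
        per_channel = y.reshape(48, 10)
        assert all(len(np.unique(row)) == 1 for row in per_channel)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            Dropout(1.0)
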